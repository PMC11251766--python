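"""Centroid size, pairwise and generalized Procrustes superimposition.

Shape is treated in Kendall's sense: configurations are translated to a common
centroid, scaled to unit centroid size, and rotated to best fit; size is kept
aside as centroid size (CS) and analysed separately. Procrustes distance is the
Euclidean distance between superimposed unit-CS coordinate sets (the tangent /
partial-distance convention of mainstream geometric-morphometrics software).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import LandmarkConfiguration, as_coords_array
from .errors import InvalidParameterError, MissingLandmarkError

__all__ = [
    "centroid_size",
    "align_pair",
    "procrustes_distance",
    "GeneralizedProcrustes",
    "GPAResult",
    "gpa",
]


def _coords(x) -> np.ndarray:
    if isinstance(x, LandmarkConfiguration):
        x = x.coords
    return np.asarray(x, dtype=float)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Accepts a LandmarkConfiguration or a (k, 3) array. Missing landmarks are an
    error — estimate them first.
    """
    x = _coords(config)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidParameterError("centroid size needs at least 2 landmarks")
    if np.isnan(x).any():
        raise MissingLandmarkError("centroid size undefined with missing landmarks")
    centered = x - x.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _center_scale(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Center at origin and scale to unit centroid size; returns (shape, CS)."""
    centered = x - x.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise InvalidParameterError("degenerate configuration: all landmarks coincide")
    return centered / cs, cs


def _optimal_rotation(mobile: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation R minimizing ||mobile @ R - target||_F (Kabsch/SVD)."""
    h = mobile.T @ target
    u, s, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def align_pair(mobile, target, allow_reflection: bool = False) -> tuple[np.ndarray, float]:
    """Superimpose ``mobile`` onto ``target`` after centering and unit-CS scaling.

    Returns (rotation, residual_distance): the 3x3 orthogonal matrix applied on
    the right of the centered unit-size mobile shape (det = +1 when reflections
    are forbidden) and the Frobenius residual of the fit — i.e. the Procrustes
    distance between the two shapes.
    """
    a = _coords(mobile)
    b = _coords(target)
    if a.shape != b.shape:
        raise InvalidParameterError(
            f"landmark count mismatch: {a.shape} vs {b.shape}"
        )
    if np.isnan(a).any() or np.isnan(b).any():
        raise MissingLandmarkError("cannot superimpose configurations with missing landmarks")
    a_u, _ = _center_scale(a)
    b_u, _ = _center_scale(b)
    r = _optimal_rotation(a_u, b_u, allow_reflection)
    residual = float(np.linalg.norm(a_u @ r - b_u))
    return r, residual


def procrustes_distance(a, b, superimpose: bool = True, allow_reflection: bool = False) -> float:
    """Procrustes distance between two configurations.

    With ``superimpose=True`` (default) the shapes are centered, scaled to unit
    CS and optimally rotated before taking the Frobenius distance — the
    pairwise (partial) Procrustes distance. With ``superimpose=False`` the raw
    coordinate difference is used; appropriate for coordinates already in a
    common GPA frame.
    """
    a = _coords(a)
    b = _coords(b)
    if a.shape != b.shape:
        raise InvalidParameterError("shape mismatch in procrustes_distance")
    if superimpose:
        _, d = align_pair(a, b, allow_reflection=allow_reflection)
        return d
    return float(np.linalg.norm(a - b))


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized Procrustes analysis of a set of landmark configurations.

    Every configuration is translated to the origin, scaled to unit centroid
    size, and iteratively rotated to the current consensus until the
    root-mean-square distance to the consensus stabilises.

    Parameters
    ----------
    tol : float
        Convergence threshold on the change of RMS distance to consensus.
    max_iter : int
        Maximum alignment sweeps; non-convergence is flagged, not raised.
    allow_reflection : bool
        Permit improper rotations in the superimposition (off for anatomy).

    Fitted attributes
    -----------------
    consensus_ : (k, 3) unit-CS mean shape.
    aligned_ : (n, k, 3) Procrustes coordinates.
    centroid_sizes_ : (n,) pre-scaling centroid sizes in mm.
    n_iter_, converged_ : iteration count and convergence flag.
    distance_matrix_ : (n, n) pairwise distances between aligned coordinates.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, allow_reflection: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.allow_reflection = allow_reflection

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise InvalidParameterError("X must be (n, k, 3)")
            if np.isnan(arr).any():
                raise MissingLandmarkError(
                    "missing landmarks in GPA input; estimate them first"
                )
        else:
            arr = as_coords_array(list(X), require_complete=True)
        if arr.shape[0] < 2:
            raise InvalidParameterError("GPA needs at least 2 configurations")
        return arr

    def fit(self, X, y=None):
        arr = self._validate(X)
        n = arr.shape[0]
        shapes = np.empty_like(arr)
        sizes = np.empty(n)
        for i in range(n):
            shapes[i], sizes[i] = _center_scale(arr[i])

        # initial registration to the first configuration
        for i in range(n):
            r = _optimal_rotation(shapes[i], shapes[0], self.allow_reflection)
            shapes[i] = shapes[i] @ r

        consensus = self._renorm(shapes.mean(axis=0))
        prev_rms = np.inf
        converged = False
        n_iter = 0
        ss_history: list[float] = []
        for n_iter in range(1, self.max_iter + 1):
            for i in range(n):
                r = _optimal_rotation(shapes[i], consensus, self.allow_reflection)
                shapes[i] = shapes[i] @ r
            consensus = self._renorm(shapes.mean(axis=0))
            ss = float(np.sum((shapes - consensus) ** 2))
            ss_history.append(ss)
            rms = float(np.sqrt(ss / n))
            if abs(prev_rms - rms) < self.tol:
                converged = True
                break
            prev_rms = rms
        self.ss_history_ = ss_history

        self.consensus_ = consensus
        self.aligned_ = shapes
        self.centroid_sizes_ = sizes
        self.n_iter_ = n_iter
        self.converged_ = converged
        flat = shapes.reshape(n, -1)
        diff = flat[:, None, :] - flat[None, :, :]
        self.distance_matrix_ = np.sqrt(np.sum(diff**2, axis=2))
        return self

    @staticmethod
    def _renorm(shape: np.ndarray) -> np.ndarray:
        shape = shape - shape.mean(axis=0)
        return shape / np.sqrt(np.sum(shape**2))

    def transform(self, X) -> np.ndarray:
        """Align new configurations to the fitted consensus (unit-CS frame)."""
        if not hasattr(self, "consensus_"):
            raise InvalidParameterError("GeneralizedProcrustes is not fitted")
        arr = self._validate(X)
        out = np.empty_like(arr)
        for i in range(arr.shape[0]):
            s, _ = _center_scale(arr[i])
            r = _optimal_rotation(s, self.consensus_, self.allow_reflection)
            out[i] = s @ r
        return out


@dataclass
class GPAResult:
    """Output bundle of a generalized Procrustes analysis."""

    consensus: np.ndarray  # (k, 3), unit CS
    aligned: np.ndarray  # (n, k, 3)
    centroid_sizes: np.ndarray  # (n,), mm
    iterations: int
    converged: bool
    distance_matrix: np.ndarray  # (n, n)
    configs: tuple[LandmarkConfiguration, ...] = ()  # metadata carriers, if given

    @property
    def n_configurations(self) -> int:
        return self.aligned.shape[0]

    def aligned_config(self, i: int) -> LandmarkConfiguration:
        """Aligned coordinates of configuration i with its original metadata."""
        if not self.configs:
            raise InvalidParameterError("GPAResult carries no configuration metadata")
        return self.configs[i].with_coords(self.aligned[i])


def gpa(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> GPAResult:
    """Run GPA over configurations; thin wrapper over GeneralizedProcrustes."""
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter, allow_reflection=allow_reflection)
    est.fit(configs)
    meta = tuple(configs) if not isinstance(configs, np.ndarray) else ()
    return GPAResult(
        consensus=est.consensus_,
        aligned=est.aligned_,
        centroid_sizes=est.centroid_sizes_,
        iterations=est.n_iter_,
        converged=est.converged_,
        distance_matrix=est.distance_matrix_,
        configs=meta,
    )
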