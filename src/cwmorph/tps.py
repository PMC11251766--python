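"""Thin-plate splines: solving, missing-landmark estimation, mesh warping.

Uses the classical 3D interpolating spline with kernel U(r) = r, a full 3D
affine part, and side conditions making the non-affine weights orthogonal to
the affine null space — the behaviour class of mainstream geometric-
morphometrics software. The dense (k + 4) x (k + 4) system is solved directly
(k = 89 by default, no approximation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import LandmarkConfiguration
from .errors import InvalidParameterError, MissingLandmarkError

__all__ = [
    "ThinPlateSpline",
    "TPSMap",
    "solve_tps",
    "estimate_missing",
    "warp_mesh",
]


class ThinPlateSpline(BaseEstimator):
    """Interpolating 3D thin-plate spline  f(x) = c + A x + sum_i w_i U(|x - s_i|).

    fit(source, target) solves the interpolation problem; transform(points)
    evaluates the fitted map. Exact at control points by construction.

    Fitted attributes
    -----------------
    source_ : (k, 3) control points.
    affine_ : (3, 3) linear part A; translation_ : (3,) offset c.
    weights_ : (k, 3) non-affine kernel coefficients.
    bending_energy_ : scalar >= 0, zero iff the map is affine.
    """

    #: condition-number threshold above which a coplanarity warning is issued
    _COND_WARN = 1e12

    def fit(self, source, target):
        s = np.asarray(source, dtype=float)
        t = np.asarray(target, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape != t.shape:
            raise InvalidParameterError("source and target must both be (k, 3)")
        k = s.shape[0]
        if k < 5:
            raise InvalidParameterError("TPS needs at least 5 control points")
        d = np.linalg.norm(s[:, None, :] - s[None, :, :], axis=2)
        off = d[~np.eye(k, dtype=bool)]
        if np.any(off == 0.0):
            raise InvalidParameterError("duplicate source points: singular TPS system")

        kmat = d  # U(r) = r
        p = np.hstack([np.ones((k, 1)), s])
        lmat = np.zeros((k + 4, k + 4))
        lmat[:k, :k] = kmat
        lmat[:k, k:] = p
        lmat[k:, :k] = p.T
        cond = np.linalg.cond(lmat)
        rhs = np.zeros((k + 4, 3))
        rhs[:k] = t
        if cond > self._COND_WARN:
            warnings.warn(
                f"TPS system ill-conditioned (cond={cond:.2e}); source landmarks "
                "may be (near-)coplanar", RuntimeWarning, stacklevel=2,
            )
            # degenerate affine null space: minimum-norm least-squares solve
            sol = np.linalg.lstsq(lmat, rhs, rcond=None)[0]
        else:
            sol = np.linalg.solve(lmat, rhs)
        w = sol[:k]
        self.source_ = s
        self.weights_ = w
        self.translation_ = sol[k]
        self.affine_ = sol[k + 1:].T  # (3, 3), applied as A @ x
        # quadratic form of the non-affine part; |.| guards the kernel's sign
        # convention (U = r is conditionally definite on the constrained space)
        self.bending_energy_ = float(abs(np.einsum("ic,ij,jc->", w, kmat, w)))
        return self

    def transform(self, points) -> np.ndarray:
        if not hasattr(self, "source_"):
            raise InvalidParameterError("ThinPlateSpline is not fitted")
        x = np.asarray(points, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        u = np.linalg.norm(x[:, None, :] - self.source_[None, :, :], axis=2)
        out = self.translation_ + x @ self.affine_.T + u @ self.weights_
        return out[0] if single else out


@dataclass
class TPSMap:
    """Solved thin-plate-spline map between two landmark sets."""

    source_landmarks: np.ndarray
    affine: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    weights: np.ndarray  # (k, 3)
    bending_energy: float
    _est: ThinPlateSpline = None

    def __call__(self, points) -> np.ndarray:
        return self._est.transform(points)


def solve_tps(source, target) -> TPSMap:
    """Solve the interpolating TPS mapping source landmarks onto target ones."""
    est = ThinPlateSpline().fit(source, target)
    return TPSMap(
        source_landmarks=est.source_,
        affine=est.affine_,
        translation=est.translation_,
        weights=est.weights_,
        bending_energy=est.bending_energy_,
        _est=est,
    )


def estimate_missing(
    config: LandmarkConfiguration,
    reference: LandmarkConfiguration,
    max_missing_frac: float = 0.2,
) -> LandmarkConfiguration:
    """Fill missing landmarks by TPS interpolation from a complete reference.

    A TPS is solved from the reference to the incomplete configuration over
    the shared (present) landmarks; missing positions are read off by mapping
    the reference's corresponding landmarks through it. Present landmarks are
    returned untouched. The reference should be shape-wise close (the
    consensus of the subject's complete configurations, else of the cohort).
    """
    if config.marker_ids != reference.marker_ids:
        raise InvalidParameterError("config and reference marker sets differ")
    if not reference.is_complete:
        raise MissingLandmarkError("reference configuration must be complete")
    miss = config.missing
    if not miss.any():
        return config
    frac = miss.mean()
    if frac > max_missing_frac:
        raise MissingLandmarkError(
            f"{miss.sum()} of {config.n_landmarks} landmarks missing "
            f"({frac:.0%} > max_missing_frac {max_missing_frac:.0%}); refusing to estimate"
        )
    present = ~miss
    if present.sum() < 5:
        raise MissingLandmarkError("fewer than 5 shared landmarks for TPS estimation")
    tps = ThinPlateSpline().fit(reference.coords[present], config.coords[present])
    coords = config.coords.copy()
    coords[miss] = tps.transform(reference.coords[miss])
    return config.with_coords(coords)


def warp_mesh(mesh, source_lms, target_lms):
    """Warp a surface mesh through the TPS defined by two landmark sets.

    ``mesh`` is a trimesh.Trimesh (or any object with ``vertices`` and
    ``faces``); returns a new trimesh.Trimesh with every vertex mapped through
    the spline and faces unchanged.
    """
    import trimesh

    est = ThinPlateSpline().fit(np.asarray(source_lms, float), np.asarray(target_lms, float))
    vertices = est.transform(np.asarray(mesh.vertices, dtype=float))
    return trimesh.Trimesh(vertices=vertices, faces=np.asarray(mesh.faces), process=False)
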