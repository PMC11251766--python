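"""Shape-space PCA, functional size/shape metrics and respiratory vectors.

PCA is an eigendecomposition of the variance-covariance matrix of the
mean-centered, flattened Procrustes coordinates (Kendall shape space, no
tangent projection beyond mean-centering — variation in breathing data is
small). The bespoke per-subject metrics are

* functional size  FS  = mean CS(IN) - mean CS(EX)  [mm], the net size change
  of one breath, computed on pre-scaling centroid sizes;
* functional shape FSh = Procrustes distance between the mean IN and mean EX
  shapes [dimensionless], the net shape change of one breath.

Respiratory vectors are per-condition means over subjects of the EX -> IN
PC-score displacement in a chosen PC subspace (PC1-PC2 by default).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidParameterError
from .procrustes import GPAResult, procrustes_distance

__all__ = [
    "ShapePCA",
    "PCAResult",
    "pca",
    "functional_size",
    "functional_shape",
    "functional_metrics",
    "respiratory_vectors",
    "shape_at_scores",
]


class ShapePCA(BaseEstimator, TransformerMixin):
    """PCA of Procrustes-aligned landmark coordinates.

    fit(X) with X of shape (n, k, 3); scores are obtained with transform.
    Components carry a deterministic sign: the largest-magnitude loading entry
    of each PC is positive, so score medians are comparable across runs.

    Fitted attributes
    -----------------
    mean_shape_ : (k, 3) centering shape.
    eigenvalues_ : descending, >= 0 (covariance eigenvalues).
    variance_fraction_ : eigenvalues / total variance.
    components_ : (m, 3k) orthonormal loadings.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise InvalidParameterError("X must be (n, k, 3) aligned coordinates")
        n, k, _ = arr.shape
        if n < 3:
            raise InvalidParameterError("shape PCA needs at least 3 configurations")
        flat = arr.reshape(n, 3 * k)
        mean = flat.mean(axis=0)
        centered = flat - mean
        # SVD route: numerically stable eigendecomposition of centered'centered/(n-1)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigvals = s**2 / (n - 1)
        m = min(n - 1, 3 * k) if self.n_components is None else self.n_components
        if m > vt.shape[0]:
            raise InvalidParameterError("n_components exceeds available rank")
        eigvals, vt = eigvals[:m], vt[:m]
        # deterministic sign: largest-|.| entry of each loading made positive
        for i in range(vt.shape[0]):
            j = np.argmax(np.abs(vt[i]))
            if vt[i, j] < 0:
                vt[i] = -vt[i]
        self.mean_shape_ = mean.reshape(k, 3)
        self.eigenvalues_ = eigvals
        self.total_variance_ = float(np.sum(centered**2) / (n - 1))
        self.variance_fraction_ = (
            eigvals / self.total_variance_ if self.total_variance_ > 0 else eigvals * 0.0
        )
        self.components_ = vt
        return self

    def transform(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        flat = arr.reshape(arr.shape[0], -1) - self.mean_shape_.ravel()
        scores = flat @ self.components_.T
        return scores[0] if single else scores

    def inverse_transform(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        single = s.ndim == 1
        s = np.atleast_2d(s)
        if s.shape[1] > self.components_.shape[0]:
            raise InvalidParameterError(
                f"{s.shape[1]} score dimensions but only "
                f"{self.components_.shape[0]} PCs available"
            )
        flat = self.mean_shape_.ravel() + s @ self.components_[: s.shape[1]]
        out = flat.reshape(s.shape[0], *self.mean_shape_.shape)
        return out[0] if single else out


@dataclass
class PCAResult:
    """Shape PCA with per-configuration scores and their metadata."""

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    scores: pd.DataFrame  # metadata columns + PC1..PCm
    loadings: np.ndarray  # (m, 3k)
    mean_shape: np.ndarray  # (k, 3)
    estimator: ShapePCA

    def score_columns(self, n: int | None = None) -> list[str]:
        cols = [c for c in self.scores.columns if c.startswith("PC")]
        return cols if n is None else cols[:n]


_META_FIELDS = ("subject_id", "condition", "instant", "cycle_index", "posture")


def _metadata_frame(gpa: GPAResult) -> pd.DataFrame:
    if gpa.configs:
        rows = [{f: getattr(c, f) for f in _META_FIELDS} for c in gpa.configs]
    else:
        rows = [{f: None for f in _META_FIELDS} for _ in range(gpa.n_configurations)]
    df = pd.DataFrame(rows)
    df["centroid_size"] = gpa.centroid_sizes
    return df


def pca(gpa: GPAResult, n_components: int | None = None) -> PCAResult:
    """PCA over the covariance of a GPA's Procrustes coordinates."""
    est = ShapePCA(n_components=n_components).fit(gpa.aligned)
    scores = est.transform(gpa.aligned)
    df = pd.concat(
        [_metadata_frame(gpa),
         pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])])],
        axis=1,
    )
    return PCAResult(
        eigenvalues=est.eigenvalues_,
        variance_fraction=est.variance_fraction_,
        scores=df,
        loadings=est.components_,
        mean_shape=est.mean_shape_,
        estimator=est,
    )


def _instant_means(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """Mean of a value over cycles, per subject x condition x instant."""
    return (
        df.groupby(["subject_id", "condition", "instant"], sort=True)[value]
        .mean()
        .unstack("instant")
    )


def functional_size(gpa: GPAResult) -> pd.DataFrame:
    """Functional size per subject x condition: mean CS(IN) - mean CS(EX), mm.

    Uses the pre-scaling centroid sizes recorded by the GPA, so the value is
    identical whether computed before or after superimposition. Subjects with
    a missing instant get NaN.
    """
    meta = _metadata_frame(gpa)
    if meta["subject_id"].isna().any():
        raise InvalidParameterError("GPA carries no configuration metadata")
    wide = _instant_means(meta, "centroid_size")
    for instant in ("EX", "IN"):
        if instant not in wide:
            wide[instant] = np.nan
    fs = (wide["IN"] - wide["EX"]).rename("FS")
    return fs.reset_index()


def functional_shape(gpa: GPAResult, method: str = "pairwise") -> pd.DataFrame:
    """Functional shape per subject x condition: Procrustes distance IN vs EX.

    ``method="pairwise"`` (default) re-superimposes the GPA-aligned mean IN
    and mean EX shapes optimally before taking the distance — the per-subject
    IN-EX Procrustes distance independent of the consensus frame.
    ``method="gpa_frame"`` takes the plain Euclidean distance between the mean
    aligned coordinates as they sit in the common GPA frame.
    """
    if method not in ("pairwise", "gpa_frame"):
        raise InvalidParameterError(f"unknown FSh method {method!r}")
    if not gpa.configs:
        raise InvalidParameterError("GPA carries no configuration metadata")
    meta = _metadata_frame(gpa)
    rows = []
    for (sid, cond), group in meta.groupby(["subject_id", "condition"], sort=True):
        shapes = {}
        for instant in ("EX", "IN"):
            idx = group.index[group["instant"] == instant]
            if len(idx) == 0:
                shapes[instant] = None
            else:
                shapes[instant] = gpa.aligned[idx].mean(axis=0)
        if shapes["EX"] is None or shapes["IN"] is None:
            fsh = np.nan
        elif np.allclose(shapes["EX"], shapes["IN"]):
            fsh = 0.0
        elif method == "pairwise":
            fsh = procrustes_distance(shapes["EX"], shapes["IN"], superimpose=True)
        else:
            fsh = float(np.linalg.norm(shapes["EX"] - shapes["IN"]))
        rows.append({"subject_id": sid, "condition": cond, "FSh": fsh})
    return pd.DataFrame(rows)


def functional_metrics(gpa: GPAResult, fsh_method: str = "pairwise") -> pd.DataFrame:
    """Combined FS/FSh table per subject x condition."""
    fs = functional_size(gpa)
    fsh = functional_shape(gpa, method=fsh_method)
    return fs.merge(fsh, on=["subject_id", "condition"], how="outer")


def respiratory_vectors(pca_result: PCAResult, n_pcs: int = 2) -> pd.DataFrame:
    """Mean EX -> IN PC-score displacement per condition.

    Returns one row per condition with the vector components in the first
    ``n_pcs`` PCs and its norm (``module``). The vector is the mean over
    subjects of per-subject (mean IN score - mean EX score) differences.
    """
    cols = pca_result.score_columns(n_pcs)
    if len(cols) < n_pcs:
        raise InvalidParameterError(f"fewer than {n_pcs} PCs available")
    df = pca_result.scores
    rows = []
    for cond, group in df.groupby("condition", sort=True):
        per_subj = (
            group.groupby(["subject_id", "instant"], sort=True)[cols]
            .mean()
            .unstack("instant")
        )
        if per_subj.empty:
            raise InvalidParameterError(f"no scores for condition {cond!r}")
        diffs = []
        for pc in cols:
            block = per_subj[pc]
            if "IN" not in block or "EX" not in block:
                raise InvalidParameterError(f"condition {cond!r} lacks an instant")
            diffs.append((block["IN"] - block["EX"]).mean())
        vec = np.asarray(diffs)
        rows.append({"condition": cond, **{pc: v for pc, v in zip(cols, vec)},
                     "module": float(np.linalg.norm(vec))})
    return pd.DataFrame(rows)


def shape_at_scores(pca_result: PCAResult, scores) -> np.ndarray:
    """Theoretical (k, 3) shape at given PC scores: mean + sum score_i * PC_i."""
    return pca_result.estimator.inverse_transform(np.asarray(scores, dtype=float))
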