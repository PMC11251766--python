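"""Paired Wilcoxon signed-rank testing and the H1-H3 hypothesis battery.

All hypotheses are paired within-subject contrasts tested two-sided with the
Wilcoxon signed-rank test (zero differences dropped, ties mid-ranked; exact
null distribution when the number of non-zero pairs is <= 25 and there are no
ties among absolute differences, normal approximation with continuity and tie
corrections otherwise).

The battery, run separately per posture group to keep posture out of the
contrasts:

* H1_size  — CS(IN) vs CS(EX) within each breathing condition;
* H2_size  — FS(QB) vs FS(REC);
* H3_size  — CS at matched instants (EX, IN) across conditions;
* H1_shape — PC1/PC2 scores of IN vs EX within each condition;
* H2_shape — FSh(QB) vs FSh(REC);
* H3_shape — PC1/PC2 scores at matched instants across conditions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, InvalidParameterError

__all__ = ["TestReport", "wilcoxon_signed_rank", "run_hypotheses",
            "significance_stars", "reports_to_frame"]


@dataclass
class TestReport:
    """One paired Wilcoxon signed-rank comparison."""

    hypothesis: str  # H1_size ... H3_shape (or free label)
    group: str  # posture: SIT | STA
    contrast: str  # human-readable description of the pairing
    n_pairs: int  # pairs entering the test (zero differences removed)
    statistic: float  # W (sum of positive-difference ranks)
    p_value: float
    direction: str  # sign of the median difference x - y: "+", "-" or "0"
    method: str  # exact | approx

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """*** < 0.001, ** < 0.01, * < 0.05, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def wilcoxon_signed_rank(
    x, y, method: str = "auto", hypothesis: str = "", group: str = "", contrast: str = ""
) -> TestReport:
    """Two-sided paired Wilcoxon signed-rank test of x vs y.

    ``method`` is ``exact``, ``approx`` or ``auto`` (exact when the number of
    non-zero differences is <= 25 and their absolute values are untied).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1-D samples")
    if len(x) < 1:
        raise InvalidParameterError("need at least one pair")
    d = x - y
    d = d[d != 0.0]  # Wilcoxon zero-drop convention
    m = len(d)
    if m == 0:
        raise DegenerateSampleError("all paired differences are zero")
    if method == "auto":
        untied = len(np.unique(np.abs(d))) == m
        method = "exact" if (m <= 25 and untied) else "approx"
    if method == "exact":
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="exact")
    elif method == "approx":
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="approx", correction=True)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())  # W = sum of positive-difference ranks
    med = np.median(d)
    direction = "+" if med > 0 else ("-" if med < 0 else "0")
    return TestReport(
        hypothesis=hypothesis, group=group, contrast=contrast, n_pairs=m,
        statistic=w_plus, p_value=float(res.pvalue),
        direction=direction, method=method,
    )


def _paired(frame: pd.DataFrame, value: str, index: list[str], column: str,
            a: str, b: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Within-subject pairing of `value` across two levels of `column`.

    Subjects missing either cell are dropped pairwise; returns (x, y, dropped).
    """
    wide = frame.pivot_table(index=index, columns=column, values=value,
                             aggfunc="mean")
    for lvl in (a, b):
        if lvl not in wide:
            wide[lvl] = np.nan
    ok = wide[[a, b]].dropna()
    return ok[a].to_numpy(), ok[b].to_numpy(), len(wide) - len(ok)


def run_hypotheses(
    cs_table: pd.DataFrame,
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    posture: str,
    n_pcs: int = 2,
    method: str = "auto",
    holm: bool = False,
    on_degenerate: str = "report",
) -> list[TestReport]:
    """Run the H1-H3 size and shape battery for one posture group.

    Parameters
    ----------
    cs_table : per-configuration table with columns subject_id, condition,
        instant, centroid_size (cycles averaged internally).
    metrics : FS/FSh table (subject_id, condition, FS, FSh).
    scores : PC-score table (subject_id, condition, instant, PC1..).
    posture : group label recorded in the reports.
    n_pcs : number of leading PCs entering the shape contrasts.
    method : Wilcoxon p-value method (auto | exact | approx).
    holm : apply a Holm step-down correction across the battery (off by
        default, matching the uncorrected presentation of the battery).
    on_degenerate : "report" records a degenerate contrast with NaN p and the
        run continues; "raise" propagates the error.

    Returns the reports in battery order.
    """
    reports: list[TestReport] = []
    pcs = [f"PC{i + 1}" for i in range(n_pcs)]

    def attempt(hyp: str, contrast: str, x, y):
        try:
            reports.append(wilcoxon_signed_rank(
                x, y, method=method, hypothesis=hyp, group=posture, contrast=contrast
            ))
        except DegenerateSampleError:
            if on_degenerate == "raise":
                raise
            reports.append(TestReport(
                hypothesis=hyp, group=posture, contrast=contrast,
                n_pairs=0, statistic=np.nan, p_value=np.nan,
                direction="0", method="degenerate",
            ))

    # --- size ---
    for cond in ("QB", "REC"):
        sub = cs_table[cs_table["condition"] == cond]
        x, y, _ = _paired(sub, "centroid_size", ["subject_id"], "instant", "IN", "EX")
        attempt("H1_size", f"CS IN vs EX | {cond}", x, y)
    x, y, _ = _paired(metrics, "FS", ["subject_id"], "condition", "QB", "REC")
    attempt("H2_size", "FS QB vs REC", x, y)
    for instant in ("EX", "IN"):
        sub = cs_table[cs_table["instant"] == instant]
        x, y, _ = _paired(sub, "centroid_size", ["subject_id"], "condition", "QB", "REC")
        attempt("H3_size", f"CS QB vs REC | {instant}", x, y)

    # --- shape ---
    for cond in ("QB", "REC"):
        sub = scores[scores["condition"] == cond]
        for pc in pcs:
            x, y, _ = _paired(sub, pc, ["subject_id"], "instant", "IN", "EX")
            attempt("H1_shape", f"{pc} IN vs EX | {cond}", x, y)
    x, y, _ = _paired(metrics, "FSh", ["subject_id"], "condition", "QB", "REC")
    attempt("H2_shape", "FSh QB vs REC", x, y)
    for instant in ("EX", "IN"):
        sub = scores[scores["instant"] == instant]
        for pc in pcs:
            x, y, _ = _paired(sub, pc, ["subject_id"], "condition", "QB", "REC")
            attempt("H3_shape", f"{pc} QB vs REC | {instant}", x, y)

    if holm:
        _holm_adjust(reports)
    return reports


def _holm_adjust(reports: list[TestReport]) -> None:
    """In-place Holm step-down adjustment of the battery p-values."""
    idx = [i for i, r in enumerate(reports) if np.isfinite(r.p_value)]
    ps = np.array([reports[i].p_value for i in idx])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, oi in enumerate(order):
        running = max(running, (m - rank) * ps[oi])
        adj[oi] = min(1.0, running)
    for i, a in zip(idx, adj):
        reports[i].p_value = float(a)


def reports_to_frame(reports: list[TestReport]) -> pd.DataFrame:
    """Tidy DataFrame of a report list, with significance stars."""
    df = pd.DataFrame([r.__dict__ for r in reports])
    df["stars"] = [r.stars for r in reports]
    return df
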