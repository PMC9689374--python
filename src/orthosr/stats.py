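"""Paired one-sided Wilcoxon signed-rank comparisons with Bonferroni.

Model/plane/ROI conditions are compared case-by-case: for each ordered
pair the null "row is not better than column" is tested one-sided on
the paired per-case scores. For 22 test cases the smallest attainable
exact p-value (all differences positive, no ties) is 1/2²² ≈ 2.38e-7.
The family-wise level is Bonferroni-corrected: 78 pairwise comparisons
among the 13 plane conditions give a 6.41e-4 threshold at α = 0.05,
and the 45 admissible ROI comparisons give 1.11e-3.

The exact null distribution is computed by convolution over sign
assignments, with zeros dropped and midranks for ties; scipy's
implementation serves as an independent cross-check in the tests but
cannot be the implementation here because its exact method does not
admit ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ComparisonMatrix",
    "wilcoxon_one_sided",
    "bonferroni_threshold",
    "comparison_matrix",
    "plane_conditions",
    "roi_conditions",
]

EXACT_N_MAX = 25


def _exact_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under random signs, for the given |d| ranks.

    Midranks are multiples of 1/2, so doubling them gives integers and
    the distribution of 2·W+ follows from the polynomial product of
    (1 + z^{2r_i}) over observations.
    """
    scaled = np.round(2 * ranks).astype(int)
    counts = np.zeros(scaled.sum() + 1)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    target = int(np.ceil(np.round(2 * w_obs, 8)))
    return float(counts[target:].sum() / counts.sum())


def wilcoxon_one_sided(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided signed-rank p-value for the alternative "x exceeds y".

    Zero differences are dropped before ranking; tied magnitudes get
    midranks. The null distribution is exact for up to 25 non-zero
    differences and a tie-corrected normal approximation with
    continuity correction beyond that. All-zero differences are a
    degenerate case reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        return _exact_sf(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(norm.sf(z))


def bonferroni_threshold(n_comparisons: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / n_comparisons``."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_comparisons


def plane_conditions(models: tuple[str, ...], planes: tuple[str, ...]) -> list[str]:
    """LR plus every model×plane condition label."""
    return ["LR"] + [f"{m}-{p}" for m in models for p in planes]


def roi_conditions(methods: tuple[str, ...], rois: tuple[str, ...]) -> list[str]:
    """Every method×ROI condition label (LR included in ``methods``)."""
    return [f"{m}|{r}" for m in methods for r in rois]


def _roi_pair_admissible(a: str, b: str) -> bool:
    ma, ra = a.split("|")
    mb, rb = b.split("|")
    return ma == mb or ra == rb


@dataclass
class ComparisonMatrix:
    """Upper-triangular one-sided p-values between ordered conditions.

    ``p[i, j]`` (i < j) tests the alternative "condition i exceeds
    condition j"; pairs excluded by the comparison rule hold NaN.
    """

    conditions: list[str]
    p: np.ndarray
    threshold: float
    n_comparisons: int
    alpha: float = 0.05

    def p_value(self, row: str, col: str) -> float:
        i = self.conditions.index(row)
        j = self.conditions.index(col)
        if i >= j:
            raise KeyError(f"cell ({row}, {col}) is not in the upper triangle")
        return float(self.p[i, j])

    def significant(self, row: str, col: str) -> bool:
        return self.p_value(row, col) < self.threshold


def comparison_matrix(
    values: dict[str, np.ndarray],
    conditions: list[str] | None = None,
    mode: str = "plane",
    alpha: float = 0.05,
) -> ComparisonMatrix:
    """All admissible pairwise one-sided comparisons between conditions.

    ``values`` maps each condition label to its per-case scores (every
    condition must cover every case, in the same order). In ``plane``
    mode every unordered pair is evaluated; in ``roi`` mode (labels
    ``method|roi``) only pairs sharing the method or sharing the ROI
    are evaluated — comparing different methods on different ROIs has
    no practical meaning. The threshold is ``alpha`` divided by the
    number of evaluated pairs.
    """
    conditions = list(conditions) if conditions is not None else list(values)
    lengths = {c: len(values[c]) for c in conditions}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"conditions have unequal case counts: {lengths}")
    m = len(conditions)
    p = np.full((m, m), np.nan)
    n_pairs = 0
    for i, j in combinations(range(m), 2):
        a, b = conditions[i], conditions[j]
        if mode == "roi" and not _roi_pair_admissible(a, b):
            continue
        p[i, j] = wilcoxon_one_sided(values[a], values[b])
        n_pairs += 1
    return ComparisonMatrix(
        conditions=conditions,
        p=p,
        threshold=bonferroni_threshold(n_pairs, alpha),
        n_comparisons=n_pairs,
        alpha=alpha,
    )
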