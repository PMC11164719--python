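"""Rank-based group comparisons and rater-agreement statistics.

Quality metrics such as FIPP and the exposure ratios are far from normal, so
group comparisons use the Kruskal–Wallis ANOVA by ranks (tie-corrected H,
chi-square reference with k−1 df) followed by pairwise Wilcoxon rank-sum
tests with a Bonferroni correction.  Pairwise p-values are exact (full
enumeration) for small tie-free samples and otherwise use the normal
approximation with a 0.5 continuity correction.

Repeatability of the ordinal quality scoring is measured with quadratically
weighted Cohen's kappa; repeatability of cropped-face pixel totals with the
two-way mixed, single-measures, consistency-form intraclass correlation
ICC(3,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, InvalidInputError

__all__ = [
    "RankTestResult",
    "AgreementResult",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "bonferroni",
    "weighted_kappa",
    "icc_3_1",
]


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_raw: float
    method: str
    df: Optional[int] = None
    p_adjusted: Optional[float] = None


@dataclass(frozen=True)
class AgreementResult:
    estimate: float
    p: Optional[float]
    n_items: int
    n_raters: int
    method: str
    f_statistic: Optional[float] = None
    df1: Optional[int] = None
    df2: Optional[int] = None
    degenerate: bool = False


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal–Wallis H over two or more groups of values.

    H is computed on mid-ranks with the tie correction
    1 − Σ(t³−t)/(N³−N); the p-value uses the chi-square distribution with
    k − 1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise InvalidInputError("every group must be non-empty")
    if sum(len(g) for g in groups) < 3:
        raise InvalidInputError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError(
            "all values identical: tie correction denominator is zero"
        )
    h, p = stats.kruskal(*groups)
    return RankTestResult(
        statistic=float(h),
        p_raw=float(p),
        df=len(groups) - 1,
        method="kruskal-wallis",
    )


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p, capped at 1."""
    if n_comparisons < 1:
        raise InvalidInputError("n_comparisons must be >= 1")
    return min(1.0, p_raw * n_comparisons)


def _wilcoxon_pair(
    x: np.ndarray, y: np.ndarray, exact_max_n: int
) -> Tuple[float, float, str]:
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not has_ties and max(len(x), len(y)) <= exact_max_n:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "wilcoxon-exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "wilcoxon-normal-cc"


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
    exact_max_n: int = 25,
) -> Dict[Tuple[str, str], RankTestResult]:
    """Two-sided Wilcoxon rank-sum tests for every pair of labelled groups.

    Exact enumeration is used when both groups have at most ``exact_max_n``
    observations and the pooled data are tie-free; otherwise the normal
    approximation with a 0.5 continuity correction.  Adjusted p-values are
    Bonferroni over the number of tested pairs.  Empty groups are skipped
    with a warning.
    """
    if adjust not in ("bonferroni", "none"):
        raise InvalidInputError(f"unknown adjustment {adjust!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrays = {}
    for lab in labels:
        arr = np.asarray(groups[lab], dtype=float)
        if len(arr) == 0:
            warnings.warn(f"group {lab!r} is empty; its pairs are skipped",
                          stacklevel=2)
            continue
        arrays[lab] = arr
    pairs = list(combinations(arrays, 2))
    if not pairs:
        raise InvalidInputError("fewer than 2 non-empty groups")
    n_pairs = len(pairs)
    out: Dict[Tuple[str, str], RankTestResult] = {}
    for a, b in pairs:
        statistic, p, method = _wilcoxon_pair(arrays[a], arrays[b], exact_max_n)
        p_adj = bonferroni(p, n_pairs) if adjust == "bonferroni" else p
        out[(a, b)] = RankTestResult(
            statistic=statistic, p_raw=p, p_adjusted=p_adj, method=method
        )
    return out


def _kappa_tables(
    a: np.ndarray, b: np.ndarray, categories: Sequence
) -> Tuple[np.ndarray, np.ndarray]:
    k = len(categories)
    index = {c: i for i, c in enumerate(categories)}
    observed = np.zeros((k, k))
    for ra, rb in zip(a, b):
        observed[index[ra], index[rb]] += 1
    observed /= len(a)
    idx = np.arange(k, dtype=float)
    if k == 1:
        weights = np.ones((1, 1))
    else:
        weights = 1.0 - ((idx[:, None] - idx[None, :]) / (k - 1)) ** 2
    return observed, weights


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    categories: Optional[Sequence] = None,
) -> AgreementResult:
    """Quadratically weighted Cohen's kappa between two raters.

    Agreement weights are w_ij = 1 − ((i−j)/(k−1))² over category positions;
    κ = (Σ w p_obs − Σ w p_exp) / (1 − Σ w p_exp) with p_exp the product of
    the marginals.  The p-value is the large-sample normal test of κ = 0
    (Fleiss–Cohen–Everitt variance under the null).  ``categories`` defaults
    to the sorted union of observed ratings; pass the full ordinal scale
    explicitly when some levels are unobserved.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("ratings must be equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise InvalidInputError("need at least 2 rated items")
    cats = list(categories) if categories is not None else sorted(
        set(a.tolist()) | set(b.tolist())
    )
    if categories is not None:
        outside = (set(a.tolist()) | set(b.tolist())) - set(cats)
        if outside:
            raise InvalidInputError(f"ratings outside categories: {sorted(outside)}")

    observed, weights = _kappa_tables(a, b, cats)
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    expected = np.outer(row, col)
    po = float((weights * observed).sum())
    pe = float((weights * expected).sum())
    if abs(1.0 - pe) < 1e-12:
        return AgreementResult(
            estimate=float("nan"), p=None, n_items=n, n_raters=2,
            method="weighted-kappa", degenerate=True,
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance of kappa under H0.
    wbar_i = weights @ col  # expected weight of row category i
    wbar_j = row @ weights  # expected weight of column category j
    term = weights - wbar_i[:, None] - wbar_j[None, :]
    var0 = (float((expected * term**2).sum()) - pe**2) / (n * (1.0 - pe) ** 2)
    if var0 <= 0:
        p = 0.0 if kappa != 0 else 1.0
    else:
        z = kappa / np.sqrt(var0)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AgreementResult(
        estimate=float(kappa), p=p, n_items=n, n_raters=2, method="weighted-kappa"
    )


def icc_3_1(table: Sequence[Sequence[float]]) -> AgreementResult:
    """Two-way mixed, single-measures, consistency ICC(3,1).

    ``table`` is items × raters, complete.  From the two-way ANOVA
    decomposition with mean squares BMS (between items) and EMS (residual):
    ICC(3,1) = (BMS − EMS) / (BMS + (k−1)·EMS); F = BMS/EMS with
    (n−1, (n−1)(k−1)) degrees of freedom.
    """
    data = np.asarray(table, dtype=float)
    if data.ndim != 2:
        raise InvalidInputError("table must be 2-D (items x raters)")
    n, k = data.shape
    if n < 2 or k < 2:
        raise InvalidInputError("need at least 2 items and 2 raters")
    if np.isnan(data).any():
        raise InvalidInputError("table must be complete (no missing cells)")

    grand = data.mean()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    df1, df2 = n - 1, (n - 1) * (k - 1)
    bms = ss_rows / df1
    ems = ss_err / df2

    denom = bms + (k - 1) * ems
    if denom <= 0:
        return AgreementResult(
            estimate=float("nan"), p=None, n_items=n, n_raters=k,
            method="icc(3,1)", df1=df1, df2=df2, degenerate=True,
        )
    icc = (bms - ems) / denom
    if ems == 0:
        f, p = float("inf"), 0.0
    else:
        f = bms / ems
        p = float(stats.f.sf(f, df1, df2))
    return AgreementResult(
        estimate=float(icc), p=p, n_items=n, n_raters=k,
        method="icc(3,1)", f_statistic=f, df1=df1, df2=df2,
    )
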