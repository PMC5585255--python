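"""Group-comparison statistics used across the assay analyses.

Four tests, matching how the experimental readouts are compared across
constructs (WT vs mutant, ± agonist): one-way ANOVA with Bonferroni-adjusted
pairwise t comparisons, Kruskal–Wallis with Dunn post hoc, the unpaired
Student t test (one- or two-tailed, pooled variance by default), and the
Mann–Whitney U test (exact for small samples).  Parametric machinery comes
from scipy; the Dunn post hoc is constructed from pooled mean ranks with a
tie-corrected pooled variance and Bonferroni multiplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    center: float  # mean (parametric) or median (rank-based)
    dispersion: float  # SD or IQR


@dataclass(frozen=True)
class GroupComparisonResult:
    test: str
    statistic: float | None
    p_value: float | None
    pairwise: tuple[PairwiseComparison, ...]
    groups: tuple[GroupSummary, ...]
    degenerate: bool = False
    note: str = ""


def _as_groups(groups, labels):
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    return arrs, list(labels)


def _requested_pairs(labels, pairs):
    if pairs is None:
        return list(itertools.combinations(range(len(labels)), 2))
    index = {lab: i for i, lab in enumerate(labels)}
    return [(index[a], index[b]) for a, b in pairs]


def anova_bonferroni(groups, pairs=None, labels=None) -> GroupComparisonResult:
    """One-way ANOVA plus Bonferroni-adjusted pairwise pooled-variance t tests.

    Identical constant groups give F = 0 with p = 1 by convention.
    """
    arrs, labels = _as_groups(groups, labels)
    if len(arrs) < 2:
        raise ConfigurationError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ConfigurationError("every group needs n ≥ 2")
    grand = np.concatenate(arrs)
    k, N = len(arrs), grand.size
    ssb = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    degenerate = False
    if ssw <= 1e-300:
        if ssb <= 1e-300:
            F, p = 0.0, 1.0
            degenerate = True
        else:
            F, p = float("inf"), 0.0
            degenerate = True
    else:
        F = (ssb / (k - 1)) / (ssw / (N - k))
        p = float(sps.f.sf(F, k - 1, N - k))

    idx_pairs = _requested_pairs(labels, pairs)
    m = len(idx_pairs)
    pw = []
    for i, j in idx_pairs:
        if np.ptp(arrs[i]) == 0 and np.ptp(arrs[j]) == 0:
            t_stat = 0.0
            p_raw = 1.0 if arrs[i].mean() == arrs[j].mean() else 0.0
        else:
            t_stat, p_raw = sps.ttest_ind(arrs[i], arrs[j], equal_var=True)
        pw.append(
            PairwiseComparison(
                (labels[i], labels[j]), float(t_stat), float(p_raw),
                min(1.0, float(p_raw) * m),
            )
        )
    summaries = tuple(
        GroupSummary(lab, a.size, float(a.mean()), float(a.std(ddof=1)))
        for lab, a in zip(labels, arrs)
    )
    return GroupComparisonResult("anova_bonferroni", float(F), float(p), tuple(pw),
                                 summaries, degenerate)


def kruskal_dunn(groups, pairs=None, labels=None) -> GroupComparisonResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn post hoc comparisons.

    Dunn z statistics are built from pooled mean ranks with the tie-corrected
    pooled variance and Bonferroni-multiplied two-sided normal p values.
    All-identical data give a degenerate result with no p value.
    """
    arrs, labels = _as_groups(groups, labels)
    if len(arrs) < 2:
        raise ConfigurationError("Kruskal–Wallis needs at least 2 groups")
    if any(a.size < 1 for a in arrs):
        raise ConfigurationError("every group needs n ≥ 1")
    pooled = np.concatenate(arrs)
    N = pooled.size
    if N < 5:
        raise ConfigurationError("Kruskal–Wallis needs total n ≥ 5")
    summaries = tuple(
        GroupSummary(lab, a.size, float(np.median(a)),
                     float(np.subtract(*np.percentile(a, [75, 25]))))
        for lab, a in zip(labels, arrs)
    )
    if np.ptp(pooled) == 0:
        return GroupComparisonResult("kruskal_dunn", None, None, (), summaries,
                                     degenerate=True, note="all observations identical")
    H, p = sps.kruskal(*arrs)

    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrs]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(arrs))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term

    idx_pairs = _requested_pairs(labels, pairs)
    m = len(idx_pairs)
    pw = []
    for i, j in idx_pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        pw.append(PairwiseComparison((labels[i], labels[j]), float(z),
                                     float(p_raw), min(1.0, float(p_raw) * m)))
    return GroupComparisonResult("kruskal_dunn", float(H), float(p), tuple(pw), summaries)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    tail: str  # "two-sided", "greater", "less"
    note: str = ""


def unpaired_t(a, b, one_tailed: bool = False, tail: str | None = None,
               equal_var: bool = True) -> TTestResult:
    """Unpaired Student t test, pooled variance by default.

    One-tailed direction defaults to the observed direction of
    mean(a) − mean(b) unless *tail* ("greater"/"less") is given.  Constant
    equal groups give t = 0 with p = 1 (two-sided) / 0.5 (one-tailed).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("t test needs n ≥ 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            if one_tailed:
                return TTestResult(0.0, 0.5, tail or "greater", "zero variance, equal means")
            return TTestResult(0.0, 1.0, "two-sided", "zero variance, equal means")
        direction = "greater" if a.mean() > b.mean() else "less"
        use_tail = tail or (direction if one_tailed else "two-sided")
        stat = float("inf") if a.mean() > b.mean() else float("-inf")
        return TTestResult(stat, 0.0, use_tail, "zero variance, unequal means")
    if one_tailed:
        if tail is None:
            tail = "greater" if a.mean() >= b.mean() else "less"
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=tail)
        return TTestResult(float(res.statistic), float(res.pvalue), tail)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue), "two-sided")


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    method: str  # "exact" | "asymptotic"


def mann_whitney(a, b, alternative: str = "two-sided") -> MannWhitneyResult:
    """Mann–Whitney U test.

    Exact enumeration when total n ≤ 12 and the data are tie-free; otherwise
    the tie-corrected normal approximation (with continuity correction).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ConfigurationError("Mann–Whitney needs n ≥ 1 per group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)
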