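"""Cohort statistics for lesion-metric tables.

The analysis pipeline mirrors standard small-cohort biostatistics practice:
a Shapiro–Wilk normality gate (which, for these skewed T2 metrics, directs
the analysis to nonparametric tests), Kruskal–Wallis omnibus comparisons
across tumour subtypes or grades with Dunn's post-hoc pairwise z tests under
Bonferroni correction, and High-res vs breath-hold protocol agreement via
Bland–Altman limits of agreement plus Spearman rank correlation.

Kruskal–Wallis H uses the standard tie correction.  Dunn's z for groups i, j
is

    z = (r̄_i − r̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) ),
    T = Σ(t³ − t) / (12(N − 1)),

with r̄ the mean pooled ranks and t the tie multiplicities; two-sided normal
p-values are multiplied by the number of comparisons (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "AgreementResult",
    "shapiro_wilk_gate",
    "kruskal_dunn",
    "spearman",
    "bland_altman_agreement",
    "grade_trend_summary",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparisonResult:
    h_statistic: float
    p_omnibus: float
    pairwise: tuple[PairwiseComparison, ...]
    n_per_group: dict[str, int]

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "z": c.z,
                    "p_unadjusted": c.p_unadjusted,
                    "p_adjusted": c.p_adjusted,
                }
                for c in self.pairwise
            ]
        )

    def pair(self, a: str, b: str) -> PairwiseComparison:
        for c in self.pairwise:
            if {c.group_a, c.group_b} == {a, b}:
                return c
        raise KeyError(f"no comparison between {a!r} and {b!r}")


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    spearman_r: float
    spearman_p: float
    n: int


def shapiro_wilk_gate(values) -> tuple[float, float, bool]:
    """Shapiro–Wilk W, p, and whether the sample passes normality at α=0.05.

    A False gate directs downstream comparisons to nonparametric tests.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(v)
    return float(w), float(p), bool(p >= ALPHA)


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_dunn(groups: dict[str, np.ndarray]) -> GroupComparisonResult:
    """Kruskal–Wallis omnibus + Dunn's Bonferroni-corrected pairwise tests."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")

    names = list(arrays)
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # average ranks on ties
    offsets = np.cumsum([0] + [arrays[k].size for k in names])
    mean_ranks = {
        k: ranks[offsets[i] : offsets[i + 1]].mean() for i, k in enumerate(names)
    }

    h, p_omni = sps.kruskal(*[arrays[k] for k in names])

    tie_sum = _tie_term(pooled)
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    pairs = []
    combos = list(combinations(names, 2))
    m = len(combos)
    for a, b in combos:
        se = np.sqrt(var_term * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_un = 2.0 * sps.norm.sf(abs(z))
        pairs.append(
            PairwiseComparison(a, b, float(z), float(p_un), float(min(1.0, p_un * m)))
        )
    return GroupComparisonResult(
        h_statistic=float(h),
        p_omnibus=float(p_omni),
        pairwise=tuple(pairs),
        n_per_group={k: int(arrays[k].size) for k in names},
    )


def _spearman_exact_p(ra: np.ndarray, rb: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n ≤ 9)."""
    n = ra.size
    da = ra - ra.mean()
    db = rb - rb.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(range(n)):
        r = np.sum(da * db[list(perm)]) / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(values_a, values_b) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    p-value by exact permutation for n ≤ 9, otherwise the t approximation —
    appropriate for cohort-scale n.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    da, db = ra - ra.mean(), rb - rb.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0:
        return 1.0 if np.sum(da * db) >= 0 else -1.0, 0.0
    rho = float(np.sum(da * db) / denom)
    n = a.size
    if n <= 9:
        p = _spearman_exact_p(ra, rb, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, float(p)


def bland_altman_agreement(values_a, values_b) -> AgreementResult:
    """Bland–Altman bias/limits of agreement plus Spearman correlation.

    Differences are a − b; limits of agreement are bias ± 1.96·SD (sample SD,
    ddof=1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rho, p = spearman(a, b)
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        spearman_r=rho,
        spearman_p=p,
        n=int(a.size),
    )


def grade_trend_summary(
    records: pd.DataFrame, metric: str = "median_t2_ms"
) -> tuple[pd.DataFrame, dict[str, GroupComparisonResult]]:
    """Per-grade medians and grade-wise Kruskal–Wallis/Dunn per protocol.

    Operates on the ccRCC rows of a lesion-record table; grades are ordered
    ascending.  Returns the tidy per-grade median table and one comparison
    result per protocol.
    """
    if metric not in records.columns:
        raise KeyError(f"metric {metric!r} absent from records")
    cc = records[records["who_isup_grade"].notna()]
    grades = sorted(cc["who_isup_grade"].unique())
    if len(grades) < 2:
        raise ValueError("need at least two WHO/ISUP grades")

    rows = []
    comparisons: dict[str, GroupComparisonResult] = {}
    for protocol, sub in cc.groupby("protocol"):
        groups = {}
        for g in grades:
            vals = sub.loc[sub["who_isup_grade"] == g, metric].to_numpy()
            rows.append(
                {
                    "protocol": protocol,
                    "who_isup_grade": int(g),
                    "metric": metric,
                    "median": float(np.median(vals)) if vals.size else np.nan,
                    "n": int(vals.size),
                }
            )
            if vals.size >= 2:
                groups[f"grade{int(g)}"] = vals
        if len(groups) >= 2:
            comparisons[str(protocol)] = kruskal_dunn(groups)
    return pd.DataFrame(rows), comparisons
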