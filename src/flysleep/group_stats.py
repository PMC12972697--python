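"""Nonparametric group statistics for sleep and ERG parameters.

The statistical recipe: a Kruskal–Wallis rank-sum screen when three or more
genotypes are compared, pairwise Wilcoxon rank-sum (Mann–Whitney) tests —
exact where feasible — with Benjamini–Hochberg correction applied across
the pairwise family of one parameter, and the rank-based effect size
r = |Z|/sqrt(n1 + n2) with significance-gated magnitude labels.

Because r is derived from the normal-approximation Z of the rank-sum
statistic, it is unaffected by the multiplicity correction: only the
p-values are adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
#: Effect-size magnitude cut-points: r < 0.3 small, 0.3 <= r < 0.5 moderate,
#: r >= 0.5 large (applied to the unrounded r, gated on adjusted p < 0.05).
R_MODERATE = 0.3
R_LARGE = 0.5

#: Largest pooled sample for which the exact rank-sum null is enumerated.
EXACT_MAX_N = 20


@dataclass
class GroupComparison:
    """One row of a pairwise-comparison statistics table."""

    parameter: str
    genotype_a: str
    genotype_b: str
    p_raw: float
    p_adj: float
    r: float
    n1: int
    n2: int
    magnitude: str  # one of "", "small", "moderate", "large"
    kw_h: float | None = None  # Kruskal-Wallis screen, shared across the family
    kw_p: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_adj < ALPHA


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(U, p, Z)`` where ``U`` is the Mann–Whitney statistic of the
    first sample.  The p-value is exact (full enumeration of the rank-sum
    null) when the pooled sample is small (<= 20) and tie-free; otherwise
    the tie- and continuity-corrected normal approximation is used.  ``Z``
    always comes from the tie-corrected normal approximation so the effect
    size r is defined even when p is exact.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < n

    method = "exact" if (n <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)

    # Tie-corrected normal approximation of U for Z (no continuity shift so
    # that identical samples give Z exactly 0).
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = 0.0 if sigma2 <= 0 else (u - mu) / math.sqrt(sigma2)
    return u, float(res.pvalue), z


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-based effect size r = |Z| / sqrt(n_total)."""
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    return abs(z) / math.sqrt(n_total)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p on (k - 1) df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def classify_magnitude(r: float, p_adj: float) -> str:
    """Significance-gated magnitude label for effect size r.

    Non-significant comparisons (adjusted p >= 0.05) get no label; otherwise
    small / moderate / large by the 0.3 and 0.5 cut-points on unrounded r.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    if p_adj >= ALPHA:
        return ""
    if r < R_MODERATE:
        return "small"
    if r < R_LARGE:
        return "moderate"
    return "large"


def _clean(values: Sequence[float]) -> np.ndarray:
    """Drop undefined entries (NaN) — e.g. waking activity of a fly that slept a full phase."""
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def compare_parameter(
    parameter: str,
    groups: Mapping[str, Sequence[float]],
    correct: bool | None = None,
) -> list[GroupComparison]:
    """All pairwise genotype comparisons for one parameter.

    With two genotypes the raw pairwise p is reported unadjusted and no
    Kruskal–Wallis screen is run.  With three or more, the Kruskal–Wallis
    test is computed over all groups and every pairwise Wilcoxon p is
    Benjamini–Hochberg adjusted as one family for this parameter.  ``correct``
    overrides that default.

    NaN values (undefined per-fly parameters) are dropped per group before
    testing; reported n1/n2 count the values actually tested.
    """
    cleaned = {g: _clean(v) for g, v in groups.items()}
    if len(cleaned) < 2:
        raise ValueError("need at least 2 genotypes")
    for name, vals in cleaned.items():
        if vals.size < 2:
            raise ValueError(
                f"genotype {name!r} has {vals.size} usable values for {parameter!r} (need >= 2)"
            )
    if correct is None:
        correct = len(cleaned) >= 3

    kw_h = kw_p = None
    if len(cleaned) >= 3:
        kw_h, kw_p = kruskal_wallis(*cleaned.values())

    pairs = list(combinations(cleaned.keys(), 2))
    raw_p: list[float] = []
    stats_rows: list[tuple[str, str, float, int, int]] = []
    for a, b in pairs:
        _, p, z = wilcoxon_rank_sum(cleaned[a], cleaned[b])
        n1, n2 = cleaned[a].size, cleaned[b].size
        raw_p.append(p)
        stats_rows.append((a, b, effect_size_r(z, n1 + n2), n1, n2))

    adj_p = bh_adjust(raw_p) if correct else np.asarray(raw_p)
    # BH can only raise p-values, but guard the invariant explicitly.
    adj_p = np.maximum(adj_p, raw_p)

    return [
        GroupComparison(
            parameter=parameter,
            genotype_a=a,
            genotype_b=b,
            p_raw=p,
            p_adj=float(pa),
            r=r,
            n1=n1,
            n2=n2,
            magnitude=classify_magnitude(r, float(pa)),
            kw_h=kw_h,
            kw_p=kw_p,
        )
        for (a, b, r, n1, n2), p, pa in zip(stats_rows, raw_p, adj_p)
    ]
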