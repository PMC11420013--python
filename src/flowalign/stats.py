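"""Nonparametric group comparisons for elongation and alignment data.

Two groups are compared by a two-tailed Mann-Whitney U test (exact
enumeration for small samples, tie-corrected normal approximation
otherwise); three or more groups by a tie-corrected Kruskal-Wallis test
with Dunn's pairwise post hoc z tests, Bonferroni-adjusted by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PosthocRow",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_groups",
    "significance_stars",
]

#: Sample-size bound below which the Mann-Whitney p-value is computed by
#: exact enumeration of rank arrangements (ties force the approximation).
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class PosthocRow:
    group_a: str
    group_b: str
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class StatResult:
    """Outcome of one group comparison."""

    method: str
    groups: list[str]
    statistic: float
    p_value: float
    posthoc: list[PosthocRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def significance_stars(p: float) -> str:
    """Four-tier star annotation: ``*`` p<0.05 ... ``****`` p<0.0001;
    ``ns`` otherwise."""
    for stars, cutoff in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cutoff:
            return stars
    return "ns"


def _as_groups(groups, names):
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ValueError("names and groups length mismatch")
    return arrays, [str(n) for n in names]


def mann_whitney_u(x, y, *, names: tuple[str, str] | None = None) -> StatResult:
    """Two-tailed Mann-Whitney U test.

    The p-value comes from exact enumeration when the pooled sample has at
    most 12 observations without ties, and from the tie-corrected normal
    approximation (with continuity correction) otherwise.  The reported U
    statistic is for the first sample.
    """
    (x, y), names = _as_groups([x, y], names)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # identical constant samples: zero rank variance, no evidence either way
        return StatResult(
            method="mann-whitney-u-degenerate",
            groups=list(names),
            statistic=float(x.size * y.size / 2.0),
            p_value=1.0,
        )
    has_ties = np.unique(pooled).size < pooled.size
    exact = pooled.size <= EXACT_MW_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    method = "mann-whitney-u-exact" if exact else "mann-whitney-u-normal"
    return StatResult(
        method=method,
        groups=list(names),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def kruskal_wallis(groups, *, names=None, warn_two_groups: bool = True) -> StatResult:
    """Tie-corrected Kruskal-Wallis H test, chi-squared p with k-1 df."""
    arrays, names = _as_groups(groups, names)
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if len(arrays) == 2 and warn_two_groups:
        import warnings

        warnings.warn(
            "Kruskal-Wallis on two groups; Mann-Whitney U is the usual choice",
            stacklevel=2,
        )
    if np.unique(np.concatenate(arrays)).size == 1:
        # scipy raises on all-identical data; H = 0, p = 1 is the limit
        return StatResult(
            method="kruskal-wallis", groups=names, statistic=0.0, p_value=1.0
        )
    res = sps.kruskal(*arrays)
    return StatResult(
        method="kruskal-wallis",
        groups=names,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def dunn_posthoc(
    groups, *, names=None, adjustment: str = "bonferroni"
) -> list[PosthocRow]:
    """Dunn's pairwise post hoc comparisons after Kruskal-Wallis.

    For groups i, j the statistic is
    ``z = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))``
    with pooled-rank means ``rbar`` and tie correction
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups of size ``t``.
    Adjustment: ``"bonferroni"`` (default, multiply by the number of
    pairs), ``"holm"``, or ``"none"``.
    """
    arrays, names = _as_groups(groups, names)
    if len(arrays) < 2:
        raise ValueError("dunn_posthoc requires at least two groups")
    if adjustment not in {"bonferroni", "holm", "none"}:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in arrays]
    bounds = np.cumsum([0] + sizes)
    rank_means = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0.0 else (rank_means[i] - rank_means[j]) / se
        zs.append(float(z))
        ps.append(float(2.0 * sps.norm.sf(abs(z))))

    m = len(pairs)
    if adjustment == "bonferroni":
        adj = [min(1.0, p * m) for p in ps]
    elif adjustment == "holm":
        order = np.argsort(ps)
        adj = [0.0] * m
        running = 0.0
        for rank_idx, k in enumerate(order):
            running = max(running, min(1.0, (m - rank_idx) * ps[k]))
            adj[k] = running
    else:
        adj = list(ps)

    return [
        PosthocRow(
            group_a=names[i],
            group_b=names[j],
            z=zs[k],
            p_unadjusted=ps[k],
            p_adjusted=adj[k],
        )
        for k, (i, j) in enumerate(pairs)
    ]


def compare_groups(
    groups, *, names=None, adjustment: str = "bonferroni"
) -> StatResult:
    """Dispatch to the study's convention: Mann-Whitney U for two groups,
    Kruskal-Wallis with Dunn's post hoc for three or more."""
    arrays, names = _as_groups(groups, names)
    if len(arrays) < 2:
        raise ValueError("need at least two groups to compare")
    if len(arrays) == 2:
        return mann_whitney_u(arrays[0], arrays[1], names=tuple(names))
    result = kruskal_wallis(arrays, names=names)
    result.posthoc = dunn_posthoc(arrays, names=names, adjustment=adjustment)
    return result
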