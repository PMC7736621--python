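"""Condition-comparison statistics tree.

Multiple-condition metrics (NS / ST / S) are compared with the classic
gated procedure: a per-group Kolmogorov-Smirnov normality check decides
between the parametric branch (one-way ANOVA followed by all-pairs
t-tests with Bonferroni correction) and the nonparametric branch
(Kruskal-Wallis followed by Dunn's all-pairs z-tests on mean ranks with
tie-corrected variance and Bonferroni-adjusted p).

The plain KS test with moments estimated from the sample is
anticonservative (it under-rejects); a Lilliefors-corrected switch is
provided.  Dunn's test is computed from the standard rank formulas:

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

with tie term T = sum(t^3 - t) over tied groups.

Significance stars follow the usual convention: * p < 0.05, ** p < 0.01,
*** p < 0.001, **** p < 0.0001 (on adjusted p-values).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "PairwiseComparison",
    "normality_gate",
    "compare_conditions",
    "dunn_all_pairs",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclasses.dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    stars: str


@dataclasses.dataclass
class StatsResult:
    metric: str
    branch: str  # "parametric" | "nonparametric"
    omnibus_name: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseComparison]
    gate_p: dict[str, float] = dataclasses.field(default_factory=dict)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [
            (c.group_a, c.group_b) for c in self.pairwise if c.p_adjusted < alpha
        ]


def normality_gate(
    groups: dict[str, np.ndarray], alpha: float = 0.05, lilliefors: bool = False
):
    """Per-group normality check; parametric iff no group rejects.

    Plain KS against a normal with the group's estimated mean/SD by
    default; ``lilliefors=True`` switches to the Lilliefors-corrected
    p-value (statsmodels), which accounts for the estimated parameters.
    Returns (branch, per-group p-values).
    """
    pvals = {}
    for name, x in groups.items():
        x = np.asarray(x, dtype=float)
        if len(x) < 3:
            raise ValueError(f"group {name!r} too small for the normality gate")
        sd = x.std(ddof=1)
        if sd == 0:
            pvals[name] = 0.0
            continue
        if lilliefors:
            from statsmodels.stats.diagnostic import lilliefors as _lf

            _, p = _lf(x, dist="norm")
        else:
            _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
        pvals[name] = float(p)
    branch = "parametric" if all(p > alpha for p in pvals.values()) else "nonparametric"
    return branch, pvals


def dunn_all_pairs(groups: dict[str, np.ndarray]):
    """Dunn's all-pairs post hoc on mean ranks, tie-corrected, raw p-values."""
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(v) for v in values]
    mean_ranks = {}
    start = 0
    for g, n in zip(names, sizes):
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    out = []
    for (ga, na), (gb, nb) in itertools.combinations(zip(names, sizes), 2):
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((ga, gb, float(z), float(p)))
    return out


def compare_conditions(
    groups: dict[str, np.ndarray],
    metric: str = "metric",
    branch: str | None = None,
    alpha: float = 0.05,
    equal_var: bool = False,
    lilliefors: bool = False,
) -> StatsResult:
    """Omnibus test plus Bonferroni-adjusted all-pairs post hocs.

    ``branch=None`` runs the normality gate first.  The parametric branch
    uses Welch t-tests by default (``equal_var=True`` for the classic
    pooled-variance Student test); the Bonferroni family is the set of all
    pairwise comparisons of the metric.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("zero variance: all observations identical")
    gate_p: dict[str, float] = {}
    if branch is None:
        branch, gate_p = normality_gate(groups, alpha=alpha, lilliefors=lilliefors)

    names = list(groups)
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = []
    if branch == "parametric":
        f, p = sps.f_oneway(*groups.values())
        omnibus = ("one-way ANOVA", float(f), float(p))
        for ga, gb in itertools.combinations(names, 2):
            t, praw = sps.ttest_ind(groups[ga], groups[gb], equal_var=equal_var)
            padj = min(1.0, float(praw) * n_pairs)
            pairwise.append(
                PairwiseComparison(ga, gb, float(t), float(praw), padj,
                                   significance_stars(padj))
            )
    elif branch == "nonparametric":
        h, p = sps.kruskal(*groups.values())
        omnibus = ("Kruskal-Wallis", float(h), float(p))
        for ga, gb, z, praw in dunn_all_pairs(groups):
            padj = min(1.0, praw * n_pairs)
            pairwise.append(
                PairwiseComparison(ga, gb, z, praw, padj, significance_stars(padj))
            )
    else:
        raise ValueError(f"unknown branch {branch!r}")
    return StatsResult(
        metric=metric, branch=branch,
        omnibus_name=omnibus[0], omnibus_statistic=omnibus[1], omnibus_p=omnibus[2],
        pairwise=pairwise, gate_p=gate_p,
    )
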