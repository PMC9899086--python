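"""Group-comparison machinery for the thermogenetic screen.

For each driver and sleep parameter, the per-fly baseline-subtracted deltas
of three genotypes are compared: experimental (driver x effector) versus its
two genetic controls (GAL4-only, UAS-only).  Normally distributed data take
one-way ANOVA with Bonferroni-corrected planned comparisons; otherwise the
Kruskal–Wallis test with Dunn's tie-corrected post hoc comparisons.  Only the
two experimental-vs-control contrasts are tested (Bonferroni factor 2), and
an effect counts as real only when the experimental group differs from BOTH
controls — which bounds the familywise false-call rate near α².

A noncentral-t power calculation mirrors the screen's power analysis: the
null takes the control group's mean and SD, the alternative the experimental
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MIN_N_NORMALITY = 8


@dataclass(frozen=True)
class PlannedComparison:
    name: str
    mean_difference: float
    rank_mean_difference: float | None
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # "anova" | "kruskal_wallis"
    statistic: float  # F or H
    p_value: float
    comparisons: tuple[PlannedComparison, ...]
    alpha: float
    significant_overall: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "significant_overall",
            all(c.p_adjusted < self.alpha for c in self.comparisons),
        )


@dataclass(frozen=True)
class PowerResult:
    n1: int
    n2: int
    effect_size: float  # (mean1 - mean0) / sd0
    alpha: float
    power: float


def normality_triage(groups: list[np.ndarray], alpha: float = 0.05) -> str:
    """Decide between ANOVA and Kruskal–Wallis.

    ANOVA only when every group has n >= 8 (the omnibus normality test's own
    validity floor) and passes the D'Agostino–Pearson skewness–kurtosis test
    at the given alpha; otherwise Kruskal–Wallis.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    for g in groups:
        if len(g) < MIN_N_NORMALITY:
            return "kruskal_wallis"
        if stats.normaltest(g).pvalue < alpha:
            return "kruskal_wallis"
    return "anova"


def anova_with_planned(exp, gal4, uas, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA with two Bonferroni-corrected planned comparisons.

    The planned t statistics use the pooled within-group variance (MS_within)
    with N − 3 degrees of freedom; the Bonferroni factor is 2 (only
    experimental-vs-control contrasts are tested).
    """
    groups = [np.asarray(g, dtype=float) for g in (exp, gal4, uas)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = 2, int(N - 3)
    if ss_within == 0:
        # Degenerate: no within-group variance at all.
        if ss_between == 0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
        comps = tuple(
            PlannedComparison(
                name, float(means[0] - means[i]), None,
                1.0 if means[0] == means[i] else 0.0,
            )
            for name, i in (("exp_vs_gal4", 1), ("exp_vs_uas", 2))
        )
        return ComparisonResult("anova", F, p, comps, alpha)
    ms_w = ss_within / df_w
    F = (ss_between / df_b) / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    comps = []
    for name, i in (("exp_vs_gal4", 1), ("exp_vs_uas", 2)):
        diff = float(means[0] - means[i])
        se = np.sqrt(ms_w * (1 / ns[0] + 1 / ns[i]))
        t = diff / se
        p_raw = 2 * stats.t.sf(abs(t), df_w)
        comps.append(PlannedComparison(name, diff, None, float(min(1.0, 2 * p_raw))))
    return ComparisonResult("anova", float(F), p, tuple(comps), alpha)


def kruskal_dunn(exp, gal4, uas, alpha: float = 0.05) -> ComparisonResult:
    """Kruskal–Wallis test with Dunn's tie-corrected planned comparisons.

    Dunn's z compares mean ranks over the pooled ranking, with variance
    (N(N+1)/12 − ΣT/(12(N−1)))·(1/n_i + 1/n_j) where ΣT = Σ(t³ − t) over tie
    groups; adjusted p = min(1, 2·p_raw) for the two planned contrasts.
    """
    groups = [np.asarray(g, dtype=float) for g in (exp, gal4, uas)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if np.all(pooled == pooled[0]):
        comps = tuple(
            PlannedComparison(name, float(groups[0].mean() - groups[i].mean()), 0.0, 1.0)
            for name, i in (("exp_vs_gal4", 1), ("exp_vs_uas", 2))
        )
        return ComparisonResult("kruskal_wallis", 0.0, 1.0, comps, alpha)
    H, p = stats.kruskal(*groups)
    ranks = stats.rankdata(pooled)
    ns = [len(g) for g in groups]
    bounds = np.cumsum([0] + ns)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(3)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    comps = []
    for name, i in (("exp_vs_gal4", 1), ("exp_vs_uas", 2)):
        diff_rank = mean_ranks[0] - mean_ranks[i]
        se = np.sqrt(var_base * (1 / ns[0] + 1 / ns[i]))
        z = diff_rank / se if se > 0 else 0.0
        p_raw = 2 * stats.norm.sf(abs(z))
        comps.append(
            PlannedComparison(
                name,
                float(groups[0].mean() - groups[i].mean()),
                float(diff_rank),
                float(min(1.0, 2 * p_raw)),
            )
        )
    return ComparisonResult("kruskal_wallis", float(H), float(p), tuple(comps), alpha)


def compare_to_controls(exp, gal4, uas, alpha: float = 0.05) -> ComparisonResult:
    """Normality triage, then the matching 3-group test with planned comparisons."""
    groups = [np.asarray(g, dtype=float) for g in (exp, gal4, uas)]
    if normality_triage(groups, alpha=alpha) == "anova":
        return anova_with_planned(*groups, alpha=alpha)
    return kruskal_dunn(*groups, alpha=alpha)


def power_ttest(
    n1: int,
    n2: int,
    mean0: float,
    sd0: float,
    mean1: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Two-sample two-sided t-test power via the noncentral t distribution.

    The null hypothesis takes the control group's mean and SD; the
    alternative takes the experimental mean.  With zero effect the power
    equals alpha exactly.
    """
    if sd0 <= 0:
        raise ValueError("sd0 must be positive")
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    d = (mean1 - mean0) / sd0
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    df = n1 + n2 - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    return PowerResult(n1, n2, float(d), alpha, power)
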