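"""Trial-level statistics: performance ANOVA, SSG chi-square, speed and
beam-angle distribution tests.

Thin, explicit wrappers over scipy/statsmodels with the conventions used
throughout the analysis (daily percent-correct as the ANOVA observation,
grouped-versus-single call counts in the chi-square, Welch correction for
beam-angle comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult", "performance_anova", "daily_success_table",
    "ssg_proportion_test", "speed_distribution_test", "beam_group_ttest",
]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.Series
    pairwise: pd.DataFrame | None = None


def daily_success_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per bat/condition/day percent-correct from a trial table.

    ``trials`` needs columns ``bat``, ``condition``, ``day``, ``success``.
    """
    g = trials.groupby(["bat", "condition", "day"], observed=True)["success"]
    out = (100.0 * g.mean()).rename("percent_correct").reset_index()
    out["n_flights"] = g.size().to_numpy()
    return out


def performance_anova(daily: pd.DataFrame, factor: str = "condition",
                      value: str = "percent_correct") -> AnovaResult:
    """One-way ANOVA on daily percent-correct with Tukey pairwise tests."""
    groups = [sub[value].to_numpy(float) for _, sub in daily.groupby(factor, observed=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 factor levels")
    f, p = sps.f_oneway(*groups)
    if not np.isfinite(f):          # all groups identical
        f, p = 0.0, 1.0
    n = sum(len(g) for g in groups)
    means = daily.groupby(factor, observed=True)[value].mean()
    pairwise = None
    if all(len(g) >= 2 for g in groups) and any(np.var(g) > 0 for g in groups):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        thsd = pairwise_tukeyhsd(daily[value].to_numpy(float),
                                 daily[factor].astype(str).to_numpy())
        pairwise = pd.DataFrame(thsd.summary().data[1:],
                                columns=thsd.summary().data[0])
    return AnovaResult(float(f), len(groups) - 1, n - len(groups), float(p),
                       means, pairwise)


def ssg_proportion_test(grouped_a: int, single_a: int,
                        grouped_b: int, single_b: int,
                        correction: bool = False) -> tuple[float, float]:
    """Chi-square test on grouped-versus-single call counts, df = 1.

    Compares the proportion of calls emitted inside sonar sound groups
    between two conditions via the 2x2 contingency chi-square (continuity
    correction off by default).  Returns ``(chi2, p)``.
    """
    table = np.array([[grouped_a, single_a], [grouped_b, single_b]], float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("a margin of the 2x2 table is empty")
    if np.any(table == 0) and not correction:
        import warnings

        warnings.warn("empty cell without continuity correction")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def speed_distribution_test(speeds_a, speeds_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on flight-speed samples."""
    a = np.asarray(speeds_a, float)
    b = np.asarray(speeds_b, float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 speed samples per group")
    d, p = sps.ks_2samp(a, b)
    return float(d), float(p)


def beam_group_ttest(angles_a, angles_b) -> tuple[float, float, float]:
    """Welch two-sample t test on beam-angle samples.

    Returns ``(t, df, p)``; two zero-variance groups with equal means give
    ``t = 0, p = 1`` by convention.
    """
    a = np.asarray(angles_a, float)
    b = np.asarray(angles_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 angles per group")
    if a.std() == 0 and b.std() == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
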