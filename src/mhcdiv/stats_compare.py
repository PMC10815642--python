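"""Group-comparison statistics for per-gene diversity summaries.

Paralogous genes of each species act as experimental repeats: two-sample
Student's t-test (pooled variance by default, Welch behind a flag),
one-way and additive two-way ANOVA (no interaction term — the paralog x
pocket layout has one observation per cell, so interaction is
inestimable), and Tukey HSD post hoc comparisons based on the
studentized range.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["TTestResult", "t_test", "anova", "tukey_hsd"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def t_test(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test (pooled Student by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float("inf"), df, 0.0)
    return TTestResult(t, df, p)


def anova(measurements: pd.DataFrame, factors: int = 1) -> pd.DataFrame:
    """One-way or additive two-way ANOVA.

    ``measurements`` needs columns ``value`` and ``factor1`` (and
    ``factor2`` when ``factors == 2``).  Returns one row per factor with
    (factor, F, df_num, df_den, p).  A factor with a single level is an
    error; if the residual variance is zero, F = 0 and p = 1 by
    convention (all observations equal within cells).
    """
    df = measurements.copy()
    needed = ["value", "factor1"] + (["factor2"] if factors == 2 else [])
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"measurements lack column {col!r}")
    for col in needed[1:]:
        if df[col].nunique() < 2:
            raise ValueError(f"{col} has fewer than 2 levels")
    if np.allclose(df["value"], df["value"].iloc[0]):
        # constant response: F = 0, p = 1 by convention
        n = len(df)
        dfs = {col: df[col].nunique() - 1 for col in needed[1:]}
        resid_df = float(n - 1 - sum(dfs.values()))
        return pd.DataFrame(
            [
                {"factor": col, "F": 0.0, "df_num": float(k), "df_den": resid_df, "p": 1.0}
                for col, k in dfs.items()
            ]
        )
    formula = "value ~ C(factor1)" + (" + C(factor2)" if factors == 2 else "")
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rows = []
    resid_df = float(table.loc["Residual", "df"])
    for name in table.index:
        if name == "Residual":
            continue
        factor = "factor1" if "factor1" in name else "factor2"
        F = table.loc[name, "F"]
        p = table.loc[name, "PR(>F)"]
        if np.isnan(F):  # zero residual variance
            ss = table.loc[name, "sum_sq"]
            F, p = (0.0, 1.0) if np.isclose(ss, 0.0) else (float("inf"), 0.0)
        rows.append(
            {
                "factor": factor,
                "F": float(F),
                "df_num": float(table.loc[name, "df"]),
                "df_den": resid_df,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def tukey_hsd(
    measurements: pd.DataFrame, factor: str = "factor1", alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for a one-way layout.

    Returns one row per unordered level pair: (level_a, level_b, diff,
    q, p_adj, significant).  q is the studentized-range statistic; p_adj
    its tail probability at k levels and the pooled within-group df.
    """
    if factor not in measurements.columns:
        raise ValueError(f"measurements lack column {factor!r}")
    levels = sorted(measurements[factor].unique())
    if len(levels) < 2:
        raise ValueError("Tukey HSD needs at least 2 levels")
    groups = [measurements.loc[measurements[factor] == lv, "value"].to_numpy(float) for lv in levels]
    k = len(levels)
    n_total = sum(g.size for g in groups)
    df_w = n_total - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_w = ss_w / df_w
    rows = []
    for (ia, la), (ib, lb) in combinations(enumerate(levels), 2):
        ga, gb = groups[ia], groups[ib]
        diff = float(gb.mean() - ga.mean())
        if ms_w > 0:
            se = np.sqrt(ms_w / 2.0 * (1.0 / ga.size + 1.0 / gb.size))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_w))
        else:  # all groups internally constant
            q = float("inf") if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "diff": diff,
                "q": float(q),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)
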