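"""Baseline descriptive tables: means +/- SD with t-tests, counts (%) with chi-square.

Continuous characteristics are compared across two groups by a
pooled-variance Student's t-test (Welch available); categorical
characteristics by a Pearson chi-square on the contingency table.
Percentages are displayed to one decimal, underlying values kept at full
precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: Table-1-style row order.
CONTINUOUS_VARS = [
    "age", "bmi", "diet_total_folate", "diet_folic_acid", "food_folate",
    "dfe", "diet_b12",
]
CATEGORICAL_VARS = [
    "sex", "race_ethnicity", "marital", "education",
    "smoking", "drinking", "hypertension", "hyperlipidemia", "diabetes",
    "impaired_cerad", "impaired_af", "impaired_dsst",
]


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Display percentage: 100 * count / total, rounded as printed."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def ttest_groups(values_a, values_b, variant: str = "student"):
    """Two-sample t-test; pooled-variance Student's by default, Welch optional."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "student"
    if equal_var:
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if pooled <= 0:
            raise ValueError("zero pooled variance: t-test degenerate")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def ttest_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b, variant: str = "student"):
    """t-test from group summaries (mean, SD, n); matches the raw-data test."""
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "student")
    )
    return float(res.statistic), float(res.pvalue)


def chisq_groups(table):
    """Pearson chi-square on a contingency table, df = (r-1)(c-1), no correction."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected count of zero")
    return float(chi2), float(p)


def baseline_table(cohort_df: pd.DataFrame, group_var: str,
                   continuous=None, categorical=None) -> pd.DataFrame:
    """Table-1-style group comparison.

    One row per continuous variable (mean, SD, n per group, t-test when
    two groups) and one row per categorical level (count, % per group,
    chi-square p shared across the variable's levels). Single-group input
    yields summaries without tests.
    """
    continuous = CONTINUOUS_VARS if continuous is None else continuous
    categorical = CATEGORICAL_VARS if categorical is None else categorical
    df = cohort_df.dropna(subset=[group_var])
    groups = sorted(df[group_var].dropna().unique().tolist(), key=str)

    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        row = {"variable": var, "level": "", "test": "t-test"}
        per_group = []
        for g in groups:
            vals = df.loc[df[group_var] == g, var].dropna().to_numpy(dtype=float)
            row[f"mean_{g}"] = vals.mean() if vals.size else np.nan
            row[f"sd_{g}"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"n_{g}"] = vals.size
            per_group.append(vals)
        if len(groups) == 2 and all(v.size >= 2 for v in per_group):
            t, p = ttest_groups(per_group[0], per_group[1])
            row["statistic"], row["pvalue"] = t, p
        else:
            row["statistic"], row["pvalue"] = np.nan, np.nan
        rows.append(row)

    for var in categorical:
        if var not in df.columns:
            continue
        sub = df.dropna(subset=[var])
        tab = pd.crosstab(sub[var], sub[group_var])
        if len(groups) >= 2 and tab.shape[0] >= 2:
            try:
                chi2, p = chisq_groups(tab.to_numpy())
            except ValueError:
                chi2, p = np.nan, np.nan
        else:
            chi2, p = np.nan, np.nan
        for level in tab.index:
            row = {"variable": var, "level": str(level), "test": "chi-square",
                   "statistic": chi2, "pvalue": p}
            for g in groups:
                cnt = int(tab.loc[level, g]) if g in tab.columns else 0
                tot = int(tab[g].sum()) if g in tab.columns else 0
                row[f"count_{g}"] = cnt
                row[f"pct_{g}"] = percentage(cnt, tot) if tot else np.nan
                row[f"n_{g}"] = tot
            rows.append(row)

    return pd.DataFrame(rows)
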