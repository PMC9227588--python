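"""Restricted-cubic-spline dose-response regression with LR tests.

Each cognitive score is regressed by OLS on a biomarker's restricted cubic
spline basis (3 knots at the 10th/50th/90th percentiles, giving one linear
and one non-linear column) plus the full covariate adjustment set: age,
age^2, sex, race/ethnicity, marital status, education (collapsed to three
levels), smoking, drinking, hypertension, hyperlipidemia, diabetes, eGFR,
and the folate-related intakes (total folate, dietary folic acid, food
folate, DFE).

Non-linearity is tested by a likelihood-ratio test of the spline model
against the nested linear model (df = 1 with 3 knots) using the Gaussian
log-likelihood ``ll = -(n/2) (ln(2 pi RSS / n) + 1)``; effect modification
by vitamin-B12 status is tested by an LR test on the basis-by-status
product columns (df = 2). Adjusted dose-response curves are
population-average (g-computation over observed covariate rows) with
delta-method 95% confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_KNOT_PERCENTILES = (10.0, 50.0, 90.0)

#: Education collapsed to the three adjustment levels used in the regression
#: models (the cohort table keeps the full five levels for description).
EDU_COLLAPSE = {
    "lt_9th": "lt_hs",
    "9_11th": "lt_hs",
    "hs_grad": "hs",
    "some_college": "gt_hs",
    "college_grad": "gt_hs",
}

CATEGORICAL_COVARIATES = ["sex", "race_ethnicity", "marital", "education3"]
BINARY_COVARIATES = [
    "smoking", "drinking", "hypertension", "hyperlipidemia", "diabetes",
]
CONTINUOUS_COVARIATES = [
    "egfr", "diet_total_folate", "diet_folic_acid", "food_folate", "dfe",
]


class DegenerateKnotError(ValueError):
    """Knot percentiles collapse onto non-distinct values."""


@dataclass(frozen=True)
class SplineSpec:
    """Three-knot restricted cubic spline specification."""

    knots: tuple
    percentiles: tuple = DEFAULT_KNOT_PERCENTILES

    def __post_init__(self):
        t = np.asarray(self.knots, dtype=float)
        if t.size != 3 or not np.all(np.diff(t) > 0):
            raise DegenerateKnotError(f"knots must be 3 strictly increasing values, got {t}")


@dataclass
class SplineFit:
    """OLS fit summary: coefficients, covariance, RSS, Gaussian log-likelihood."""

    params: pd.Series
    cov_params: pd.DataFrame
    rss: float
    loglik: float
    n: int
    k_params: int
    column_names: list = field(default_factory=list)


@dataclass(frozen=True)
class NonlinearityTest:
    statistic: float
    df: int
    pvalue: float


@dataclass
class CurveEstimate:
    """Adjusted dose-response curve on an exposure grid with 95% CI."""

    grid: np.ndarray
    fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def compute_knots(x, percentiles=DEFAULT_KNOT_PERCENTILES) -> SplineSpec:
    """Empirical-percentile knots (linear interpolation of order statistics)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if np.unique(x).size < 3:
        raise DegenerateKnotError("need at least 3 distinct exposure values")
    knots = np.percentile(x, percentiles, method="linear")
    if not np.all(np.diff(knots) > 0):
        raise DegenerateKnotError(f"percentiles {percentiles} give tied knots {knots}")
    return SplineSpec(knots=tuple(knots), percentiles=tuple(percentiles))


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Two-column restricted cubic spline basis: (x, R(x)).

    ``R(x) = [(x-t1)+^3 - (x-t2)+^3 (t3-t1)/(t3-t2) + (x-t3)+^3 (t2-t1)/(t3-t2)]
    / (t3-t1)^2`` -- Harrell's truncated-power restricted form, linear beyond
    the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t1, t2, t3 = spec.knots

    def p3(u):
        return np.maximum(u, 0.0) ** 3

    r = (
        p3(x - t1)
        - p3(x - t2) * (t3 - t1) / (t3 - t2)
        + p3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, r])


def _complete_cases(df: pd.DataFrame, cols) -> pd.DataFrame:
    return df.dropna(subset=[c for c in cols if c in df.columns])


def build_design(
    cohort_df: pd.DataFrame,
    exposure: str,
    outcome: str,
    spline: SplineSpec | None = None,
    adjust: bool = True,
    extra_cols: tuple = (),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Assemble the regression design matrix and response.

    Returns ``(X, y, rows)`` where ``X`` has an intercept, the exposure
    spline columns (or the bare exposure if ``spline`` is None), dummy-coded
    categoricals and continuous covariates, restricted to complete cases;
    ``rows`` is the complete-case cohort slice the design was built from.
    Zero-variance columns are dropped with a warning.
    """
    needed = [exposure, outcome]
    if adjust:
        needed += ["age", "sex", "race_ethnicity", "marital", "education"]
        needed += BINARY_COVARIATES + CONTINUOUS_COVARIATES
    needed += list(extra_cols)
    rows = _complete_cases(cohort_df, needed).reset_index(drop=True)

    parts = [pd.Series(1.0, index=rows.index, name="intercept")]
    xcol = rows[exposure].to_numpy(dtype=float)
    if spline is not None:
        basis = rcs_basis(xcol, spline)
        parts.append(pd.Series(basis[:, 0], index=rows.index, name=f"{exposure}"))
        parts.append(pd.Series(basis[:, 1], index=rows.index, name=f"{exposure}_rcs"))
    else:
        parts.append(pd.Series(xcol, index=rows.index, name=f"{exposure}"))

    if adjust:
        age = rows["age"].to_numpy(dtype=float)
        parts.append(pd.Series(age, index=rows.index, name="age"))
        parts.append(pd.Series(age**2, index=rows.index, name="age_sq"))
        cat = rows[["sex", "race_ethnicity", "marital"]].copy()
        cat["education3"] = rows["education"].map(EDU_COLLAPSE).fillna(rows["education"])
        multi_level = []
        for c in CATEGORICAL_COVARIATES:
            if cat[c].nunique() <= 1:
                warnings.warn(f"dropping zero-variance design column {c!r}", stacklevel=2)
            else:
                multi_level.append(c)
        dummies = pd.get_dummies(cat[multi_level], drop_first=True, dtype=float)
        dummies = dummies.reindex(sorted(dummies.columns), axis=1)
        parts.append(dummies)
        for c in BINARY_COVARIATES:
            parts.append(pd.Series(rows[c].astype(float).to_numpy(), index=rows.index, name=c))
        for c in CONTINUOUS_COVARIATES:
            if c in rows.columns:
                parts.append(pd.Series(rows[c].to_numpy(dtype=float), index=rows.index, name=c))

    X = pd.concat(parts, axis=1)
    keep = []
    for c in X.columns:
        if c != "intercept" and X[c].nunique() <= 1:
            warnings.warn(f"dropping zero-variance design column {c!r}", stacklevel=2)
            continue
        keep.append(c)
    X = X[keep]
    y = rows[outcome].astype(float).rename(outcome)
    return X, y, rows


def gaussian_loglik(rss: float, n: int, var_floor: float = 0.0) -> float:
    """Profile Gaussian log-likelihood of an OLS fit.

    A perfect fit (RSS = 0) is floored at ``var_floor`` (machine epsilon
    times the response variance upstream) so the log stays finite.
    """
    rss = max(float(rss), float(var_floor), np.finfo(float).tiny)
    return -(n / 2.0) * (np.log(2.0 * np.pi * rss / n) + 1.0)


def fit_ols(X: pd.DataFrame, y: pd.Series) -> SplineFit:
    """OLS fit with nonrobust covariance and Gaussian log-likelihood.

    Raises an estimation error listing collinear columns when the design is
    rank deficient.
    """
    Xv = np.asarray(X, dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"need n > params, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # name the columns implicated in the deficiency via QR pivoting
        _, r = np.linalg.qr(Xv)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design (collinear columns: {bad})")
    model = sm.OLS(np.asarray(y, dtype=float), Xv)
    res = model.fit()
    var_floor = np.finfo(float).eps * float(np.var(np.asarray(y, dtype=float))) * n
    return SplineFit(
        params=pd.Series(res.params, index=X.columns),
        cov_params=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        rss=float(res.ssr),
        loglik=gaussian_loglik(res.ssr, n, var_floor),
        n=n,
        k_params=p,
        column_names=list(X.columns),
    )


def lr_test(fit_full: SplineFit, fit_reduced: SplineFit) -> NonlinearityTest:
    """Likelihood-ratio test between nested Gaussian OLS fits.

    ``LR = 2 (ll_full - ll_reduced) = n ln(RSS_reduced / RSS_full)``,
    referred to chi-square with df = difference in parameter counts.
    """
    if fit_full.n != fit_reduced.n:
        raise ValueError("LR test requires models fit to the same rows")
    df = fit_full.k_params - fit_reduced.k_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    lr = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = float(stats.chi2.sf(lr, df))
    return NonlinearityTest(statistic=lr, df=df, pvalue=p)


def lr_nonlinearity(fit_linear: SplineFit, fit_spline: SplineFit) -> NonlinearityTest:
    """LR test for non-linearity: spline model vs nested linear model (df = 1)."""
    return lr_test(fit_spline, fit_linear)


def fit_spline_model(
    cohort_df: pd.DataFrame,
    exposure: str,
    outcome: str,
    percentiles=DEFAULT_KNOT_PERCENTILES,
    adjust: bool = True,
):
    """Fit the spline and nested linear models; return fits, test and spec.

    Convenience wrapper running knot placement, both designs on identical
    complete-case rows, and the non-linearity LR test.
    """
    rows0 = _complete_cases(
        cohort_df,
        [exposure, outcome]
        + (["age", "sex", "race_ethnicity", "marital", "education"]
           + BINARY_COVARIATES + CONTINUOUS_COVARIATES if adjust else []),
    )
    spec = compute_knots(rows0[exposure].to_numpy(dtype=float), percentiles)
    X_s, y, rows = build_design(cohort_df, exposure, outcome, spline=spec, adjust=adjust)
    X_l = X_s.drop(columns=[f"{exposure}_rcs"])
    fit_s = fit_ols(X_s, y)
    fit_l = fit_ols(X_l, y)
    test = lr_nonlinearity(fit_l, fit_s)
    return {
        "spec": spec,
        "fit_spline": fit_s,
        "fit_linear": fit_l,
        "nonlinearity": test,
        "X": X_s,
        "y": y,
        "rows": rows,
    }


def predict_curve(
    fit: SplineFit,
    spec: SplineSpec,
    X: pd.DataFrame,
    exposure: str,
    grid=None,
    n_grid: int = 50,
    level: float = 0.95,
) -> CurveEstimate:
    """Population-average adjusted dose-response curve with delta-method CI.

    For each grid value g the exposure columns of every observed design row
    are replaced by the basis at g and predictions are averaged; the CI is
    ``xbar' Sigma xbar`` on the averaged design row.
    """
    xobs = X[exposure].to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(xobs.min(), xobs.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < xobs.min() - 1e-9 or grid.max() > xobs.max() + 1e-9:
        raise ValueError("prediction grid extends beyond the observed exposure range")

    z = stats.norm.ppf(0.5 + level / 2.0)
    cols = list(X.columns)
    i_lin = cols.index(exposure)
    i_rcs = cols.index(f"{exposure}_rcs") if f"{exposure}_rcs" in cols else None
    xbar = np.asarray(X, dtype=float).mean(axis=0)

    beta = fit.params.to_numpy()
    sigma = fit.cov_params.to_numpy()
    fitv = np.empty(grid.size)
    se = np.empty(grid.size)
    for j, g in enumerate(grid):
        row = xbar.copy()
        basis = rcs_basis(np.array([g]), spec)
        row[i_lin] = basis[0, 0]
        if i_rcs is not None:
            row[i_rcs] = basis[0, 1]
        fitv[j] = row @ beta
        se[j] = np.sqrt(row @ sigma @ row)
    return CurveEstimate(grid=grid, fit=fitv, lower=fitv - z * se, upper=fitv + z * se)


def subgroup_fits(
    cohort_df: pd.DataFrame,
    exposure: str,
    outcome: str,
    status_col: str = "low_b12",
    percentiles=DEFAULT_KNOT_PERCENTILES,
    adjust: bool = True,
) -> dict:
    """Run the spline pipeline independently within each B12 stratum.

    Strata too small to fit (n <= parameter count) are skipped with a
    warning rather than failing the whole analysis.
    """
    out = {}
    labelled = cohort_df.dropna(subset=[status_col])
    for label, name in ((1.0, "low"), (0.0, "normal")):
        sub = labelled[labelled[status_col] == label]
        if sub.empty:
            continue
        try:
            out[name] = fit_spline_model(sub, exposure, outcome, percentiles, adjust)
        except (ValueError, DegenerateKnotError) as exc:
            warnings.warn(f"stratum {name!r} skipped: {exc}", stacklevel=2)
    return out


def interaction_lr(
    cohort_df: pd.DataFrame,
    exposure: str,
    outcome: str,
    status_col: str = "low_b12",
    percentiles=DEFAULT_KNOT_PERCENTILES,
    adjust: bool = True,
) -> NonlinearityTest:
    """LR test of biomarker-by-B12-status effect modification (df = 2).

    Full model adds the modifier main effect and both spline-basis x
    modifier product columns to the main-effects spline model; reduced
    model has the modifier main effect only.
    """
    df = cohort_df.dropna(subset=[status_col])
    mod = df[status_col].astype(float)
    if mod.nunique() < 2:
        raise ValueError(f"modifier {status_col!r} has no variation")
    spec = compute_knots(
        _complete_cases(df, [exposure, outcome])[exposure].to_numpy(dtype=float),
        percentiles,
    )
    X, y, rows = build_design(
        df, exposure, outcome, spline=spec, adjust=adjust, extra_cols=(status_col,)
    )
    m = rows[status_col].astype(float).to_numpy()
    X_red = X.copy()
    X_red[status_col] = m
    X_full = X_red.copy()
    X_full[f"{exposure}:{status_col}"] = X[exposure].to_numpy() * m
    X_full[f"{exposure}_rcs:{status_col}"] = X[f"{exposure}_rcs"].to_numpy() * m
    return lr_test(fit_ols(X_full, y), fit_ols(X_red, y))
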