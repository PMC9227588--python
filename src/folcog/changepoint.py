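"""Single change-point (two-line) estimation by exhaustive profile likelihood.

Where a dose-response shows evidence of non-linearity, a continuous
two-line model ``y = b0 + b1 x + b2 (x - c)_+ (+ covariates)`` is fit at
every candidate change point c, and the candidate with the highest
Gaussian likelihood (equivalently lowest RSS) is selected. Candidates are
the unique observed exposure values with tail trimming and a minimum
number of observations on each side, so every profiled fit has support on
both limbs. Ties on RSS break to the smallest candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from folcog.splines import gaussian_loglik


class GridError(ValueError):
    """No admissible change-point candidates."""


@dataclass
class ChangePointFit:
    """Profile-likelihood change-point fit.

    ``slope_above = slope_below + slope_change``; ``profile`` holds every
    candidate with its RSS and log-likelihood.
    """

    breakpoint: float
    intercept: float
    slope_below: float
    slope_change: float
    rss: float
    loglik: float
    n: int
    profile: pd.DataFrame

    @property
    def slope_above(self) -> float:
        return self.slope_below + self.slope_change


def candidate_grid(
    x,
    trim_lo: float = 5.0,
    trim_hi: float = 95.0,
    min_per_side: int = 10,
) -> np.ndarray:
    """Admissible change-point candidates.

    Unique observed exposure values within the [trim_lo, trim_hi]
    percentile window having at least ``min_per_side`` observations
    strictly below and at-or-above each candidate.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if np.unique(x).size < 2:
        raise GridError("exposure has fewer than 2 distinct values")
    lo, hi = np.percentile(x, [trim_lo, trim_hi])
    cands = np.unique(x)
    cands = cands[(cands >= lo) & (cands <= hi)]
    n_below = np.searchsorted(np.sort(x), cands, side="left")
    n_above = x.size - n_below
    cands = cands[(n_below >= min_per_side) & (n_above >= min_per_side)]
    if cands.size == 0:
        raise GridError(
            f"no candidate with >= {min_per_side} observations per side "
            f"inside the [{trim_lo}, {trim_hi}] percentile window"
        )
    return cands


def fit_changepoint(x, y, covariates=None, grid=None) -> ChangePointFit:
    """Profile the change point over ``grid`` and return the best fit.

    At each candidate c, OLS of y on ``[1, x, (x - c)_+]`` plus optional
    covariate columns; singular candidate designs are skipped (logged in
    the profile with NaN RSS). Complete cases only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    else:
        C = np.empty((x.size, 0))
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    x, y, C = x[ok], y[ok], C[ok]
    if grid is None:
        grid = candidate_grid(x)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise GridError("empty candidate grid")

    n = x.size
    base = np.column_stack([np.ones(n), x, np.zeros(n), C])
    best = None
    records = []
    for c in grid:
        base[:, 2] = np.maximum(x - c, 0.0)
        coef, rss_arr, rank, _ = linalg.lstsq(
            base, y, lapack_driver="gelsd", check_finite=False
        )
        if rank < base.shape[1]:
            records.append((c, np.nan, np.nan))
            continue
        rss = float(rss_arr) if np.size(rss_arr) else float(np.sum((y - base @ coef) ** 2))
        ll = gaussian_loglik(rss, n, np.finfo(float).eps * float(np.var(y)) * n)
        records.append((c, rss, ll))
        # grid is ascending and the comparison strict, so ties keep the smallest c
        if best is None or rss < best[1]:
            best = (c, rss, ll, coef.copy())
    if best is None:
        raise GridError("every candidate design was singular")
    c, rss, ll, coef = best
    profile = pd.DataFrame(records, columns=["candidate", "rss", "loglik"])
    return ChangePointFit(
        breakpoint=float(c),
        intercept=float(coef[0]),
        slope_below=float(coef[1]),
        slope_change=float(coef[2]),
        rss=rss,
        loglik=ll,
        n=n,
        profile=profile,
    )


def breakpoint_report(fits: dict) -> pd.DataFrame:
    """Tidy breakpoint table from ``{(marker, test): ChangePointFit}``.

    One row per marker-test pair: change point, both slopes, RSS and n.
    The per-fit likelihood profiles remain on the fit objects for export.
    """
    rows = []
    for (marker, test), f in fits.items():
        rows.append(
            {
                "marker": marker,
                "test": test,
                "breakpoint": f.breakpoint,
                "slope_below": f.slope_below,
                "slope_above": f.slope_above,
                "rss": f.rss,
                "n": f.n,
            }
        )
    return pd.DataFrame(
        rows, columns=["marker", "test", "breakpoint", "slope_below", "slope_above", "rss", "n"]
    )
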