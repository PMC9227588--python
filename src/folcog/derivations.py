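"""Cohort ingestion, derived analysis variables, and eligibility filtering.

Derivations attached per participant:

* eGFR from the 2009 CKD-EPI creatinine equation (mL/min/1.73 m^2),
* low vitamin-B12 status (serum B12 < 148 pmol/L or MMA > 210 nmol/L),
* cognitive-impairment flags (CERAD-WL < 17 and CERAD-DR < 5; AF < 14;
  DSST < 34),
* dietary folate equivalents (1 DFE = 1 ug food folate = 0.6 ug folic acid).

Eligibility keeps participants aged 60+, with complete analysis fields,
eGFR >= 60 and no stroke history, recording one exclusion reason per
dropped record in a fixed order (age, completeness, eGFR, stroke) so the
audit counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

B12_DEFICIENCY_CUTOFF = 148.0  # pmol/L
MMA_ELEVATED_CUTOFF = 210.0  # nmol/L
EGFR_CUTOFF = 60.0  # mL/min/1.73 m^2
MIN_AGE = 60.0

#: Fields that must be present for a record to count as complete:
#: the four cognitive tests, demographics, history flags, and blood values.
REQUIRED_FIELDS = [
    "age", "sex", "race_ethnicity", "marital", "education", "bmi",
    "smoking", "drinking", "hypertension", "hyperlipidemia", "diabetes",
    "stroke_history", "serum_creatinine",
    "rbc_folate", "serum_total_folate", "five_methyl_thf", "vitamin_b12", "mma",
    "cerad_wl", "cerad_dr", "af", "dsst",
]


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


@dataclass
class Cohort:
    """An ordered participant table plus provenance metadata."""

    data: pd.DataFrame
    source: str = "<memory>"
    filters_applied: list = field(default_factory=list)
    n_in: int | None = None
    missing_cells: int = 0

    def __post_init__(self):
        if self.n_in is None:
            self.n_in = len(self.data)
        if self.data["id"].duplicated().any():
            raise ValueError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.data)


_NUMERIC = [
    "age", "bmi", "serum_creatinine",
    "rbc_folate", "serum_total_folate", "five_methyl_thf", "vitamin_b12",
    "mma", "umfa", "diet_total_folate", "diet_folic_acid", "food_folate",
    "dfe", "diet_b12", "cerad_wl", "cerad_dr", "af", "dsst",
]
_BOOL = [
    "smoking", "drinking", "hypertension", "hyperlipidemia", "diabetes",
    "stroke_history",
]


def read_cohort(path: str | Path, column_map: dict | None = None,
                sep: str = ",") -> Cohort:
    """Read a delimited cohort table into a typed :class:`Cohort`.

    ``column_map`` maps canonical names to the file's column names (for
    external sources such as NHANES exports). Unparseable numeric cells
    become missing values; the total count of missing numeric cells is
    recorded in provenance.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)
    required = ["id"] + REQUIRED_FIELDS
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"required column missing: {col!r}")

    df = raw.copy()
    missing_cells = 0
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            missing_cells += int(df[col].isna().sum())
    for col in _BOOL:
        if col in df.columns:
            df[col] = (
                df[col].astype(str).str.strip().str.lower()
                .map({"true": True, "false": False, "1": True, "0": False,
                      "yes": True, "no": False})
            )
    df["id"] = pd.to_numeric(df["id"], errors="raise")
    return Cohort(data=df, source=str(path), missing_cells=missing_cells)


def compute_egfr(creatinine, age, sex, race_black=False):
    """2009 CKD-EPI creatinine eGFR (mL/min/1.73 m^2).

    ``141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age * 1.018[female]
    * 1.159[Black]`` with k = 0.7 (female) / 0.9 (male) and a = -0.329
    (female) / -0.411 (male). Vectorised over its inputs.
    """
    scr = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    female = np.asarray(
        pd.Series(np.atleast_1d(sex)).astype(str).str.lower().isin(["female", "f"])
    )
    female = np.broadcast_to(female, scr.shape) if scr.shape else female[0]
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
        * np.where(np.asarray(race_black, dtype=bool), 1.159, 1.0)
    )
    return egfr if egfr.shape else float(egfr)


def classify_b12_status(b12, mma):
    """Low iff serum B12 < 148 pmol/L or MMA > 210 nmol/L; NaN if either missing."""
    b12 = np.asarray(b12, dtype=float)
    mma = np.asarray(mma, dtype=float)
    low = (b12 < B12_DEFICIENCY_CUTOFF) | (mma > MMA_ELEVATED_CUTOFF)
    out = np.where(np.isnan(b12) | np.isnan(mma), np.nan, low.astype(float))
    return out if out.shape else float(out)


def flag_cognitive_impairment(cerad_wl, cerad_dr, af, dsst) -> dict:
    """Impairment flags at the standard cutoffs (all strict inequalities).

    ``impaired_cerad`` requires both WL < 17 and DR < 5; AF < 14 and
    DSST < 34 flag the fluency and processing-speed domains. Missing
    inputs propagate as NaN.
    """
    wl = np.asarray(cerad_wl, dtype=float)
    dr = np.asarray(cerad_dr, dtype=float)
    af = np.asarray(af, dtype=float)
    ds = np.asarray(dsst, dtype=float)

    def _flag(cond, *inputs):
        bad = np.zeros(np.broadcast(*inputs).shape, dtype=bool) if inputs else None
        for a in inputs:
            bad |= np.isnan(a)
        return np.where(bad, np.nan, cond.astype(float))

    return {
        "impaired_cerad": _flag((wl < 17) & (dr < 5), wl, dr),
        "impaired_af": _flag(af < 14, af),
        "impaired_dsst": _flag(ds < 34, ds),
    }


def compute_dfe(food_folate, folic_acid):
    """Dietary folate equivalents: food folate + folic acid / 0.6 (ug)."""
    ff = np.asarray(food_folate, dtype=float)
    fa = np.asarray(folic_acid, dtype=float)
    if np.any(ff < 0) or np.any(fa < 0):
        raise ValueError("folate intakes must be non-negative")
    out = ff + fa / 0.6
    return out if out.shape else float(out)


def derive_flags(cohort: Cohort) -> Cohort:
    """Attach eGFR, low-B12 status and impairment flags as columns."""
    df = cohort.data.copy()
    ok = df["serum_creatinine"].notna() & df["age"].notna()
    egfr = np.full(len(df), np.nan)
    if ok.any():
        egfr[ok.to_numpy()] = compute_egfr(
            df.loc[ok, "serum_creatinine"].to_numpy(),
            df.loc[ok, "age"].to_numpy(),
            df.loc[ok, "sex"].to_numpy(),
            race_black=(df.loc[ok, "race_ethnicity"] == "NHB").to_numpy(),
        )
    df["egfr"] = egfr
    df["low_b12"] = classify_b12_status(df["vitamin_b12"].to_numpy(), df["mma"].to_numpy())
    flags = flag_cognitive_impairment(
        df["cerad_wl"].to_numpy(), df["cerad_dr"].to_numpy(),
        df["af"].to_numpy(), df["dsst"].to_numpy(),
    )
    for k, v in flags.items():
        df[k] = v
    return Cohort(
        data=df, source=cohort.source,
        filters_applied=list(cohort.filters_applied),
        n_in=cohort.n_in, missing_cells=cohort.missing_cells,
    )


def apply_eligibility(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
    """Apply the eligibility filter; return the kept cohort and an audit log.

    Rules, applied per record in fixed order with one recorded reason each:
    age >= 60; complete :data:`REQUIRED_FIELDS`; eGFR >= 60; no stroke
    history. Idempotent: filtering a filtered cohort is the identity.
    """
    df = cohort.data
    if "egfr" not in df.columns:
        cohort = derive_flags(cohort)
        df = cohort.data

    reasons = pd.Series(pd.NA, index=df.index, dtype="object")

    too_young = df["age"].notna() & (df["age"] < MIN_AGE)
    reasons[too_young] = "age<60"

    incomplete = df[REQUIRED_FIELDS].isna().any(axis=1)
    reasons[reasons.isna() & incomplete] = "incomplete"

    low_egfr = df["egfr"].notna() & (df["egfr"] < EGFR_CUTOFF)
    reasons[reasons.isna() & low_egfr] = "egfr<60"

    stroke = df["stroke_history"].fillna(False).astype(bool)
    reasons[reasons.isna() & stroke] = "stroke"

    keep = reasons.isna()
    log = pd.DataFrame(
        {"id": df.loc[~keep, "id"].to_numpy(), "reason": reasons[~keep].to_numpy()}
    )
    out = Cohort(
        data=df.loc[keep].reset_index(drop=True),
        source=cohort.source,
        filters_applied=list(cohort.filters_applied) + ["eligibility"],
        n_in=cohort.n_in,
        missing_cells=cohort.missing_cells,
    )
    assert len(cohort) == len(out) + len(log)
    return out, log
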