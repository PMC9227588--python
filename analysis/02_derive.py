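"""Derive analysis variables and apply the eligibility filter.

Attaches CKD-EPI eGFR, low-B12 status (B12 < 148 pmol/L or MMA > 210
nmol/L) and cognitive-impairment flags, then keeps participants aged 60+
with complete analysis fields, eGFR >= 60 and no stroke history, writing
the analysis cohort and an exclusion audit under results/.
"""

from pathlib import Path

from folcog.derivations import apply_eligibility, derive_flags, read_cohort

OUT = Path("results")


def main() -> None:
    cohort = derive_flags(read_cohort(OUT / "cohort.csv"))
    kept, log = apply_eligibility(cohort)
    kept.data.to_csv(OUT / "analysis_cohort.csv", index=False)
    log.to_csv(OUT / "exclusions.csv", index=False)
    n_low = int((kept.data["low_b12"] == 1.0).sum())
    print(f"eligible: {len(kept)} of {len(cohort)}; "
          f"exclusions: {log['reason'].value_counts().to_dict()}")
    print(f"low vitamin-B12 status: {n_low} ({100 * n_low / len(kept):.1f}%)")


if __name__ == "__main__":
    main()
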