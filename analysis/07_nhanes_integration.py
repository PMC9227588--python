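"""Optional: run the pipeline on a real NHANES 2011-2014 extract.

The published cohort quantities (baseline table cells, cluster marker
means, appendix breakpoints, cluster ANOVA p-values) derive from the
NHANES 2011-2012 and 2013-2014 cycles, which must be downloaded from the
NCHS site; they are not reproducible from synthetic data. This script
documents that path; it does nothing unless an extract is supplied.

Expected input: a merged CSV with one row per participant aged 60+,
mapped onto the package's column dictionary. Typical source variables:
demographics (RIDAGEYR, RIAGENDR, RIDRETH1, DMDMARTL, DMDEDUC2),
examination (BMXBMI), laboratory (LBXSCR creatinine; LBDRFOSI RBC folate;
LBDFOTSI serum total folate; LBXSF1SI 5MeTHF; LBDB12SI vitamin B12;
LBDMMASI MMA; LBXSF6SI UMFA), dietary day-1 totals (DR1TFOLA, DR1TFA,
DR1TFF, DR1TFDFE, DR1TVB12), questionnaire history flags, and the
cognitive module (CFDCST1-3 word-learning trials, CFDCSR delayed recall,
CFDAST animal fluency, CFDDS digit symbol). XPT transport files convert
to CSV with pandas.read_sas or pyreadstat before mapping.

Usage::

    python analysis/07_nhanes_integration.py path/to/nhanes_extract.csv
"""

import sys
from pathlib import Path

from folcog.derivations import apply_eligibility, derive_flags, read_cohort
from folcog.pipeline import RunConfig, run_pipeline


def main() -> None:
    if len(sys.argv) < 2:
        print(__doc__)
        print("no extract supplied; nothing to do.")
        return
    extract = Path(sys.argv[1])
    cohort = derive_flags(read_cohort(extract))
    kept, log = apply_eligibility(cohort)
    print(f"eligible: {len(kept)} of {len(cohort)} "
          f"(exclusions: {log['reason'].value_counts().to_dict()})")
    config = RunConfig(
        output_dir="results/nhanes_run",
        seed=0,
        input_path=extract,
        restarts=10_000,  # full-scale clustering settings
        b=2_000,
    )
    run_pipeline(config)
    print("full pipeline outputs written under results/nhanes_run/")


if __name__ == "__main__":
    main()
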