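"""Baseline characteristics tables.

Builds the Table-1-style comparison of the analysis cohort by vitamin-B12
status (means +/- SD with pooled t-tests; counts (%) with chi-square) and
prints the headline group shares.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from folcog.descriptives import baseline_table, percentage

OUT = Path("results")


def main() -> None:
    adf = pd.read_csv(OUT / "analysis_cohort.csv")
    adf["b12_status"] = np.where(adf["low_b12"] == 1.0, "low", "normal")
    table = baseline_table(adf, "b12_status")
    table.to_csv(OUT / "baseline_by_b12.csv", index=False)

    n = len(adf)
    n_low = int((adf["b12_status"] == "low").sum())
    print(f"analysis cohort n = {n}: low B12 {n_low} ({percentage(n_low, n)}%), "
          f"normal {n - n_low} ({percentage(n - n_low, n)}%)")
    age = table[table["variable"] == "age"].iloc[0]
    print(f"age: low {age['mean_low']:.2f} +/- {age['sd_low']:.2f} vs "
          f"normal {age['mean_normal']:.2f} +/- {age['sd_normal']:.2f} "
          f"(t-test p = {age['pvalue']:.3g})")
    print(f"wrote {len(table)} rows to {OUT / 'baseline_by_b12.csv'}")


if __name__ == "__main__":
    main()
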