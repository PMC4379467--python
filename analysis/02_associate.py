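#!/usr/bin/env python
"""Per-cohort ANCOVA of expression on age and sex, BH FDR control, and
merging into the non-redundant associated set.

Reads the matrices written by 01_simulate.py; writes the merged set and a
per-cohort significance summary to results/, full association tables to
scratch/study/.
"""

from pathlib import Path

import pandas as pd

from agewire import association, io

SCRATCH = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    meta = io.read_metadata(SCRATCH / "metadata.tsv")
    tables = {}
    rows = []
    for label, group in meta.groupby("cohort"):
        expr = io.read_matrix(SCRATCH / f"expression_{label}.tsv")
        table = association.associate_cohort(
            expr[list(group["sample_id"])], group.reset_index(drop=True)
        )
        tables[label] = table
        io.write_matrix(table, SCRATCH / f"association_{label}.tsv")
        rows.append(
            {
                "cohort": label,
                "genes_tested": len(table),
                "sig_age": int(table["sig_age"].sum()),
                "sig_sex": int(table["sig_sex"].sum()),
            }
        )

    merged = association.merge_nonredundant(tables)
    io.write_table(merged, RESULTS / "02_merged_set.tsv")
    summary = pd.DataFrame(rows)
    io.write_table(summary, RESULTS / "02_association_summary.tsv")

    truth = pd.read_csv(SCRATCH / "truth.tsv", sep="\t")
    true_age = set(truth.loc[truth["age_effect"] != 0, "gene"])
    called = set(merged.loc[merged["covariate"] == "age", "gene"])
    print(summary.to_string(index=False))
    print(f"\nmerged set: {(merged['covariate'] == 'age').sum()} age-associated, "
          f"{(merged['covariate'] == 'sex').sum()} sex-associated genes")
    print(f"planted-age recovery: {len(called & true_age)}/{len(true_age)} "
          f"({len(called - true_age)} false calls)")


if __name__ == "__main__":
    main()
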