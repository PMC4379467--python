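#!/usr/bin/env python
"""Simulate the synthetic liver study: two expression cohorts sharing one
ground truth, a planted-module interactome, and a 4-stage rodent series.

Large matrices go to scratch/study/ (inputs for the later steps); a small
summary of what was planted goes to results/.
"""

from pathlib import Path

import pandas as pd

from agewire import io
from agewire.syndata import SyntheticConfig, gen_cohort, gen_interactome, gen_stage_series

SCRATCH = Path("scratch/study")
RESULTS = Path("results")
SEED = 7

def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    config = SyntheticConfig(seed=SEED)
    expr1, meta1, truth = gen_cohort(config, cohort_label="cohort1")
    expr2, meta2, _ = gen_cohort(config, cohort_label="cohort2", truth=truth, seed=SEED + 1)

    module = sorted(truth.loc[truth["age_effect"] != 0, "gene"])
    interactome = gen_interactome(
        truth, module, n_background=500, p_in=0.3, p_out=0.02, seed=SEED + 2
    )
    series = gen_stage_series(truth, stages=[2, 6, 21, 104], noise_sd=0.25, seed=SEED + 3)

    io.write_matrix(expr1, SCRATCH / "expression_cohort1.tsv")
    io.write_matrix(expr2, SCRATCH / "expression_cohort2.tsv")
    io.write_table(pd.concat([meta1, meta2]), SCRATCH / "metadata.tsv")
    io.write_table(truth, SCRATCH / "truth.tsv")
    io.write_table(
        pd.DataFrame(sorted(interactome.edges()), columns=["a", "b"]),
        SCRATCH / "edges.tsv",
    )
    io.write_matrix(series, SCRATCH / "stage_series.tsv")

    summary = pd.DataFrame(
        [
            ("genes", config.n_genes),
            ("samples_per_cohort", config.n_samples),
            ("planted_age_genes", int((truth["age_effect"] != 0).sum())),
            ("planted_age_up", int((truth["age_effect"] > 0).sum())),
            ("planted_sex_genes", int((truth["sex_effect"] != 0).sum())),
            ("interactome_nodes", interactome.number_of_nodes()),
            ("interactome_edges", interactome.number_of_edges()),
        ],
        columns=["quantity", "value"],
    )
    io.write_table(summary, RESULTS / "01_simulation_summary.tsv")
    print(summary.to_string(index=False))
    print(f"\nmatrices written to {SCRATCH}/")


if __name__ == "__main__":
    main()
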