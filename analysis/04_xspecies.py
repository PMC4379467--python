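#!/usr/bin/env python
"""Cross-species concordance: do genes rising (falling) with age in the
human cohorts also rise (fall) across the rodent stage series?

Transfers the merged age calls through a partial ortholog map, calls each
rodent gene's trend by Spearman correlation with stage order, and scores the
directional overlaps with upper-tail hypergeometric probabilities.
"""

from pathlib import Path

import pandas as pd

from agewire import io, xspecies

SCRATCH = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    series = io.read_matrix(SCRATCH / "stage_series.tsv")
    truth = pd.read_csv(SCRATCH / "truth.tsv", sep="\t")
    merged = pd.read_csv(RESULTS / "02_merged_set.tsv", sep="\t")
    merged_age = merged[merged["covariate"] == "age"]

    # partial ortholog map: 3 of every 4 genes have a rodent counterpart
    ortho = {g: g.lower() for i, g in enumerate(truth["gene"]) if i % 4 != 0}
    series.index = [ortho.get(g, g) for g in series.index]

    universe_pairs, _ = xspecies.map_orthologs(set(ortho), ortho)
    uni_trends = {
        rod: xspecies.stage_trend(series.loc[rod].to_numpy(float))
        for _, rod in universe_pairs
    }
    determinate = {r for r, t in uni_trends.items() if t != 0}

    rows = []
    for direction, tag in ((1, "up"), (-1, "down")):
        human = set(merged_age.loc[merged_age["direction"] == direction, "gene"])
        pairs, unmapped = xspecies.map_orthologs(human, ortho)
        trends = {h: uni_trends[r] for h, r in pairs}
        K = sum(1 for t in trends.values() if t != 0)
        k = sum(1 for t in trends.values() if t == direction)
        n_dir = sum(1 for t in uni_trends.values() if t == direction)
        enr = xspecies.concordance_enrichment(k=k, K=K, n=n_dir, N=len(determinate))
        rows.append(
            {
                "human_direction": tag,
                "k_overlap": k,
                "K_human_mapped": K,
                "n_rodent_direction": n_dir,
                "N_universe": len(determinate),
                "p_upper_tail": enr.p,
                "p_display": enr.text,
                "n_unmapped": len(unmapped),
            }
        )
        print(
            f"human {tag}: {k}/{K} mapped genes share the rodent trend "
            f"({len(unmapped)} unmapped); hypergeometric p {enr.text}"
        )
    io.write_table(pd.DataFrame(rows), RESULTS / "04_concordance.tsv")


if __name__ == "__main__":
    main()
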