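"""Cross-species trend concordance and qPCR fold-change arithmetic.

Human age-direction calls are transferred through an ortholog map onto a
short ordered rodent stage series (e.g. liver RNA-seq at 2, 6, 21 and 104
weeks). A gene's rodent trend is the sign of the Spearman correlation of its
expression with stage order, thresholded at |rho| >= 0.5 by default; the
overlap between human-up (or human-down) genes and rodent genes with the
same trend is scored with an upper-tail hypergeometric probability.

Fold changes for qPCR validation use the standard ddCt scheme: per replicate
dCt = Ct_target - Ct_housekeeping, ddCt against the mean dCt of the
reference timepoint, fold = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from agewire.errors import InputError

__all__ = [
    "map_orthologs",
    "stage_trend",
    "EnrichmentResult",
    "concordance_enrichment",
    "ddct_fold_change",
]

#: below this, an upper-tail probability is reported as a bound, not a float
MACHINE_EPS_P = 2.2e-16


def map_orthologs(
    genes: Iterable[str], ortholog_map: Mapping[str, str]
) -> tuple[list[tuple[str, str]], list[str]]:
    """Split ``genes`` into (human, rodent) ortholog pairs and unmapped genes."""
    pairs: list[tuple[str, str]] = []
    unmapped: list[str] = []
    for gene in sorted(set(genes)):
        if gene in ortholog_map:
            pairs.append((gene, ortholog_map[gene]))
        else:
            unmapped.append(gene)
    return pairs, unmapped


def stage_trend(
    values: Sequence[float],
    stage_ages: Sequence[float] | None = None,
    min_abs_rho: float = 0.5,
) -> int:
    """Monotone-trend call for one gene over an ordered stage series.

    Returns +1 / -1 when the Spearman correlation of expression with stage
    order reaches ``min_abs_rho`` in magnitude, else 0; a constant series is
    trendless (0). Only the ordering of stages matters, not their spacing.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise InputError(f"stage series needs >= 3 stages, got {y.size}")
    if stage_ages is not None:
        ages = list(stage_ages)
        if len(ages) != y.size:
            raise InputError("stage_ages length must match values")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise InputError("stage ages must be strictly increasing")
    if np.ptp(y) == 0:
        return 0
    rho = float(stats.spearmanr(np.arange(y.size), y).statistic)
    if rho >= min_abs_rho:
        return 1
    if rho <= -min_abs_rho:
        return -1
    return 0


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric overlap probability.

    ``p`` is the raw float; ``text`` renders sub-machine-precision values as
    the bound "< 2.2e-16" rather than a literal zero.
    """

    k: int
    K: int
    n: int
    N: int
    p: float

    @property
    def text(self) -> str:
        return f"< {MACHINE_EPS_P:g}" if self.p < MACHINE_EPS_P else f"{self.p:.6g}"


def concordance_enrichment(k: int, K: int, n: int, N: int) -> EnrichmentResult:
    """P(X >= k) for the overlap of a K-gene and an n-gene set in an N-gene
    universe: sum_{i>=k} C(K,i) C(N-K, n-i) / C(N, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise InputError(f"need K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise InputError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k=k, K=K, n=n, N=N, p=min(max(p, 0.0), 1.0))


def ddct_fold_change(
    ct: pd.DataFrame, reference_timepoint
) -> pd.DataFrame:
    """Per-timepoint mean fold change and SEM from replicate Ct values.

    ``ct`` columns: timepoint, replicate, target_ct, housekeeping_ct.
    Per replicate, dCt = target - housekeeping; ddCt subtracts the mean dCt
    of the reference timepoint; fold = 2^(-ddCt). SEM is the sample SD over
    replicates divided by sqrt(#replicates).
    """
    required = {"timepoint", "replicate", "target_ct", "housekeeping_ct"}
    missing = required - set(ct.columns)
    if missing:
        raise InputError(f"Ct table missing columns: {sorted(missing)}")
    if ct[["target_ct", "housekeeping_ct"]].isna().any().any():
        bad = ct.loc[ct[["target_ct", "housekeeping_ct"]].isna().any(axis=1)]
        raise InputError(
            f"missing Ct replicate(s) at timepoint(s) {sorted(bad['timepoint'].unique())}"
        )
    counts = ct.groupby("timepoint").size()
    if (counts < 2).any():
        raise InputError(
            f"every timepoint needs >= 2 replicates; short: "
            f"{sorted(counts.index[counts < 2])}"
        )
    if reference_timepoint not in set(ct["timepoint"]):
        raise InputError(f"reference timepoint {reference_timepoint!r} not present")

    work = ct.copy()
    work["dct"] = work["target_ct"].astype(float) - work["housekeeping_ct"].astype(float)
    ref_mean = work.loc[work["timepoint"] == reference_timepoint, "dct"].mean()
    work["fold"] = 2.0 ** (-(work["dct"] - ref_mean))
    grouped = work.groupby("timepoint")["fold"]
    out = pd.DataFrame(
        {
            "mean_fold": grouped.mean(),
            "sem": grouped.std(ddof=1) / np.sqrt(grouped.size()),
            "n_replicates": grouped.size(),
        }
    )
    return out
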