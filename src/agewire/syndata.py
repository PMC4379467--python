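"""Synthetic cohorts, interactomes and stage series with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two-sex cohorts with continuous ages, a subset of genes carrying
linear age slopes and/or additive sex shifts on top of Gaussian noise, an
interactome in which the associated genes form a denser module than the
background, and a short ordered stage series with monotone trends. Every
generator is a pure function of its arguments and seed, so identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from agewire.errors import ConfigurationError

__all__ = ["SyntheticConfig", "gen_cohort", "gen_interactome", "gen_stage_series"]

#: share of age-affected genes given a positive slope (the rest are negative);
#: mirrors the predominance of genes whose expression rises with age in liver.
POSITIVE_FRACTION = 0.6


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic expression cohort.

    Defaults emulate a liver microarray cohort: ~1300 genes on a log2 scale
    with baseline N(8, 2^2), donors aged 1-85 years with a modest male excess,
    and a small fraction of genes carrying age and/or sex effects.
    """

    n_genes: int = 1344
    n_samples: int = 150
    age_min: float = 1.0
    age_max: float = 85.0
    male_fraction: float = 0.6
    frac_age_assoc: float = 0.065
    frac_sex_assoc: float = 0.033
    age_slope: float = 0.05  # log2 expression units per year
    sex_shift: float = 0.5  # log2 expression units, added to males
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("male_fraction", "frac_age_assoc", "frac_sex_assoc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_samples < 1:
            raise ConfigurationError(f"n_samples must be >= 1, got {self.n_samples}")
        if not self.age_min < self.age_max:
            raise ConfigurationError(
                f"age_min must be < age_max, got {self.age_min} >= {self.age_max}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.baseline_sd < 0:
            raise ConfigurationError(f"baseline_sd must be >= 0, got {self.baseline_sd}")


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def gen_cohort(
    config: SyntheticConfig,
    cohort_label: str = "synthetic",
    truth: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one expression cohort.

    Returns ``(expression, metadata, truth)``: a gene x sample log2 expression
    matrix, per-sample metadata (``sample_id``, ``age``, ``sex``, ``cohort``),
    and a truth table with each gene's planted ``age_effect`` (slope per year)
    and ``sex_effect`` (additive shift in males).

    Model per gene g and sample s::

        expr[g, s] = baseline_g + age_effect_g * age_s
                     + sex_effect_g * I(male_s) + N(0, noise_sd^2)

    with ages uniform on [age_min, age_max] and sexes Bernoulli(male_fraction).

    Passing an existing ``truth`` table reuses its gene symbols and planted
    effects so several cohorts can share one ground truth; ``seed`` overrides
    ``config.seed`` for the sampling of ages, sexes, baselines and noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if truth is not None:
        genes = list(truth["gene"])
    else:
        genes = _gene_symbols(config.n_genes)
    n_genes = len(genes)
    samples = [f"{cohort_label}_S{i:04d}" for i in range(1, config.n_samples + 1)]

    ages = rng.uniform(config.age_min, config.age_max, size=config.n_samples)
    male = rng.random(config.n_samples) < config.male_fraction
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "age": ages,
            "sex": np.where(male, "male", "female"),
            "cohort": cohort_label,
        }
    )

    if truth is not None:
        age_effect = truth["age_effect"].to_numpy(float)
        sex_effect = truth["sex_effect"].to_numpy(float)
    else:
        n_age = int(round(config.frac_age_assoc * n_genes))
        n_sex = int(round(config.frac_sex_assoc * n_genes))
        age_idx = rng.choice(n_genes, size=n_age, replace=False)
        sex_idx = rng.choice(n_genes, size=n_sex, replace=False)

        age_effect = np.zeros(n_genes)
        n_pos = int(round(POSITIVE_FRACTION * n_age))
        age_effect[age_idx[:n_pos]] = config.age_slope
        age_effect[age_idx[n_pos:]] = -config.age_slope

        sex_effect = np.zeros(n_genes)
        half = n_sex // 2
        sex_effect[sex_idx[:half]] = config.sex_shift
        sex_effect[sex_idx[half:]] = -config.sex_shift

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, config.n_samples))
    values = (
        baseline[:, None]
        + np.outer(age_effect, ages)
        + np.outer(sex_effect, male.astype(float))
        + noise
    )
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    truth = pd.DataFrame(
        {"gene": genes, "age_effect": age_effect, "sex_effect": sex_effect}
    )
    return expr, meta, truth


def gen_interactome(
    truth: pd.DataFrame,
    assoc_genes: Iterable[str],
    n_background: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> nx.Graph:
    """Planted-module interactome: a denser Erdos-Renyi block on the
    associated genes (edge probability ``p_in``) over a sparse background
    (``p_out`` everywhere else).

    Background nodes are the non-associated genes from ``truth`` (topped up
    with ``BG####`` symbols when ``n_background`` exceeds them).
    """
    for name, v in (("p_in", p_in), ("p_out", p_out)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
    if p_in <= p_out:
        raise ConfigurationError(f"p_in must exceed p_out, got p_in={p_in}, p_out={p_out}")

    assoc = sorted(set(assoc_genes))
    pool = [g for g in truth["gene"] if g not in set(assoc)]
    background = pool[:n_background]
    for i in range(len(background), n_background):
        background.append(f"BG{i + 1:04d}")

    nodes = assoc + background
    assoc_set = set(assoc)
    is_assoc = np.array([g in assoc_set for g in nodes])
    n = len(nodes)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    inside = is_assoc[iu] & is_assoc[ju]
    prob = np.where(inside, p_in, p_out)
    keep = rng.random(len(iu)) < prob

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(
        (nodes[i], nodes[j]) for i, j in zip(iu[keep], ju[keep])
    )
    return graph


def gen_stage_series(
    truth: pd.DataFrame,
    stages: Sequence[float],
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Ordered stage series (one column per stage age) whose per-gene trend
    follows the sign of the planted ``age_effect`` when ``noise_sd`` is 0.
    """
    stages = list(stages)
    if len(stages) < 3:
        raise ConfigurationError(f"stages must have >= 3 entries, got {len(stages)}")
    if any(b <= a for a, b in zip(stages, stages[1:])):
        raise ConfigurationError(f"stages must be strictly increasing, got {stages}")
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")

    rng = np.random.default_rng(seed)
    effects = truth["age_effect"].to_numpy(float)
    values = np.outer(effects, np.asarray(stages, float))
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    cols = [f"stage_{s:g}" for s in stages]
    out = pd.DataFrame(values, index=pd.Index(truth["gene"], name="gene"), columns=cols)
    out.attrs["stage_ages"] = stages
    return out
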