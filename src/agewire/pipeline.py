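"""End-to-end orchestration: synthetic or user-supplied data in, report out.

A run executes: (optional) preprocessing -> per-cohort association -> merge
-> age-binned means and clustering of the age-direction subgroups -> induced
interaction subnetwork vs edge-subsampled null ensemble -> cross-species
trend concordance. One global seed fans out to fixed per-stage child seeds,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import agewire
from agewire import association, io, network, syndata, xspecies
from agewire.errors import AgewireError, ConfigurationError
from agewire.preprocess import preprocess_cohort
from agewire.syndata import SyntheticConfig

__all__ = ["RunConfig", "RunReport", "Finding", "validate_inputs", "run_full"]


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``synthetic`` is true (and ``syn`` holds the generator settings),
    or the real-input paths (expression, metadata, catalog, edges) are all
    set. Thresholds mirror the analysis defaults: p < 0.001 with BH FDR at
    5%, 100 control networks, rodent-trend threshold |rho| >= 0.5.
    """

    out_dir: str = "results/run"
    seed: int = 0
    synthetic: bool = True
    syn: SyntheticConfig = field(default_factory=SyntheticConfig)
    expr_path: str | None = None
    meta_path: str | None = None
    catalog_path: str | None = None
    edges_path: str | None = None
    edges_dialect: str = "tsv2col"
    orthologs_path: str | None = None
    stage_series_path: str | None = None
    preprocess_protocol: str | None = None  # None = input already normalized
    p_thresh: float = 0.001
    fdr: float = 0.05
    gate: str = "ancova"
    n_random: int = 100
    trend_min_abs_rho: float = 0.5

    # synthetic-interactome shape: a denser module over a sparse background
    interactome_p_in: float = 0.3
    interactome_p_out: float = 0.02
    interactome_n_background: int = 500
    stage_ages: tuple[float, ...] = (2.0, 6.0, 21.0, 104.0)
    stage_noise_sd: float = 0.25

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("expr_path", "meta_path", "catalog_path", "edges_path"):
                if getattr(self, name) is None:
                    raise ConfigurationError(
                        f"non-synthetic run requires {name} to be set"
                    )
        if not 0 < self.p_thresh < 1:
            raise ConfigurationError(f"p_thresh must be in (0, 1), got {self.p_thresh}")
        if not 0 < self.fdr <= 1:
            raise ConfigurationError(f"fdr must be in (0, 1], got {self.fdr}")
        if self.n_random < 1:
            raise ConfigurationError(f"n_random must be >= 1, got {self.n_random}")
        if self.synthetic:
            self.syn.validate()

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key=value config file; keyword overrides win."""
        values: dict = {}
        syn_values: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            target = syn_values if key.startswith("syn.") else values
            key = key.removeprefix("syn.")
            target[key] = value
        values.update(overrides)

        def convert(value, anno):
            if anno == "bool":
                return str(value).lower() in ("1", "true", "yes")
            if anno in ("int", "count"):
                return int(value)
            if anno == "float":
                return float(value)
            return value

        kwargs = {}
        for name, f in cls.__dataclass_fields__.items():
            if name in values:
                v = values[name]
                if isinstance(v, str):
                    anno = str(f.type).replace(" ", "")
                    if anno.startswith("bool"):
                        v = convert(v, "bool")
                    elif anno.startswith("int"):
                        v = convert(v, "int")
                    elif anno.startswith("float"):
                        v = convert(v, "float")
                kwargs[name] = v
        if syn_values:
            syn_kwargs = {}
            for name, f in SyntheticConfig.__dataclass_fields__.items():
                if name in syn_values:
                    caster = int if f.type in ("int",) else float
                    syn_kwargs[name] = caster(syn_values[name])
            kwargs["syn"] = SyntheticConfig(**syn_kwargs)
        return cls(**kwargs)


@dataclass
class RunReport:
    seed: int
    version: str
    manifest: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def validate_inputs(config: RunConfig) -> list[Finding]:
    """Pre-flight checks; error findings abort a run before any computation."""
    findings: list[Finding] = []
    try:
        config.validate()
    except ConfigurationError as exc:
        findings.append(Finding("error", str(exc)))
        return findings
    if config.synthetic:
        return findings

    for name in ("expr_path", "meta_path", "catalog_path", "edges_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            findings.append(Finding("error", f"{name} does not exist: {p}"))
    if any(f.level == "error" for f in findings):
        return findings

    expr = io.read_matrix(config.expr_path)
    meta = io.read_metadata(config.meta_path)
    known = set(meta["sample_id"])
    missing = [s for s in expr.columns if s not in known]
    if missing:
        findings.append(
            Finding("error", f"{len(missing)} matrix sample(s) absent from metadata")
        )
    sexes = set(meta["sex"].unique())
    if not sexes <= {"male", "female"}:
        findings.append(Finding("error", f"unexpected sex levels: {sorted(sexes)}"))
    elif len(sexes) < 2:
        findings.append(Finding("error", "only one sex present"))
    if meta["age"].var() == 0:
        findings.append(Finding("error", "age variance is zero"))
    if (meta["age"].min() < 0) or (meta["age"].max() > 120):
        findings.append(Finding("error", "ages outside [0, 120]"))
    if config.catalog_path:
        catalog = io.read_catalog(config.catalog_path)
        uncovered = expr.index.difference(catalog["symbol"])
        if len(uncovered):
            frac = len(uncovered) / len(expr.index)
            findings.append(
                Finding(
                    "warning",
                    f"catalog missing {len(uncovered)} matrix gene(s) ({frac:.0%})",
                )
            )
    return findings


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def run_full(config: RunConfig) -> RunReport:
    """Execute the whole pipeline and write every table under ``out_dir``."""
    findings = validate_inputs(config)
    errors = [f.message for f in findings if f.level == "error"]
    if errors:
        raise ConfigurationError("; ".join(errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=agewire.__version__)
    seeds = _stage_seeds(config.seed)
    stage = "setup"

    def emit(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        if index:
            io.write_matrix(frame, path)
        else:
            io.write_table(frame, path)
        report.manifest.append(name)

    try:
        # ---- data ----------------------------------------------------
        stage = "data"
        if config.synthetic:
            expr1, meta1, truth = syndata.gen_cohort(
                config.syn, cohort_label="cohort1", seed=seeds[0]
            )
            expr2, meta2, _ = syndata.gen_cohort(
                config.syn, cohort_label="cohort2", truth=truth, seed=seeds[1]
            )
            cohorts = {"cohort1": (expr1, meta1), "cohort2": (expr2, meta2)}
            emit(truth, "truth.tsv")
        else:
            expr = io.read_matrix(config.expr_path)
            meta = io.read_metadata(config.meta_path)
            if config.preprocess_protocol:
                expr = preprocess_cohort(expr, config.preprocess_protocol)
            cohorts = {
                label: (expr[group["sample_id"]], group.reset_index(drop=True))
                for label, group in meta.groupby("cohort")
            }
            truth = None
        for label, (e, m) in cohorts.items():
            emit(m, f"metadata_{label}.tsv")
            emit(e, f"expression_{label}.tsv", index=True)

        # ---- association ---------------------------------------------
        stage = "association"
        tables = {}
        for label, (e, m) in cohorts.items():
            table = association.associate_cohort(
                e, m, p_thresh=config.p_thresh, fdr=config.fdr, gate=config.gate
            )
            tables[label] = table
            emit(table, f"association_{label}.tsv", index=True)
            report.counts[f"{label}_sig_age"] = int(table["sig_age"].sum())
            report.counts[f"{label}_sig_sex"] = int(table["sig_sex"].sum())
        merged = association.merge_nonredundant(tables)
        emit(merged, "merged_set.tsv")
        merged_age = merged[merged["covariate"] == "age"]
        merged_sex = merged[merged["covariate"] == "sex"]
        report.counts["merged_age"] = int(len(merged_age))
        report.counts["merged_sex"] = int(len(merged_sex))

        # ---- binning + clustering ------------------------------------
        stage = "binning"
        label0 = sorted(cohorts)[0]
        e0, m0 = cohorts[label0]
        bins = association.bin_ages(m0, width=20.0)
        means = association.bin_means(e0, bins)
        emit(means, "binned_means.tsv", index=True)
        for direction, tag in ((1, "up"), (-1, "down")):
            genes = merged_age.loc[merged_age["direction"] == direction, "gene"]
            genes = [g for g in genes if g in means.index]
            if len(genes) >= 3 and means.shape[1] >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    labels = association.hierarchical_clusters(
                        means.loc[genes], k=min(3, len(genes))
                    )
                cluster_frame = labels.rename("cluster").rename_axis("gene").reset_index()
                emit(cluster_frame, f"clusters_age_{tag}.tsv")

        # ---- network -------------------------------------------------
        stage = "network"
        age_genes = set(merged_age["gene"])
        if config.synthetic:
            module = sorted(truth.loc[truth["age_effect"] != 0, "gene"])
            interactome = syndata.gen_interactome(
                truth,
                assoc_genes=module,
                n_background=config.interactome_n_background,
                p_in=config.interactome_p_in,
                p_out=config.interactome_p_out,
                seed=seeds[2],
            )
        else:
            interactome = network.parse_interactions(
                config.edges_path, dialect=config.edges_dialect
            )
        observed_net = network.induced_subgraph(interactome, age_genes)
        nonassoc = set(interactome.nodes()) - age_genes
        null_source = network.induced_subgraph(interactome, nonassoc)
        report.counts["network_nodes"] = observed_net.number_of_nodes()
        report.counts["network_edges"] = observed_net.number_of_edges()
        report.counts["null_source_nodes"] = null_source.number_of_nodes()
        report.counts["null_source_edges"] = null_source.number_of_edges()
        x = observed_net.number_of_edges()
        if x >= 1 and null_source.number_of_edges() >= x:
            obs_table = network.centrality_table(observed_net)
            emit(obs_table, "centrality_observed.tsv", index=True)
            ensemble = network.sample_null_ensemble(
                null_source, x=x, n=config.n_random, seed=seeds[3]
            )
            comp_rows = []
            for measure in network.MEASURES:
                result = network.compare_centrality(obs_table, ensemble, measure)
                report.comparisons[measure] = result.p_value
                comp_rows.append(
                    {
                        "measure": measure,
                        "observed_median": result.observed_median,
                        "null_median": result.null_median,
                        "u_statistic": result.u_statistic,
                        "p_value": result.p_value,
                    }
                )
            emit(pd.DataFrame(comp_rows), "centrality_comparison.tsv")
        else:
            warnings.warn("network stage skipped: too few observed/null edges")

        # ---- cross-species -------------------------------------------
        stage = "xspecies"
        if config.synthetic:
            series = syndata.gen_stage_series(
                truth, stages=list(config.stage_ages),
                noise_sd=config.stage_noise_sd, seed=seeds[4],
            )
            # deterministic partial map: 3 of every 4 genes have an ortholog
            ortho = {
                g: g.lower() for i, g in enumerate(truth["gene"]) if i % 4 != 0
            }
            series.index = [ortho.get(g, g) for g in series.index]
        elif config.stage_series_path and config.orthologs_path:
            series = io.read_matrix(config.stage_series_path)
            ortho = io.read_ortholog_map(config.orthologs_path)
        else:
            series = None
        if series is not None:
            rows = []
            for direction, tag in ((1, "up"), (-1, "down")):
                human = set(merged_age.loc[merged_age["direction"] == direction, "gene"])
                pairs, unmapped = xspecies.map_orthologs(human, ortho)
                trends = {}
                for hum, rod in pairs:
                    if rod in series.index:
                        trends[hum] = xspecies.stage_trend(
                            series.loc[rod].to_numpy(float),
                            min_abs_rho=config.trend_min_abs_rho,
                        )
                universe_pairs, _ = xspecies.map_orthologs(set(ortho), ortho)
                uni_trends = {
                    rod: xspecies.stage_trend(
                        series.loc[rod].to_numpy(float),
                        min_abs_rho=config.trend_min_abs_rho,
                    )
                    for _, rod in universe_pairs
                    if rod in series.index
                }
                determinate = {r for r, t in uni_trends.items() if t != 0}
                N = len(determinate)
                n_dir = sum(1 for t in uni_trends.values() if t == direction)
                K = sum(1 for t in trends.values() if t != 0)
                k = sum(1 for t in trends.values() if t == direction)
                if N and K and n_dir:
                    enr = xspecies.concordance_enrichment(k=k, K=K, n=n_dir, N=N)
                    rows.append(
                        {
                            "human_direction": tag,
                            "k_overlap": k,
                            "K_human_mapped": K,
                            "n_rodent_direction": n_dir,
                            "N_universe": N,
                            "p_upper_tail": enr.p,
                            "p_display": enr.text,
                            "n_unmapped": len(unmapped),
                        }
                    )
                    report.counts[f"concordance_{tag}_overlap"] = k
                    report.comparisons[f"concordance_{tag}_p"] = enr.p
            if rows:
                emit(pd.DataFrame(rows), "concordance.tsv")

        # ---- report --------------------------------------------------
        stage = "report"
        (out / "report.json").write_text(report.to_json() + "\n")
        report.manifest.append("report.json")
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise AgewireError(f"pipeline failed at stage {stage!r}: {exc}") from exc
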