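"""Interaction subnetworks, centralities, and the edge-resampled null ensemble.

Centrality conventions follow the liver-RBP analysis this package implements:
node and edge betweenness are raw Brandes counts (endpoints excluded,
unordered pairs counted once); closeness uses the convention that a
disconnected pair is assigned distance |V| - 1; the local clustering
coefficient of a degree<2 node defaults to 0 so every node enters the pooled
distributions. Per-measure values are normalized by that measure's maximum
within their own network before any cross-network comparison.

The null model is edge subsampling, not rewiring: each of the (default 100)
control networks consists of x edges drawn uniformly without replacement
from the interactome of non-associated genes, with nodes induced by the
sampled edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from agewire.errors import InputError

__all__ = [
    "parse_interactions",
    "induced_subgraph",
    "degree",
    "local_clustering",
    "all_shortest_paths",
    "closeness",
    "betweenness",
    "edge_betweenness",
    "normalize_by_max",
    "centrality_table",
    "NullEnsemble",
    "sample_null_ensemble",
    "ComparisonResult",
    "compare_centrality",
]

MEASURES = ("degree", "betweenness", "closeness", "clustcoef")

_BIOGRID_COLS = [
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
    "Organism Interactor A",
    "Organism Interactor B",
]


def parse_interactions(path, dialect: str, organism: int = 9606) -> nx.Graph:
    """Read an undirected simple interaction graph from a TSV edge file.

    ``tsv2col``: first two columns are gene symbols. ``biogrid_tab2``: uses
    the Official Symbol Interactor A/B columns and keeps only rows where
    both Organism Interactor ids equal ``organism``. Self-loops are dropped
    and unordered duplicates collapse.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "biogrid_tab2":
        missing = [c for c in _BIOGRID_COLS if c not in table.columns]
        if missing:
            raise InputError(f"BioGRID Tab 2 file missing columns: {missing}")
        keep = (table["Organism Interactor A"] == str(organism)) & (
            table["Organism Interactor B"] == str(organism)
        )
        pairs = table.loc[keep, _BIOGRID_COLS[:2]].to_numpy()
    elif dialect == "tsv2col":
        if table.shape[1] < 2:
            raise InputError("two-column edge file needs at least 2 columns")
        pairs = table.iloc[:, :2].to_numpy()
    else:
        raise InputError(f"unknown edge dialect {dialect!r}")

    graph = nx.Graph()
    graph.add_edges_from((a, b) for a, b in pairs if a != b)
    if graph.number_of_edges() == 0:
        warnings.warn(f"no edges parsed from {path}", stacklevel=2)
    return graph


def induced_subgraph(net: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subnetwork of edges with both endpoints in ``genes``; nodes left with
    no edge are dropped (so an 88-gene set can yield a 47-node network)."""
    genes = set(genes)
    sub = nx.Graph()
    sub.add_edges_from(
        (u, v) for u, v in net.edges() if u in genes and v in genes
    )
    return sub


def degree(net: nx.Graph) -> dict[str, int]:
    return dict(net.degree())


def local_clustering(net: nx.Graph, node) -> float:
    """Fraction of a node's neighbour pairs that are connected; 0 when the
    node has fewer than two neighbours."""
    if node not in net:
        raise InputError(f"node {node!r} not in network")
    return float(nx.clustering(net, node))


def _disconnected_distance(net: nx.Graph) -> float:
    return net.number_of_nodes() - 1


def all_shortest_paths(net: nx.Graph) -> pd.DataFrame:
    """All-pairs BFS distance matrix; disconnected pairs get |V| - 1."""
    nodes = list(net.nodes())
    fill = _disconnected_distance(net)
    dist = pd.DataFrame(float(fill), index=nodes, columns=nodes)
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, d in lengths.items():
            dist.loc[source, target] = float(d)
    return dist


def closeness(net: nx.Graph, node) -> float:
    """(|V| - 1) / sum of distances to every other node, with disconnected
    pairs counted at distance |V| - 1."""
    n = net.number_of_nodes()
    if n < 2:
        raise InputError("closeness needs at least 2 nodes")
    if node not in net:
        raise InputError(f"node {node!r} not in network")
    lengths = nx.single_source_shortest_path_length(net, node)
    fill = _disconnected_distance(net)
    total = sum(lengths.get(other, fill) for other in net.nodes() if other != node)
    return (n - 1) / total


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Raw Brandes node betweenness: unordered pairs counted once, endpoints
    excluded; dependencies accumulate only along realised shortest paths."""
    return {k: float(v) for k, v in nx.betweenness_centrality(net, normalized=False).items()}


def edge_betweenness(net: nx.Graph) -> dict[tuple, float]:
    """Raw shortest-path counts through each edge (unordered pairs once)."""
    return {
        e: float(v)
        for e, v in nx.edge_betweenness_centrality(net, normalized=False).items()
    }


def normalize_by_max(values: np.ndarray) -> np.ndarray:
    """Divide by the maximum; an all-zero vector is returned unchanged with a
    warning (there is nothing to scale to 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    top = values.max()
    if top <= 0:
        warnings.warn("all-zero vector: max-normalization is a no-op", stacklevel=2)
        return values.copy()
    return values / top


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """Per-node centralities plus per-measure max-normalized columns."""
    nodes = list(net.nodes())
    if not nodes:
        raise InputError("empty network")
    table = pd.DataFrame(index=pd.Index(nodes, name="node"))
    deg = degree(net)
    table["degree"] = [deg[v] for v in nodes]
    btw = betweenness(net)
    table["betweenness"] = [btw[v] for v in nodes]
    if net.number_of_nodes() >= 2:
        table["closeness"] = [closeness(net, v) for v in nodes]
    else:
        table["closeness"] = np.nan
    clust = nx.clustering(net)
    table["clustcoef"] = [clust[v] for v in nodes]
    for measure in MEASURES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table[f"normalized_{measure}"] = normalize_by_max(table[measure].to_numpy())
    return table


@dataclass
class NullEnsemble:
    """Edge-subsampled control networks with pooled normalized centralities."""

    members: list[nx.Graph]
    pooled: dict[str, np.ndarray]
    seed: int
    measures: tuple[str, ...] = MEASURES


def sample_null_ensemble(
    source: nx.Graph,
    x: int,
    n: int = 100,
    seed: int = 0,
    measures: Sequence[str] = MEASURES,
) -> NullEnsemble:
    """Build ``n`` control networks of exactly ``x`` edges each, drawn
    uniformly without replacement from ``source``'s edge set.

    Each member's node set is induced by its sampled edges; its centralities
    are computed, max-normalized within the member, and pooled across the
    ensemble per measure.
    """
    edges = sorted(tuple(sorted(e)) for e in source.edges())
    if x > len(edges):
        raise InputError(f"cannot sample x={x} edges from a {len(edges)}-edge source")
    unknown = [m for m in measures if m not in MEASURES]
    if unknown:
        raise InputError(f"unknown centrality measures: {unknown}")
    rng = np.random.default_rng(seed)
    members: list[nx.Graph] = []
    pooled: dict[str, list[np.ndarray]] = {m: [] for m in measures}
    for _ in range(n):
        idx = rng.choice(len(edges), size=x, replace=False)
        member = nx.Graph()
        member.add_edges_from(edges[i] for i in idx)
        members.append(member)
        nodes = list(member.nodes())
        raw: dict[str, np.ndarray] = {}
        if "degree" in measures:
            deg = member.degree()
            raw["degree"] = np.array([deg[v] for v in nodes], float)
        if "clustcoef" in measures:
            clust = nx.clustering(member)
            raw["clustcoef"] = np.array([clust[v] for v in nodes], float)
        if "betweenness" in measures:
            btw = nx.betweenness_centrality(member, normalized=False)
            raw["betweenness"] = np.array([btw[v] for v in nodes], float)
        if "closeness" in measures:
            raw["closeness"] = np.array([closeness(member, v) for v in nodes], float)
        for m in measures:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled[m].append(normalize_by_max(raw[m]))
    return NullEnsemble(
        members=members,
        pooled={m: np.concatenate(v) for m, v in pooled.items()},
        seed=seed,
        measures=tuple(measures),
    )


@dataclass(frozen=True)
class ComparisonResult:
    measure: str
    observed_median: float
    null_median: float
    u_statistic: float
    p_value: float


def compare_centrality(
    observed: pd.DataFrame, ensemble: NullEnsemble, measure: str
) -> ComparisonResult:
    """Two-sided Mann-Whitney U between the observed network's normalized
    node values and the ensemble's pooled values for one measure.

    Exact enumeration when both sides are small (<= 50) and tie-free,
    otherwise the normal approximation with tie correction.
    """
    from scipy import stats

    col = f"normalized_{measure}"
    if col not in observed.columns:
        raise InputError(f"observed table lacks column {col!r}")
    if measure not in ensemble.pooled:
        raise InputError(f"ensemble lacks pooled measure {measure!r}")
    obs = observed[col].to_numpy(float)
    null = ensemble.pooled[measure]
    if obs.size == 0 or null.size == 0:
        raise InputError("both comparison sides must be non-empty")
    combined = np.concatenate([obs, null])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (max(obs.size, null.size) <= 50 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(obs, null, alternative="two-sided", method=method)
    return ComparisonResult(
        measure=measure,
        observed_median=float(np.median(obs)),
        null_median=float(np.median(null)),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
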