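import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from agewire.syndata import SyntheticConfig, gen_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene, 80-sample cohort with planted age and sex effects."""
    config = SyntheticConfig(
        n_genes=300, n_samples=80, frac_age_assoc=0.1, frac_sex_assoc=0.1, seed=11
    )
    expr, meta, truth = gen_cohort(config, cohort_label="small")
    return expr, meta, truth


@pytest.fixture
def two_component_graph():
    """Edge A-B plus isolated node C: the closeness convention fixture."""
    g = nx.Graph()
    g.add_edge("A", "B")
    g.add_node("C")
    return g


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


def random_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    """Seeded G(n, p) with string node labels."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(f"v{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(f"v{i}", f"v{j}")
    return g
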