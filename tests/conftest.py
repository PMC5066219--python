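import networkx as nx
import pytest

from tissuemod.pipeline import RunConfig, run_pipeline
from tissuemod.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The reference synthetic bundle (default study conditions)."""
    return generate_bundle(seed=1)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """Full pipeline run on the reference bundle (200-rep nulls)."""
    cfg = RunConfig(n_reps=200, seed=1)
    return run_pipeline(
        default_bundle.interactome,
        default_bundle.expression,
        default_bundle.disease_sets,
        go=default_bundle.go,
        cfg=cfg,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A miniature bundle for fast mechanical tests."""
    cfg = SyntheticConfig(
        n_genes=400,
        n_tissues=4,
        n_diseases=6,
        n_planted_links=2,
        genes_per_disease=15,
        module_size=6,
    )
    return generate_bundle(cfg, seed=3)


@pytest.fixture
def path_graph():
    g = nx.Graph()
    nx.add_path(g, ["a", "b", "c", "d", "e"])
    return g


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g
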