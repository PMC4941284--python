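import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from netpharm import CompoundTargetScoreMatrix, SyntheticConfig, generate_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL = SyntheticConfig(
    n_genes=150,
    n_reference_drugs=12,
    n_herbs=2,
    compounds_per_herb=4,
    n_pathways=5,
    pathway_size_range=(6, 10),
    ppi_mean_degree=4.0,
    n_disease_genes=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(SMALL)


@pytest.fixture(scope="session")
def small_profiles(small_bundle):
    return CompoundTargetScoreMatrix.compute(
        small_bundle.similarity,
        small_bundle.ppi,
        small_bundle.drug_targets,
        sorted(small_bundle.ppi.nodes()),
    )


@pytest.fixture()
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g
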