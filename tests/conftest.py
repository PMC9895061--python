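import io

import pytest
from hypothesis import settings

from litnet import (
    AbstractCorpus,
    AbstractRecord,
    FixtureConfig,
    GeneList,
    GenePmidMap,
    generate_fixture,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def stream(text: str) -> io.StringIO:
    return io.StringIO(text)


@pytest.fixture
def tiny_gene_list() -> GeneList:
    return GeneList(("PRDX1", "TXN", "KEAP1"))


@pytest.fixture
def tiny_corpus() -> AbstractCorpus:
    return AbstractCorpus(
        [
            AbstractRecord("1", "Oxidative stress", "Reactive Oxygen Species (ROS) are elevated."),
            AbstractRecord("2", "Thioredoxin", "species of reactive fish; oxygen levels measured"),
            AbstractRecord("3", "Redox control", "reactive-oxygen  species signaling in tumors"),
            AbstractRecord("4", "Unrelated", "cell cycle arrest and apoptosis"),
        ]
    )


@pytest.fixture
def tiny_map(tiny_gene_list) -> GenePmidMap:
    return GenePmidMap(
        mapping={"PRDX1": frozenset({"1", "3"}), "TXN": frozenset({"2", "4"}), "KEAP1": frozenset()},
        unmapped=frozenset(),
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One generated planted-signal bundle shared by read-only tests."""
    return generate_fixture(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def small_config() -> FixtureConfig:
    """A scaled-down config for tests that generate many bundles."""
    return FixtureConfig(
        n_genes=40, n_planted=3, abstracts_per_gene=12, planted_prevalence=0.6,
        background_prevalence=0.05, background_edge_prob=0.05, seed=0,
    )
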