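"""Shared fixtures: tiny corpora and a planted two-pool training corpus."""

import numpy as np
import pytest

from dxembed import GeneMap, RecordCorpus, TrainConfig, train_d2d


def make_two_pool_corpus(n_records=2000, seed=7):
    """Records of 5 tokens drawn from one of two disjoint 5-disease pools."""
    rng = np.random.default_rng(seed)
    pools = [[f"A{i}" for i in range(1, 6)], [f"B{i}" for i in range(1, 6)]]
    records = []
    for _ in range(n_records):
        pool = pools[int(rng.integers(0, 2))]
        records.append(tuple(rng.choice(pool, size=5)))
    return RecordCorpus(records)


@pytest.fixture(scope="session")
def two_pool_corpus():
    return make_two_pool_corpus()


@pytest.fixture(scope="session")
def two_pool_config():
    return TrainConfig(dim=16, window=8, negatives=25, epochs=5, seed=7)


@pytest.fixture(scope="session")
def two_pool_model(two_pool_corpus, two_pool_config):
    return train_d2d(two_pool_corpus, two_pool_config, min_count=1)


@pytest.fixture()
def tiny_corpus():
    return RecordCorpus([("A", "B"), ("A", "C"), ("B", "C", "A")])


@pytest.fixture()
def tiny_gene_map():
    return GeneMap({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
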