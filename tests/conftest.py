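import numpy as np
import pytest

from sentstruct import example_parse_trees, synth


@pytest.fixture(scope="session")
def fixture_trees():
    """Packaged passive/active parses of the worked-example sentence."""
    return example_parse_trees()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic configuration shared across tests."""
    return synth.SyntheticConfig(
        n_sets=10, embedding_dim=24, probe_rank=12,
        n_vertices=40, n_participants=6, master_seed=11)


@pytest.fixture(scope="session")
def small_records(small_config):
    return synth.generate_stimuli(small_config)


@pytest.fixture(scope="session")
def planted_embeddings(small_config, small_records):
    B0 = synth.planted_probe_matrix(small_config, seed=101)
    es = synth.generate_embeddings(small_records, B0, noise_sd=0.0, seed=102,
                                   prefixes="full")
    gold = synth.gold_depths(small_records, prefixes="full")
    return B0, es, gold


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
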