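import numpy as np
import pytest

import effconn as ec
from effconn.model import DecoderConfig, ECModel, EncoderConfig

TINY_T = 30


@pytest.fixture(scope="session")
def tiny_encoder_config() -> EncoderConfig:
    return EncoderConfig(n_layers=2, n_heads=2, hidden_dim=16)


@pytest.fixture(scope="session")
def tiny_decoder_config() -> DecoderConfig:
    return DecoderConfig(hidden_dim=8)


@pytest.fixture()
def tiny_model(tiny_encoder_config, tiny_decoder_config) -> ECModel:
    return ECModel(TINY_T, tiny_encoder_config, tiny_decoder_config, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """5 subjects, 5 regions, 40 timepoints of linear coupled dynamics."""
    graph = ec.make_stable_graph(5, 5, 0, 0.6, seed=11)
    opts = ec.SimOptions(coupling_strength=0.6, noise_sd=0.5, subject_graph_flip_prob=0.0)
    cohort, truths = ec.simulate_cohort(graph, 5, 40, opts, seed=11)
    return cohort, truths


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
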