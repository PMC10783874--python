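"""Shared fixtures: synthetic corpora, tiny model configurations, and a
session-scoped pre-trained tiny checkpoint reused by the transfer tests."""

import numpy as np
import pytest

from batmannet import generate_fixtures
from batmannet.model import BatmanNet, ModelConfig
from batmannet.pretrain import TrainConfig, prepare_corpus, pretrain

TINY = ModelConfig(hidden=32, n_encoder=2, n_decoder=1, gnn_hops=2,
                   heads=2, ffn_dim=64)


@pytest.fixture(scope="session")
def fixture_smiles():
    return list(generate_fixtures(256, seed=7))


@pytest.fixture(scope="session")
def small_corpus(fixture_smiles):
    graphs, duals, rejects = prepare_corpus(fixture_smiles[:50])
    assert not rejects
    return graphs, duals


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return BatmanNet(tiny_config, seed=0)


@pytest.fixture(scope="session")
def pretrained_tiny(fixture_smiles, tiny_config):
    """A briefly pre-trained tiny model over 200 fixture molecules; shared by
    the transfer and probe tests."""
    model, history = pretrain(
        fixture_smiles[:200], tiny_config,
        TrainConfig(batch_size=32, total_steps=800, warmup=100,
                    mask_ratio=0.6, seed=11, val_fraction=0.1, eval_every=100))
    return model, history
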