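"""Shared fixtures: tiny synthetic corpora and a small trained model.

Everything is generated programmatically and seeded, so the suite needs
no data files and is fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from iterprot.network import NetworkConfig
from iterprot.pipeline import PipelineConfig, train_iterative
from iterprot.synthetic_data import SyntheticConfig, generate_corpus

#: Short training schedule for fixture models: the 4-rate ladder is kept,
#: epochs are cut so unit tests run in seconds.
TINY_NET = NetworkConfig(ae_epochs=1, bp_epochs_per_rate=2)


@pytest.fixture(scope="session")
def tiny_corpus():
    cfg = SyntheticConfig(n_proteins=8, length_range=(20, 34), seed=42)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def tiny_records(tiny_corpus):
    return [rec for rec, _ in tiny_corpus]


@pytest.fixture(scope="session")
def tiny_profiles(tiny_corpus):
    return [prof for _, prof in tiny_corpus]


@pytest.fixture(scope="session")
def tiny_model(tiny_records, tiny_profiles):
    cfg = PipelineConfig(n_iterations=2, network=TINY_NET, seed=7)
    return train_iterative(tiny_records, tiny_profiles, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
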