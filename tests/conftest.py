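"""Shared fixtures: tiny corpora for unit tests and the session-scoped
trained desk-scale model used by the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from phanet.model import AssociationModel, ModelConfig
from phanet.synthetic import SyntheticConfig, generate_corpus, holdout_split
from phanet.training import GenomeStore, TrainConfig, train


def random_dna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small planted-signal corpus: 6 hosts (3 clades), 18 phages."""
    cfg = SyntheticConfig(n_host_clades=3, hosts_per_clade=2, phages_per_host=3,
                          host_genome_length=12_000, phage_genome_length=6_000,
                          signal_strength=0.9, seed=5)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def tiny_store(tiny_corpus):
    return GenomeStore.from_records(tiny_corpus.hosts + tiny_corpus.phages)


@pytest.fixture(scope="session")
def default_corpus():
    """The default-condition corpus (signal 0.8) used by end-to-end checks."""
    return generate_corpus(SyntheticConfig(signal_strength=0.8, seed=0))


@pytest.fixture(scope="session")
def default_store(default_corpus):
    return GenomeStore.from_records(default_corpus.hosts + default_corpus.phages)


@pytest.fixture(scope="session")
def trained_desk_model(default_corpus, default_store):
    """Desk-scale model trained on the default corpus; shared by tests.

    Returns (model, train_pairs, heldout_pairs, history).
    """
    tr, te = holdout_split(default_corpus, 0.2, seed=0)
    model = AssociationModel(ModelConfig.desk_scale(seed=0))
    model, hist = train(model, tr, default_store, TrainConfig.desk_scale(seed=0),
                        validation_pairs=te,
                        host_pool=[h.id for h in default_corpus.hosts])
    return model, tr, te, hist
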