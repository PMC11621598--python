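"""Shared fixtures.

The expensive end-to-end fixture (`trained_model`) trains one reduced
classifier on the default imbalanced planted-motif dataset and is
shared, session-scoped, by the interpretation and acceptance tests.
"""

import numpy as np
import pytest

from dnamod.network import MethylationClassifier, ModelConfig
from dnamod.records import SequenceRecord, encode_dataset
from dnamod.simulate import SyntheticSpec, generate_dataset
from dnamod.training import TrainConfig, train

REDUCED_CONFIG = dict(
    embed_dim=32, n_resnet_blocks=2, n_attention_blocks=1, n_heads=8, seed=1
)


def make_record(sequence=None, label="6mA", rec_id="r1", center=None):
    """A valid 41-nt record; the central base is forced to the class chemistry."""
    if sequence is None:
        sequence = "ACGT" * 10 + "A"
    if center is None:
        center = "A" if label in ("6mA", "6mA-neg") else "C"
    sequence = sequence[:20] + center + sequence[21:]
    return SequenceRecord(id=rec_id, sequence=sequence, label=label)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    return generate_dataset(default_spec)


@pytest.fixture(scope="session")
def trained_model(default_dataset):
    """Reduced-config classifier trained on the default planted-motif data."""
    model = MethylationClassifier(ModelConfig(**REDUCED_CONFIG))
    history = train(
        model,
        default_dataset,
        TrainConfig(epochs=60, learning_rate=3e-3, patience=10, seed=1),
    )
    return model, history


@pytest.fixture(scope="session")
def heldout_dataset():
    counts = {"4mC": 100, "5hmC": 20, "5mC": 100, "6mA": 100, "6mA-neg": 100}
    return generate_dataset(SyntheticSpec(counts=counts, seed=1007))


@pytest.fixture(scope="session")
def heldout_encoded(heldout_dataset):
    return encode_dataset(heldout_dataset)
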