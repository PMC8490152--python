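import numpy as np
import pytest

from regformer.model import SeqToTracksModel, toy_config
from regformer.synthetic import RegulatoryGrammar, make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_model():
    """A very small trunk (4 kb input, 4 pooling stages) for fast unit tests."""
    cfg = toy_config(
        channels=16,
        conv_blocks=4,
        transformer_blocks=1,
        heads=2,
        key_size=4,
        value_size=8,
        positional_features=6,
        input_length=4096,
        crop_bins=4,
        head_widths={"human": 3, "mouse": 2},
        seed=7,
    )
    return SeqToTracksModel(cfg)


@pytest.fixture(scope="session")
def tiny_onehot(tiny_model, rng):
    L = tiny_model.cfg.input_length
    return np.eye(4, dtype="float32")[rng.integers(0, 4, L)]


@pytest.fixture(scope="session")
def small_dataset():
    """16 short loci with nearby enhancers, usable for quick training runs."""
    grammar = RegulatoryGrammar(enhancer_distance_range=(1500, 2500), lambda0=8.0)
    return make_dataset(
        grammar,
        16,
        8192,
        split_fractions={"train": 0.75, "validation": 0.125, "test": 0.125},
        seed=11,
        n_enhancers=1,
        allow_insulators=False,
    )
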