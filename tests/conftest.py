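import numpy as np
import pytest

from acpseg import ModelConfig, ACPTransUNet, generate_dataset, DatasetSplit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """One initialised tiny network shared by read-only tests."""
    model = ACPTransUNet(ModelConfig.tiny()).initialize(np.random.default_rng(7))
    model.eval()
    return model


@pytest.fixture(scope="session")
def phantom_bench():
    """Eight 64x64 phantom pairs with an all-train split."""
    pairs = generate_dataset(8, size=64, seed=0)
    split = DatasetSplit(tuple(p[0] for p in pairs), (), ())
    return pairs, split
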