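import numpy as np
import pytest

from fedaar.datasets import SynthConfig, channel_stats, generate_federation, normalise
from fedaar.nn import ModelSpec


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    return ModelSpec(n_classes=4, window_len=40, feature_dim=8, hidden=(4, 6), init_seed=7)


@pytest.fixture(scope="session")
def tiny_federation():
    """Three small normalised clients + test subject, 4 classes, 40-step windows."""
    cfg = SynthConfig(
        n_clients=3, n_classes=4, windows_per_client=80, window_len=40, seed=11
    )
    clients, test = generate_federation(cfg)
    stats = channel_stats(clients)
    return [normalise(c, stats) for c in clients], normalise(test, stats)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
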