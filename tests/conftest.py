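import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from echoforce import VirtualPhantom, train_quality_model

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom():
    return VirtualPhantom()


@pytest.fixture(scope="session")
def reference(phantom):
    return phantom.reference


@pytest.fixture(scope="session")
def trained_model(phantom):
    """Gated SVM trained on a modest default-phantom dataset."""
    dataset = phantom.generate_dataset(n_per_class=100, seed=7)
    train_set, _ = dataset.split(train_frac=0.8, seed=7)
    return train_quality_model(train_set, phantom.reference, seed=7)


def random_frame(rng: np.random.Generator, shape=(32, 32)) -> np.ndarray:
    return rng.integers(0, 256, size=shape, dtype=np.uint8)
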