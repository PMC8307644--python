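import numpy as np
import pytest

from drgrade import BackboneSpec, SyntheticDatasetSpec, build_model, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small long-tailed synthetic dataset shared across tests."""
    spec = SyntheticDatasetSpec(class_counts=(100, 10, 21, 3, 3), seed=7)
    return generate_dataset(spec)


@pytest.fixture()
def tiny_model():
    return build_model(
        BackboneSpec("tiny", output_channels=16),
        BackboneSpec("tiny", output_channels=24, width=10),
        d=256, num_classes=5, seed=0,
    )
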