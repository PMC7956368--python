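import numpy as np
import pytest

from dissimspace.data import LabeledImage
from dissimspace.siamese import ArchitectureSpec, LayerSpec
from dissimspace.synthetic import GeneratorConfig, make_dataset


def tiny_architecture(input_size: int = 20, embed: int = 8) -> ArchitectureSpec:
    """A minimal conv-pool-FC backbone for fast unit tests."""
    return ArchitectureSpec(1, [
        LayerSpec("input", filter_size=input_size),
        LayerSpec("conv", filter_size=3, num_filters=4),
        LayerSpec("relu"),
        LayerSpec("max_pool", filter_size=2, stride=2),
        LayerSpec("fully_connected", out_units=embed),
    ], embedding_dim=embed)


@pytest.fixture(scope="session")
def tiny_arch() -> ArchitectureSpec:
    return tiny_architecture()


@pytest.fixture(scope="session")
def small_dataset() -> list[LabeledImage]:
    """2 classes x 10 small images with strong texture separation."""
    return make_dataset(GeneratorConfig(classes=2, per_class=10, side=20,
                                        separation=2.0, noise_sd=0.2, seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
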