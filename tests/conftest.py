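import numpy as np
import pytest

from stripeid import ArchConfig, SyntheticConfig, generate_dataset
from stripeid.preprocessing import records_to_arrays, split_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_arch():
    return ArchConfig.tiny(n_classes=12)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """The default desk-scale population: 12 individuals, 10 images/part."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def synthetic_arrays(synthetic_dataset):
    """(Xtr, ytr), (Xte, yte), classes for the default synthetic population."""
    train, test = split_dataset(synthetic_dataset, (4, 1), seed=0)
    Xtr, ytr, classes = records_to_arrays(train, 96)
    Xte, yte, _ = records_to_arrays(test, 96, classes)
    return (Xtr, ytr), (Xte, yte), classes
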