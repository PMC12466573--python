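import pytest

from regulonkit.core import PipelineConfig
from regulonkit.synth import generate_dataset


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset (seed 11) shared across slow tests."""
    return generate_dataset(seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset for tests that only need structure, not power."""
    return generate_dataset(seed=3, n_genes=60, n_targets=12, n_noise_peaks=20)
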