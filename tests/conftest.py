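import numpy as np
import pytest

from hhocnn.phantom import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_tumor_spec():
    """Noiseless phantom with a tumor blob (three-intensity template)."""
    return PhantomSpec(tumor=True, noise_sigma=0.0, salt_pepper=0.0, seed=5)


@pytest.fixture
def noisy_template():
    """The default study conditions: moderate Gaussian noise + 2% impulses."""
    return PhantomSpec(noise_sigma=4.0, salt_pepper=0.02)


@pytest.fixture(scope="session")
def small_dataset():
    template = PhantomSpec(noise_sigma=4.0, salt_pepper=0.02)
    return generate_dataset(10, 0.5, template, seed=42)
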