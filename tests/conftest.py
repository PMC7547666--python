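import numpy as np
import pytest

from specselect.synthetic import generate, reduced_benchmark_config


@pytest.fixture(scope="session")
def benchmark_data():
    """Reduced-scale two-band spectra (p=301) with ground truth, seed 0."""
    ds, truth = generate(reduced_benchmark_config(seed=0))
    return ds, truth


@pytest.fixture(scope="session")
def quiet_benchmark_data():
    """Same design at instrument-level noise, for high-SNR unit checks."""
    ds, truth = generate(reduced_benchmark_config(seed=0, noise_sd=2e-4))
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
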