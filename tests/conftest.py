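import numpy as np
import pytest

from pztpas.simulate import AcquisitionMode, NoiseParams, generate_dataset
from pztpas.spectral import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def fixed_dataset():
    """One 80-record fixed-mode dataset at default study conditions."""
    return generate_dataset(80, AcquisitionMode.FIXED,
                            noise=NoiseParams.for_mode("fixed", seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise dataset: spectra are a deterministic function of glucose."""
    noise = NoiseParams(additive_sd=0.0, gain_jitter_sd=0.0, band_amplitude_jitter_sd=0.0,
                        baseline_drift_sd=0.0, subject_band_shift_sd=0.0, ref_noise_sd=0.0,
                        seed=0)
    return generate_dataset(80, AcquisitionMode.FIXED, noise=noise)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250901)
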