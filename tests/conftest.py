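import numpy as np
import pytest

from tandemgc.gc2d import TICImage
from tandemgc.synth import SynthConfig, build_spectral_library, make_study_design


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small, fast acquisition grid used by unit tests (125 samples/mod)."""
    return SynthConfig(modulation_period=2.5, acquisition_rate=50.0,
                       n_modulations=120, mz_range=(45, 194))


@pytest.fixture
def quiet_config():
    """Noiseless, jitter-free variant for exact-recovery tests."""
    return SynthConfig(modulation_period=2.5, acquisition_rate=50.0,
                       n_modulations=120, mz_range=(45, 194),
                       rt_jitter_1d=0.0, rt_jitter_2d=0.0,
                       noise_sigma_70=0.0, noise_sigma_12=0.0,
                       shot_noise=False)


@pytest.fixture
def small_library():
    return build_spectral_library(8, seed=42, mz_range=(45, 194),
                                  include_named=False)


@pytest.fixture
def separated_library():
    """8 compounds spread evenly over both retention dimensions so no pair
    co-elutes on the tiny test grid."""
    lib = build_spectral_library(8, seed=42, mz_range=(45, 194),
                                 include_named=False)
    for k, entry in enumerate(lib):
        entry.ri = 1000.0 + 180.0 * k
        entry.two_d_time = 0.6 + 0.22 * k
    return lib


@pytest.fixture
def single_run_design():
    return make_study_design(1, 0, 0, 1, 1)


def make_image(array, modulation_period=2.5, acquisition_rate=50.0, channel="70eV"):
    return TICImage(image=np.asarray(array, dtype=float),
                    modulation_period=modulation_period,
                    acquisition_rate=acquisition_rate, channel=channel)


@pytest.fixture
def image_factory():
    return make_image


def gaussian_blob(shape, center, sigmas, volume):
    """2D Gaussian with an (approximately) specified total volume."""
    ii = np.arange(shape[0])[:, None]
    jj = np.arange(shape[1])[None, :]
    w = np.exp(-0.5 * (((ii - center[0]) / sigmas[0]) ** 2
                       + ((jj - center[1]) / sigmas[1]) ** 2))
    return volume * w / w.sum()


@pytest.fixture
def blob_factory():
    return gaussian_blob
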