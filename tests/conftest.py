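import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sipraman as sr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_table() -> sr.BandTable:
    return sr.load_band_table("reference_strains")


@pytest.fixture(scope="session")
def noiseless_config(reference_table) -> sr.SimConfig:
    """Deterministic generator: no noise, no jitter, no amplitude spread."""
    return sr.SimConfig(
        band_table=reference_table,
        snr=float("inf"),
        jitter_sd=0.0,
        intensity_cv=0.0,
        seed=0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_spectrum(axis, intensities, cell_id="cell", **kwargs) -> sr.Spectrum:
    return sr.Spectrum(cell_id=cell_id, axis=np.asarray(axis, float),
                       intensities=np.asarray(intensities, float), **kwargs)


@pytest.fixture(scope="session")
def toy_uniform() -> sr.Spectrum:
    """Flat-noise-free toy spectrum: a Lorentzian on a uniform grid."""
    x = np.arange(500.0, 1801.0)
    y = 1.0 / (1.0 + ((x - 1000.0) / 6.0) ** 2)
    return sr.Spectrum(cell_id="toy", axis=x, intensities=y)
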