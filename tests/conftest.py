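import numpy as np
import pytest

from corestrat import (CFCSModel, SyntheticConfig, estimate_supported,
                       generate_core)


@pytest.fixture(scope="session")
def noise_free_core():
    """Default-geometry core with every noise source switched off."""
    cfg = SyntheticConfig(seed=0, activity_cv=0.0, pigment_noise_sd=0.0,
                          spectra_noise_sd=0.0)
    table, cube, truth = generate_core(cfg)
    return cfg, table, cube, truth


@pytest.fixture(scope="session")
def default_core():
    """Default study conditions (10% activity noise, lognormal pigment
    noise, Poisson counts), seed 0."""
    cfg = SyntheticConfig(seed=0)
    table, cube, truth = generate_core(cfg)
    return cfg, table, cube, truth


@pytest.fixture()
def dated_profile(noise_free_core):
    """Noise-free activity profile with the true supported baseline set,
    so dating errors isolate the age-model arithmetic."""
    cfg, table, _, _ = noise_free_core
    prof = table.activity
    prof.supported, prof.supported_err = cfg.supported_pb210, 0.0
    return cfg, prof


@pytest.fixture()
def linear_age_model():
    """Simple linear chronology: 2018 CE at the surface, 1918 at 20 cm."""
    from corestrat import AgeModel

    depth = np.linspace(0.0, 20.0, 21)
    age = 2018.0 - 5.0 * depth
    return AgeModel(depth=depth, age=age, age_lo=age - 2, age_hi=age + 2,
                    method="CFCS",
                    sed_rate_cm_yr=np.full_like(depth, 0.2))
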