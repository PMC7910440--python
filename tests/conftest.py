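import numpy as np
import pytest

from radh2 import column_from_lithology
from radh2.synthetic import exponential_rate_field, make_porewater_profile


@pytest.fixture(scope="session")
def clay_column():
    """A South-Pacific-style thin abyssal-clay column over old basement."""
    return column_from_lithology(
        "abyssal_clay", water_depth_m=5000.0, thickness_m=70.0, basement_age_ma=100.0
    )


@pytest.fixture(scope="session")
def o2_scenario():
    """Forward-modelled oxic porewater profile with known consumption rates.

    Exponentially depth-decaying net O2 consumption (surface rate
    2e-11 mol cm^-3 yr^-1, e-folding 8 m) in a 30-m column, sampled at 25
    depths; the deliberately noise-free variant for exact-recovery checks.
    """
    field = exponential_rate_field(2e-11, 8.0)
    profile, truth = make_porewater_profile(
        field, Z_m=30.0, noise_sd_uM=0.0, seed=11, n_points=25
    )
    return field, profile, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
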