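import dataclasses

import pytest

from hgscreen import (
    default_parameters,
    synth_life_table,
    synth_utility_norms,
)
from hgscreen.parameters import AgeGroupExposure, PercentileAnchor


@pytest.fixture(scope="session")
def ps():
    """Base-case parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def lt():
    """Default synthetic period life table."""
    return synth_life_table()


@pytest.fixture(scope="session")
def un():
    """Default synthetic utility norms."""
    return synth_utility_norms()


@pytest.fixture(scope="session")
def collapsed_ps(ps):
    """Parameter set whose nine PSA marginals are (near) point masses at
    the deterministic values: degenerate-uncertainty edge case."""
    tight = (
        AgeGroupExposure("20-39", 0.66, (0.6599, 0.6601),
                         (PercentileAnchor(75, 1.6, (1.5999, 1.6001)),)),
        AgeGroupExposure("40-59", 0.82, (0.8199, 0.8201),
                         (PercentileAnchor(75, 1.7, (1.6999, 1.7001)),
                          PercentileAnchor(90, 2.9, (2.8999, 2.9001)))),
    )
    return dataclasses.replace(
        ps,
        exposure_groups=tight,
        ratio_ci=(1.6999, 1.7001),            # log-midpoint = 1.7
        effect_gamma_shape=1e8,
        effect_gamma_scale=0.094 / 1e8,       # mean = deterministic effect
        p_success_beta=(6e6, 1e6),
        effectiveness_beta=(11.6e6, 9.2e6),
        mmr_disutility_sd=1e-9,
    )
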