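import numpy as np
import pytest

import zitpseq as zq


@pytest.fixture(scope="session")
def tiny_spec():
    """Small trial (N=160, interim at 80) for fast end-to-end checks."""
    return zq.scenario_spec(4, N_max=160, interim_sizes=(80,))


@pytest.fixture(scope="session")
def tiny_null_spec():
    """Small null-effect trial: posterior exceedance stays far from 1."""
    return zq.scenario_spec(1, N_max=160, interim_sizes=(80,))


@pytest.fixture(scope="session")
def tiny_settings():
    return zq.McmcSettings(chains=2, burn_in=300, keep=600, seed=0)


@pytest.fixture(scope="session")
def reduced_settings():
    return zq.McmcSettings.reduced(seed=7)


@pytest.fixture(scope="session")
def scenario1_cohort():
    """One n=1800 cohort under the null scenario."""
    return zq.generate_cohort(zq.scenario_spec(1), 1800, seed=424242)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)
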