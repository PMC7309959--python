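import numpy as np
import pytest

import ra223cea as r


@pytest.fixture(scope="session")
def base_config():
    return r.load_config(None)


@pytest.fixture(scope="session")
def base_result(base_config):
    return r.evaluate_base(base_config)


@pytest.fixture(scope="session")
def radium_trace(base_config):
    return r.build_trace(
        base_config.curve("OS", r.ARM_RADIUM),
        base_config.curve("PFS", r.ARM_RADIUM),
        base_config.curve("SSE", r.ARM_RADIUM),
        horizon_weeks=base_config.horizon_weeks,
    )


@pytest.fixture(scope="session")
def bsc_trace(base_config):
    return r.build_trace(
        base_config.curve("OS", r.ARM_BSC),
        base_config.curve("PFS", r.ARM_BSC),
        base_config.curve("SSE", r.ARM_BSC),
        horizon_weeks=base_config.horizon_weeks,
    )


def random_lognormal_curve(rng: np.random.Generator) -> r.SurvivalCurve:
    """A lognormal law with a median between ~5 and ~150 weeks."""
    mu = rng.uniform(1.5, 5.0)
    log_sigma = rng.uniform(-0.7, 0.4)
    return r.SurvivalCurve("lognormal", mu, log_sigma)
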