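import numpy as np
import pytest

from crtscreen import SimConfig, gen_covariates, gen_grna_indicators, gen_zinb_expression


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def null_screen(sim_config):
    """One simulated null screen: confounded gRNA presence, NB expression."""
    rng = np.random.default_rng(12345)
    Z = gen_covariates(1000, sim_config, rng)
    x = gen_grna_indicators(Z, sim_config.tau, rng)
    y = gen_zinb_expression(Z, x, sim_config.beta, alpha=1.0, lam=0.0, seed=rng)
    assert x.sum() >= 10 and y.sum() > 0
    return Z, x, y
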