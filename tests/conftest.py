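import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermopred as tp
from thermopred.dhmm import DHMMPosterior, DHMMSpec

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: master seed for every stochastic test; per-test streams are spawned from it
MASTER_SEED = 0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recovery_truth():
    """Study-scale generating values for sampler-recovery checks."""
    return tp.TrueParameters.from_correlations(
        beta0=0.0,
        gamma0=-0.5,
        sd_intercept=0.8,
        sd_time=0.2,
        omega=0.4,
        r_intercept_omega=-0.6,
    )


@pytest.fixture(scope="session")
def study_scale_fit(recovery_truth):
    """One DHMM fit on 36 individuals x 6 occasions, reused across tests."""
    cfg = tp.SimulationConfig(n_individuals=36, rng_seed=11)
    df = tp.simulate_trait_table(cfg, recovery_truth, n_occasions=6)
    post = tp.sample_dhmm(
        DHMMSpec.minimal("y"), df,
        chains=4, iterations=1500, warmup=500, thin=1, seed=11,
    )
    return df, post


def make_posterior(n_draws=200, n_individuals=2, **param_draws) -> DHMMPosterior:
    """Hand-built posterior container for formula-level tests.

    Scalar values are broadcast to constant draw vectors; arrays must have
    length ``n_draws``.
    """
    params = {}
    for name, val in param_draws.items():
        arr = np.asarray(val, dtype=float)
        if arr.ndim == 0:
            arr = np.full(n_draws, float(arr))
        params[name] = arr.reshape(1, n_draws)
    return DHMMPosterior(
        spec=DHMMSpec.minimal("y"),
        params=params,
        random_effects=np.zeros((1, n_draws, n_individuals, 3)),
        individuals=np.arange(1, n_individuals + 1),
        accept_rates=(1.0,),
    )


@pytest.fixture
def fake_posterior():
    return make_posterior
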