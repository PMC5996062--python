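import numpy as np
import pytest

import ohga


@pytest.fixture(scope="session")
def small_cohort():
    """Fully observed cohort of 120 subjects under the default scenario."""
    cfg = ohga.GeneratorConfig(n_subjects=120, seed=42)
    return ohga.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def po_cohort():
    """Cohort from the pure proportional-odds scenario (no lag dynamics)."""
    cfg = ohga.GeneratorConfig(
        n_subjects=400, seed=7, true_params=ohga.TrueParams.for_proportional_odds()
    )
    return ohga.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def quick_mcmc(**kw):
    defaults = dict(n_chains=4, n_warmup=100, n_draws=200, max_extensions=1, strict=False)
    defaults.update(kw)
    return ohga.MCMCConfig(**defaults)
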