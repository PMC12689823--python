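import numpy as np
import pytest

import sskim


@pytest.fixture(scope="session")
def small_params():
    """Weakly coupled 3-neuron, 20-bin GP trajectory (fixed seed)."""
    rng = np.random.default_rng(42)
    fields = rng.normal(-1.0, 0.5, (3, 20))
    couplings = rng.normal(0.0, 0.25, (3, 3, 20))
    return sskim.ParamTrajectory(fields=fields, couplings=couplings)


@pytest.fixture(scope="session")
def small_spikes(small_params):
    return sskim.simulate_spikes(small_params, L=100, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_spikes):
    cfg = sskim.FitConfig(max_em_iter=30, em_rel_tol=1e-5)
    posterior, hypers, ll = sskim.fit_em(small_spikes, cfg)
    return posterior, hypers, ll
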