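import numpy as np
import pytest

from ozflux.io import RunConfig, SiteMeta
from ozflux.pipeline import analyze
from ozflux.synthetic import TruthParams, gen_halfhourly_truth, gen_meteorology

NOISELESS = {"flux": 0.0, "ta": 0.0, "o3": 0.0}


@pytest.fixture(scope="session")
def site():
    return SiteMeta()


@pytest.fixture(scope="session")
def noiseless_world(site):
    """20 rain-free days with zero observation noise plus its truth sidecar."""
    params = TruthParams(seed=11, noise_sd=dict(NOISELESS), rain_rate=0.0)
    met = gen_meteorology(20, params, site)
    obs, truth = gen_halfhourly_truth(met, params, site)
    return params, obs, truth


@pytest.fixture(scope="session")
def noiseless_analysis(site, noiseless_world):
    _, obs, _ = noiseless_world
    return analyze(obs, site, RunConfig(site=site))


@pytest.fixture(scope="session")
def noisy_world(site):
    """62-day default world: 5% flux noise, rain events, u* suppression."""
    params = TruthParams(seed=7)
    met = gen_meteorology(62, params, site)
    obs, truth = gen_halfhourly_truth(met, params, site, ustar_suppress=0.09)
    return params, obs, truth


@pytest.fixture(scope="session")
def noisy_analysis(site, noisy_world):
    _, obs, _ = noisy_world
    return analyze(obs, site, RunConfig(site=site))
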