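import numpy as np
import pytest

from wavegrn import grn_model as gm


@pytest.fixture(scope="session")
def default_profile():
    return gm.make_speed_profile(100, "linear")


@pytest.fixture(scope="session")
def default_sim(default_profile):
    """Intact circuit, strong static enhancers, default grid/gradient/ICs."""
    return gm.simulate(gm.DEFAULT_PARAMS, default_profile, record_every=10)


@pytest.fixture(scope="session")
def weak_static_sim(default_profile):
    """Intact circuit with halved static-enhancer strengths."""
    return gm.simulate(gm.WEAK_STATIC_PARAMS, default_profile, record_every=10)


@pytest.fixture(scope="session")
def imaging_benchmark_results():
    """Full imaging-chain benchmark on two synthetic movies (slow; shared)."""
    from wavegrn import reproduce as rep

    return rep.imaging_benchmark(seed=11, snr=5.0, n_nuclei=50, frames=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
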