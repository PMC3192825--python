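import numpy as np
import pytest

from linksel import wf_simulator as wf


@pytest.fixture(scope="session")
def small_equilibrium():
    """A small stationary neutral population (session-cached)."""
    lay = wf.build_layout(scale=0.1)
    return wf.run_equilibrium(lay, N=10_000, rate=1.0, lam=100, gens=1200,
                              seed=42)


@pytest.fixture(scope="session")
def small_replicate():
    """One small neutral split replicate (session-cached)."""
    lay = wf.build_layout(scale=0.1)
    return wf.run_replicate(
        lay, wf.DemographicModel(bottleneck=False), wf.neutral_model(),
        None, rate=1.0, seed=7, lam=100,
    )
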