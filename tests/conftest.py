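import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loadscape.simulate import (
    LandscapeParams,
    SimParams,
    simulate_genotypes,
    simulate_landscape,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_sim_params(seed=0, **kw):
    """Scaled-down simulation for fast unit tests."""
    base = dict(
        n_pop_a=8,
        n_pop_b=10,
        ne_ancestral=100,
        ne_bottleneck=8,
        t_split=150,
        t_bottleneck=60,
        t_recovery=10,
        burn_in=300,
        n_sites={"synonymous": 300, "missense": 300, "lof": 250, "intergenic": 500},
        seed=seed,
    )
    base.update(kw)
    return SimParams(**base)


@pytest.fixture(scope="session")
def default_sim():
    return simulate_genotypes(SimParams(seed=0))


@pytest.fixture(scope="session")
def default_landscape(default_sim):
    present, futures, samples = simulate_landscape(
        LandscapeParams(seed=1), default_sim.samples
    )
    return present, futures, samples


@pytest.fixture(scope="session")
def polarized(default_sim):
    from loadscape.polarize import polarize_result

    dosage, seg = polarize_result(default_sim)
    return dosage, seg


def derived_freq(dosage, mask):
    sub = dosage[mask]
    called = sub >= 0
    n = 2 * called.sum(axis=0)
    d = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, d / np.maximum(n, 1), np.nan)
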