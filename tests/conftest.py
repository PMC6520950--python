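import numpy as np
import pytest

from repairsurv import catalog as cat
from repairsurv import synthetic


@pytest.fixture(scope="session")
def packaged_catalog():
    return cat.load_packaged_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic residual-signal cohort shared across tests."""
    cfg = synthetic.SimulationConfig(n_samples=300, seed=42)
    return synthetic.simulate_cohort(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def brute_force_logrank(time, event, group):
    """Independent logrank oracle: explicit risk-set table per event time.

    Walks every distinct event time, forms the 2x2 risk-set table, and sums
    observed-minus-expected with the hypergeometric variance.  Slow on
    purpose; no shared code with the package routine.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    O_E, V = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dead = (time == t) & (event == 1)
        d = dead.sum()
        d1 = (dead & (group == 1)).sum()
        O_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return np.nan
    return O_E ** 2 / V


def random_survival_dataset(rng, n_max=8):
    """Tiny random survival dataset with both groups non-empty and >=1 event."""
    while True:
        n = rng.integers(3, n_max + 1)
        time = rng.integers(1, 6, size=n).astype(float)  # integer times force ties
        event = rng.integers(0, 2, size=n)
        group = rng.integers(0, 2, size=n)
        if event.sum() >= 1 and 0 < group.sum() < n:
            return time, event, group
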