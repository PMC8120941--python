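import numpy as np
import pytest

from porethz import gen_set


def abema_residual(f, n_eff, n_s, L):
    """Raw residual of the real AB-EMA mixing equation (zero at a solution)."""
    e, s = n_eff**2, n_s**2
    return f * (1 - e) / (e + L * (1 - e)) + (1 - f) * (s - e) / (e + L * (s - e))


@pytest.fixture
def porosities():
    return np.round(np.arange(1, 11) * 0.05, 10)


@pytest.fixture
def constant_L_set(porosities):
    """Noiseless AB-EMA set with L = 0.5 on the fit grid, n_s = 1.86."""
    return gen_set(1.86, 0.5, porosities)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_consistent_set(rng, n=6):
    """A random noiseless AB-EMA set in the pharmaceutically realistic regime
    (solid index 1.3-2.2, anchor porosity <= 0.12 so the solid-index margins
    are always defined).  Returns (set, n_s, L)."""
    ns = rng.uniform(1.3, 2.2)
    L = rng.uniform(0.0, 1.0)
    f1 = rng.uniform(0.02, 0.12)
    rest = rng.uniform(f1 + 0.02, 0.6, size=n - 1)
    f = np.sort(np.concatenate([[f1], rest]))
    return gen_set(ns, L, f), ns, L
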