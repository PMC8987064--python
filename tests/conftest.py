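"""Shared fixtures: small simulated ensembles and synthetic trajectories.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from allofret.reference import two_state_params
from allofret.telegraph import simulate_ensemble


@pytest.fixture(scope="session")
def asyn_params():
    """Active-enzyme, no-ligand two-state parameters on aSyn aggregates."""
    return two_state_params("asyn_active", sigma=0.03)


@pytest.fixture(scope="session")
def noisy_ensemble(asyn_params):
    """40 noisy trajectories of 2,000 frames at 0.1 s."""
    return simulate_ensemble(asyn_params, 40, 2000, 0.1, with_noise=True,
                             seed=11)


@pytest.fixture(scope="session")
def noiseless_ensemble(asyn_params):
    """Same ensemble without observation noise (independent seed)."""
    return simulate_ensemble(asyn_params, 40, 2000, 0.1, with_noise=False,
                             seed=12)


def nested_loop_correlation(x, tau, y=None):
    """Literal transcription of the windowed-mean correlation formula.

    C_tau = 1/(N-tau) * sum_{t=1}^{N-tau} {I(t) - mean(I(1..N-tau))}
                                        * {J(t+tau) - mean(J(1+tau..N))}
    computed with explicit Python loops; the independent oracle for the
    vectorized implementation.
    """
    x = np.asarray(x, dtype=float)
    y = x if y is None else np.asarray(y, dtype=float)
    n = len(x)
    m1 = 0.0
    for tp in range(n - tau):
        m1 += x[tp]
    m1 /= n - tau
    m2 = 0.0
    for tp in range(tau, n):
        m2 += y[tp]
    m2 /= n - tau
    acc = 0.0
    for t in range(n - tau):
        acc += (x[t] - m1) * (y[t + tau] - m2)
    return acc / (n - tau)
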