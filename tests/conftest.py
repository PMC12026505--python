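import dataclasses

import numpy as np
import pytest

from forktrace import simkit


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def noiseless_preset():
    """Deterministic kinetics: rate 100 bp/s, no pauses, always completes."""
    return dataclasses.replace(
        simkit.KINETIC_PRESETS["unconstrained"],
        burst_rate_mean=100.0,
        burst_rate_sd=0.0,
        pause_prob_once=0.0,
        pause_prob_twice=0.0,
        completion_prob=1.0,
        localization_noise_bp=0.0,
    )


def two_phase_trace(n1=31, n2=30, slope1=100.0, slope2=0.0, dt=5.0, noise=0.0, seed=0):
    """Piecewise-linear trace: slope1 for n1 points then slope2, contiguous."""
    rng = np.random.default_rng(seed)
    t = np.arange(n1 + n2) * dt
    x = np.empty_like(t, dtype=float)
    x[:n1] = slope1 * t[:n1]
    x[n1:] = x[n1 - 1] + slope2 * (t[n1:] - t[n1 - 1])
    if noise:
        x = x + rng.normal(0, noise, len(t))
    return t, x
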