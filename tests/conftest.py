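from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from heelsync.synthetic import SyntheticTrialSpec, generate_trial

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Noiseless default trial spec (bilateral squat, offset -1.0 s)."""
    return SyntheticTrialSpec(
        true_offset_s=-1.0, noise_sd_kin=0.0, noise_sd_force=0.0, seed=1)


@pytest.fixture
def clean_trial(clean_spec):
    return generate_trial(clean_spec)


@pytest.fixture
def noisy_trial():
    return generate_trial(SyntheticTrialSpec(true_offset_s=-1.38, seed=4))


def random_heel_like_signals(rng, n_signals: int, length: int = 200):
    """Smooth-ish random walks covering event and no-event cases for the
    heel detector equivalence check."""
    out = []
    for _ in range(n_signals):
        kind = rng.integers(4)
        if kind == 0:
            v = np.cumsum(rng.normal(size=length))
        elif kind == 1:
            v = np.convolve(rng.normal(size=length), np.ones(7) / 7, mode="same")
        elif kind == 2:  # monotone (no local minimum -> no event)
            v = -np.sort(rng.normal(size=length))
        else:  # plateau-heavy, forces tie handling
            v = np.round(np.cumsum(rng.normal(size=length)), 1)
        out.append(v)
    return out


def random_force_like_signals(rng, n_signals: int, length: int = 300):
    out = []
    for _ in range(n_signals):
        kind = rng.integers(3)
        if kind == 0:
            v = np.abs(np.cumsum(rng.normal(size=length)))
        elif kind == 1:
            v = np.concatenate([rng.normal(0, 1, length // 2),
                                rng.normal(0, 1, length - length // 2) + rng.uniform(0, 50)])
        else:  # constant-ish / plateau cases
            v = np.round(rng.normal(0, 0.5, length), 1)
        out.append(v)
    return out
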