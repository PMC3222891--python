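"""Shared fixtures: small synthetic designs and pattern sets."""

import numpy as np
import pytest

from patternsep.design import make_design
from patternsep.simulate import SignalSpec, generate_patterns


@pytest.fixture(scope="session")
def small_design():
    """4 participants x 8 trials/condition, default timing."""
    return make_design(n_participants=4, n_trials_per_condition=8, seed=11)


@pytest.fixture(scope="session")
def full_design():
    """The study-sized design: 15 participants x 20 trials/condition."""
    return make_design(n_participants=15, n_trials_per_condition=20, seed=1)


@pytest.fixture(scope="session")
def bound_only_patterns(small_design):
    """Pattern sets with unique bound traces only (no shared codes)."""
    spec = SignalSpec(n_voxels=120, amp_bound=2.0, amp_context=0.0,
                      amp_event=0.0, noise_sd=1.0, p_inaccurate=0.0)
    return generate_patterns(small_design, spec, seed=5)


@pytest.fixture(scope="session")
def separable_patterns(small_design):
    """Nearly noise-free, widely separated condition clusters."""
    spec = SignalSpec(n_voxels=60, amp_bound=50.0, amp_context=0.0,
                      amp_event=0.0, noise_sd=0.5, p_inaccurate=0.0)
    return generate_patterns(small_design, spec, seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
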