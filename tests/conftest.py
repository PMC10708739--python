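"""Shared fixtures: small seeded models and recordings, built once per session."""
import numpy as np
import pytest

from psgcausal.synthetic import (make_ground_truth, simulate_recording)
from psgcausal.windowing import select_windows


@pytest.fixture(scope="session")
def gt_small():
    """Stable 4-channel SVAR(2) with a handful of cross-links."""
    return make_ground_truth(d=4, p=2, lag_density=0.25, contemp_density=0.2,
                             target_spectral_radius=0.8, seed=7)


@pytest.fixture(scope="session")
def rec_small(gt_small):
    """120-s recording from the small model."""
    return simulate_recording(gt_small, 120.0, seed=11, subject_id="S-small")


@pytest.fixture(scope="session")
def roster_model():
    """Default 10-channel roster model at the reference densities."""
    return make_ground_truth(d=10, p=2, lag_density=0.08, contemp_density=0.05,
                             target_spectral_radius=0.85, seed=1)


@pytest.fixture(scope="session")
def roster_recording(roster_model):
    """620-s, 100-Hz roster recording (enough grid slots for a 50-window quota)."""
    return simulate_recording(roster_model, 620.0, seed=2,
                              subject_id="S-roster")


@pytest.fixture(scope="session")
def roster_windows(roster_recording):
    """Quota of 50 accepted stationary windows from the roster recording."""
    return select_windows(roster_recording, quota=50, seed=3, max_order=4)


@pytest.fixture(scope="session")
def known_var1():
    """Hand-written stable VAR(1): x1 drives x0, no feedback."""
    A = np.array([[0.5, 0.4], [0.0, 0.5]])
    return A
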