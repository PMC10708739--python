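"""Window grid, standardization, stationarity screen, quota selection."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgcausal.exceptions import ConfigError, WindowQuotaError
from psgcausal.synthetic import GroundTruthModel, Recording, simulate_recording
from psgcausal.windowing import (Window, grid_starts, is_stationary,
                                 resample_to_common_rate, select_windows,
                                 standardize)


@settings(max_examples=50, deadline=None)
@given(n=st.integers(0, 100_000), L=st.integers(1, 5000),
       step=st.integers(1, 5000))
def test_grid_starts_properties(n, L, step):
    starts = grid_starts(n, L, step)
    assert np.all(starts % step == 0)
    assert np.all(starts + L <= n)
    if n >= L:
        assert starts[0] == 0
        assert len(starts) == (n - L) // step + 1


def test_default_grid_overlap_is_half_or_none():
    # 20-s windows on a 10-s grid at 100 Hz: L=2000, step=1000
    starts = grid_starts(62_000, 2000, 1000)
    for i, a in enumerate(starts[:10]):
        for b in starts[i + 1:12]:
            overlap = max(0, a + 2000 - b)
            assert overlap in (0, 1000)


def test_standardize_centered_and_zscored(rec_small):
    w = Window("r", 0, rec_small.data[:, :2000], 100.0)
    c = standardize(w, "centered")
    np.testing.assert_allclose(c.data.mean(axis=1), 0, atol=1e-12)
    z = standardize(w, "zscored")
    np.testing.assert_allclose(z.data.std(axis=1), 1, atol=1e-12)
    with pytest.raises(ConfigError):
        standardize(w, "whitened")


def test_zscore_zero_variance_names_channel():
    data = np.vstack([np.zeros(100), np.random.default_rng(0).normal(size=100)])
    w = Window("r", 0, data, 100.0, channel_names=["Flat", "Ok"])
    with pytest.raises(ConfigError, match="Flat"):
        standardize(w, "zscored")


def test_resample_identity_and_downsample(rec_small):
    same = resample_to_common_rate(rec_small, rec_small.rate_hz)
    assert same is rec_small
    fast = Recording("hf", rec_small.data, 200.0, rec_small.channel_names)
    slow = resample_to_common_rate(fast, 100.0)
    assert slow.rate_hz == 100.0
    assert slow.n_samples == fast.n_samples // 2
    with pytest.raises(ConfigError):
        resample_to_common_rate(rec_small, 200.0)


def test_is_stationary_on_stable_process(rec_small):
    w = standardize(Window("r", 0, rec_small.data[:, :2000], 100.0), "centered")
    ok, radius = is_stationary(w, 2)
    assert ok and 0 < radius < 1


def test_unit_root_process_has_radius_near_one():
    rng = np.random.default_rng(0)
    walk = np.cumsum(rng.standard_normal((2, 4000)), axis=1)
    w = standardize(Window("rw", 0, walk, 100.0), "centered")
    ok, radius = is_stationary(w, 1)
    assert radius > 0.95


def test_select_windows_meets_quota_and_is_deterministic(roster_recording):
    a = select_windows(roster_recording, quota=10, seed=5, max_order=4)
    b = select_windows(roster_recording, quota=10, seed=5, max_order=4)
    assert len(a) == 10
    assert [w.start_sample for w in a.windows] == \
        [w.start_sample for w in b.windows]
    for w in a.windows:
        assert w.n_samples == 2000
        assert w.start_sample % 1000 == 0
        assert w.spectral_radius < 1
        assert 1 <= w.order <= 4
    assert set(a.rejection_reasons.values()) <= {"nonstationary",
                                                 "rank-deficient"}


def test_select_windows_quota_exhaustion(rec_small):
    short = Recording("short", rec_small.data[:, :4000], 100.0,
                      rec_small.channel_names)
    with pytest.raises(WindowQuotaError):
        select_windows(short, quota=50, seed=0, max_order=2)


def test_select_windows_rejects_random_walk_channel():
    d = 3
    lag = np.zeros((1, d, d))
    lag[0] = np.diag([1.0, 0.5, 0.5])
    gt = GroundTruthModel(d=d, p=1, lagged_coeffs=lag,
                          contemporaneous=np.zeros((d, d)),
                          noise_cov=np.eye(d))
    rec = simulate_recording(gt, 620.0, seed=3, subject_id="drift")
    ws = select_windows(rec, quota=20, seed=4, max_order=2)
    # a unit-root channel makes some windows fail the radius screen
    assert all(r == "nonstationary" for r in ws.rejection_reasons.values())


def test_manifest_contains_accepted_and_rejected(roster_recording):
    ws = select_windows(roster_recording, quota=5, seed=6, max_order=4)
    df = ws.to_manifest()
    assert (df["accepted"].sum()) == 5
    assert len(df) == 5 + ws.rejected_count


def test_rejection_calibration_monotone_in_instability():
    from psgcausal.experiments import window_acceptance_rate
    mild = window_acceptance_rate(0.7, seed=5)
    strong = window_acceptance_rate(0.95, seed=5)
    drift = window_acceptance_rate(drift=True, seed=5)
    assert mild > 0.9
    assert strong > 0.9      # well-inside-unit-circle cohorts sail through
    assert mild >= strong >= drift
    assert drift <= 0.99     # a random-walk channel is rejected measurably
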