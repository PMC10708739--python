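"""Generator oracles: stationary law, stability targeting, cohort plumbing."""
import json

import numpy as np
import pytest

from psgcausal.exceptions import ConfigError, InstabilityError
from psgcausal.synthetic import (CovariateSpec, GroundTruthModel,
                                 default_waist_covariate, logistic_ramp,
                                 make_cohort, make_ground_truth, read_cohort,
                                 set_edge_weight, simulate_recording,
                                 write_cohort)


def test_spectral_radius_hits_target():
    for seed in (0, 1, 2):
        gt = make_ground_truth(d=6, p=2, lag_density=0.2, contemp_density=0.1,
                               target_spectral_radius=0.85, seed=seed)
        assert abs(gt.spectral_radius() - 0.85) < 1e-3


def test_zero_density_means_no_cross_edges():
    gt = make_ground_truth(d=5, p=2, lag_density=0.0, contemp_density=0.0,
                           target_spectral_radius=0.8, seed=0)
    assert not np.any(gt.lagged_coeffs)
    assert not np.any(gt.contemporaneous)
    assert gt.edge_list == frozenset()


def test_edge_list_matches_matrices():
    gt = make_ground_truth(d=5, p=2, lag_density=0.3, contemp_density=0.2,
                           target_spectral_radius=0.8, seed=4)
    for (src, tgt, lag) in gt.edge_list:
        if lag == 0:
            assert gt.contemporaneous[tgt, src] != 0
        else:
            assert gt.lagged_coeffs[lag - 1][tgt, src] != 0
    # and conversely every nonzero entry is listed
    n_listed = len(gt.edge_list)
    n_nonzero = int(np.count_nonzero(gt.lagged_coeffs)
                    + np.count_nonzero(gt.contemporaneous))
    assert n_listed == n_nonzero


def test_stationary_covariance_matches_long_simulation(gt_small):
    rec = simulate_recording(gt_small, 3000.0, seed=5)
    emp = np.cov(rec.data)
    model_cov = gt_small.stationary_covariance()
    rel = np.abs(emp - model_cov).max() / np.abs(model_cov).max()
    assert rel < 0.05


def test_simulation_deterministic(gt_small):
    a = simulate_recording(gt_small, 30.0, seed=9)
    b = simulate_recording(gt_small, 30.0, seed=9)
    c = simulate_recording(gt_small, 30.0, seed=10)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_set_edge_weight_changes_single_entry(gt_small):
    half = gt_small.lagged_coeffs[0][0, 1] / 2
    new = set_edge_weight(gt_small, 1, 0, 1, half)
    assert new.lagged_coeffs[0][0, 1] == pytest.approx(half)
    diff = np.abs(new.lagged_coeffs - gt_small.lagged_coeffs)
    diff[0, 0, 1] = 0.0
    assert not np.any(diff)


def test_set_edge_weight_rejects_destabilizing_value(gt_small):
    with pytest.raises(InstabilityError):
        set_edge_weight(gt_small, 1, 0, 1, 50.0)


def test_unstable_model_simulation_raises():
    A = np.array([[[1.2, 0.0], [0.0, 1.2]]])
    gt = GroundTruthModel(d=2, p=1, lagged_coeffs=A,
                          contemporaneous=np.zeros((2, 2)),
                          noise_cov=np.eye(2))
    with pytest.raises(InstabilityError):
        simulate_recording(gt, 600.0, seed=0)


def test_covariate_spec_requires_lagged_edge():
    spec = default_waist_covariate()
    with pytest.raises(ConfigError):
        CovariateSpec(name="x", distribution=spec.distribution,
                      target_edge=(1, 0, 0), effect=spec.effect)


def test_logistic_ramp_monotone_and_bounded():
    ramp = logistic_ramp(95.0, 8.0, 1.8)
    xs = np.linspace(40, 180, 50)
    ys = np.array([ramp(x) for x in xs])
    assert np.all(np.diff(ys) > 0)
    assert ys.min() > 0 and ys.max() < 1.8
    assert ramp(95.0) == pytest.approx(0.9)  # half the maximum at the midpoint


def test_make_cohort_table_contains_no_ground_truth(gt_small):
    spec = default_waist_covariate()
    spec = CovariateSpec(name=spec.name, distribution=spec.distribution,
                         target_edge=(1, 0, 1), effect=spec.effect)
    recs, table = make_cohort(5, gt_small, spec, 30.0, seed=21)
    assert list(table.columns) == ["subject_id", spec.name, "sex"]
    assert len(recs) == 5
    assert table[spec.name].between(60, 150).all()
    assert set(table["sex"]) <= {"F", "M"}


def test_make_cohort_subjects_stable_under_cohort_size(gt_small):
    spec = default_waist_covariate()
    spec = CovariateSpec(name=spec.name, distribution=spec.distribution,
                         target_edge=(1, 0, 1), effect=spec.effect)
    recs3, _ = make_cohort(3, gt_small, spec, 20.0, seed=33)
    recs5, _ = make_cohort(5, gt_small, spec, 20.0, seed=33)
    for a, b in zip(recs3, recs5):
        np.testing.assert_array_equal(a.data, b.data)


@pytest.mark.parametrize("fmt", ["csv", "npz"])
def test_cohort_roundtrip(tmp_path, gt_small, fmt):
    spec = default_waist_covariate()
    spec = CovariateSpec(name=spec.name, distribution=spec.distribution,
                         target_edge=(1, 0, 1), effect=spec.effect)
    recs, table = make_cohort(3, gt_small, spec, 10.0, seed=2)
    out = tmp_path / fmt
    write_cohort(recs, out, fmt=fmt, ground_truth=gt_small,
                 covariate_table=table)
    back, table2, manifest = read_cohort(out)
    assert len(back) == 3
    for a, b in zip(recs, back):
        assert a.subject_id == b.subject_id
        assert a.channel_names == b.channel_names
        np.testing.assert_allclose(a.data, b.data, rtol=0, atol=1e-12)
    assert list(table2["subject_id"]) == list(table["subject_id"])
    gt_json = json.dumps(manifest["ground_truth"], sort_keys=True)
    assert '"d": 4' in gt_json


def test_write_cohort_rejects_unknown_format(tmp_path, gt_small):
    rec = simulate_recording(gt_small, 5.0, seed=1)
    with pytest.raises(ConfigError):
        write_cohort([rec], tmp_path / "bad", fmt="edf", ground_truth=gt_small)
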