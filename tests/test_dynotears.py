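"""DBN structure learning: lag design, acyclicity, OLS limit, thresholding."""
import numpy as np
import pytest

from psgcausal.dynotears import (DynamicBayesianNetwork, acyclicity,
                                 build_lag_matrix, cv_hyperparams,
                                 fit_dynotears, select_order_dbn,
                                 threshold_and_collapse)
from psgcausal.exceptions import ConfigError
from psgcausal.experiments import make_recovery_model
from psgcausal.synthetic import simulate_recording


def _centered(model, n, seed):
    rec = simulate_recording(model, n / 100.0, seed=seed)
    x = rec.data.T
    return x - x.mean(axis=0)


def test_build_lag_matrix_shapes_and_alignment():
    x = np.arange(24, dtype=float).reshape(12, 2)
    X, Y = build_lag_matrix(x, 2)
    assert X.shape == (11, 2)           # m + 1 - p rows
    assert Y.shape == (11, 4)
    np.testing.assert_array_equal(X, x[1:])
    # lag-1 block aligns to the previous sample
    np.testing.assert_array_equal(Y[:, :2], x[:-1])
    # deepest lag is zero-padded in the first row only
    np.testing.assert_array_equal(Y[0, 2:], [0.0, 0.0])
    np.testing.assert_array_equal(Y[1:, 2:], x[:-2])


def test_acyclicity_values():
    assert acyclicity(np.zeros((4, 4))) == pytest.approx(0.0)
    tri = np.triu(np.ones((4, 4)), k=1)
    assert acyclicity(tri) == pytest.approx(0.0, abs=1e-12)
    cyc = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert acyclicity(cyc) > 0.1


def test_unconstrained_zero_penalty_matches_ols():
    model = make_recovery_model(3, d=3, p=2)
    x = _centered(model, 2000, seed=3)
    res = fit_dynotears(x, 2, lambda_w=0.0, lambda_a=0.0, constrain=False)
    # zero penalties + no acyclicity constraint = per-equation OLS of each
    # channel on the other channels (W) and every lag column (A)
    X, Y = build_lag_matrix(x, 2)
    for i in range(3):
        others = [j for j in range(3) if j != i]
        Z = np.hstack([X[:, others], Y])
        coef, *_ = np.linalg.lstsq(Z, X[:, i], rcond=None)
        est = np.concatenate([res.W[others, i], res.A[:, i]])
        np.testing.assert_allclose(est, coef, atol=1e-4)


def test_constrained_fit_reaches_acyclicity_tolerance():
    model = make_recovery_model(0, d=4, p=1, n_lag_edges=3, n_contemp_edges=2)
    x = _centered(model, 3000, seed=1)
    res = fit_dynotears(x, 1)
    assert res.h_final <= 1e-8
    assert np.all(np.diag(res.W) == 0.0)
    summ = res.threshold(0.1)
    assert acyclicity(summ.W_binary.astype(float)) == pytest.approx(0.0,
                                                                    abs=1e-9)


def test_threshold_and_collapse_orientation():
    model = make_recovery_model(5, d=4, p=2)
    x = _centered(model, 3000, seed=5)
    res = fit_dynotears(x, 2)
    summ = threshold_and_collapse(res, 0.1)
    assert summ.collapsed.shape == (4, 4)
    assert np.all(np.diag(summ.collapsed) == 0)
    # every collapsed link is backed by a surviving W or A entry
    for tgt, src in zip(*np.nonzero(summ.collapsed)):
        backed = summ.W_binary[src, tgt] or summ.A_binary[:, src, tgt].any()
        assert backed
    with pytest.raises(ConfigError):
        threshold_and_collapse(res, -0.1)


def test_tau_zero_keeps_exact_nonzeros():
    model = make_recovery_model(6, d=3, p=1)
    x = _centered(model, 2000, seed=6)
    res = fit_dynotears(x, 1)
    summ = res.threshold(0.0)
    np.testing.assert_array_equal(summ.W_binary, (res.W != 0).astype(int))


def test_select_order_dbn_and_model_class():
    model = make_recovery_model(7, d=3, p=2)
    x = _centered(model, 2000, seed=7)
    best, scores = select_order_dbn(x, max_order=3)
    assert best in scores and 1 <= best <= 3
    dbn = DynamicBayesianNetwork(x, order=2)
    res = dbn.fit()
    assert res.order == 2 and res.h_final <= 1e-8


def test_cv_hyperparams_returns_grid_cell():
    model = make_recovery_model(8, d=3, p=1)
    windows = [_centered(model, 400, seed=80 + i) for i in range(4)]
    grid = [(0.0005, 0.005), (0.05, 0.05)]
    best, table = cv_hyperparams(windows, grid, orders=[1], k_folds=2)
    assert best in grid
    assert len(table) == len(grid)
    assert table["rmse"].notna().all()
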