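"""Granger statistics: BY adjustment oracle, directionality, result objects."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from psgcausal.exceptions import ConfigError
from psgcausal.granger import (GrangerResults, PairwiseGranger, by_adjust,
                               pairwise_conditional_gc, pool_by_across_windows)
from psgcausal.synthetic import GroundTruthModel, simulate_recording
from psgcausal.windowing import Window


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60),
       st.integers(0, 2 ** 31 - 1))
def test_by_adjust_matches_statsmodels(ps, seed):
    rng = np.random.default_rng(seed)
    p = np.asarray(ps)
    rng.shuffle(p)
    ours = by_adjust(p)
    _, ref, _, _ = multipletests(p, method="fdr_by")
    np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_by_adjust_rejects_invalid():
    with pytest.raises(ConfigError):
        by_adjust(np.array([0.1, 1.5]))
    with pytest.raises(ConfigError):
        by_adjust(np.array([-0.1]))


def _one_edge_recording(m, seed):
    A = np.array([[0.5, 0.4], [0.0, 0.5]])
    gt = GroundTruthModel(d=2, p=1, lagged_coeffs=A[None],
                          contemporaneous=np.zeros((2, 2)),
                          noise_cov=np.eye(2))
    rec = simulate_recording(gt, m / 100.0, seed=seed)
    x = rec.data.T
    return x - x.mean(axis=0)


def test_gc_detects_direction():
    x = _one_edge_recording(5000, seed=0)
    res = pairwise_conditional_gc(x, 1)
    assert res.adjacency[0, 1] == 1          # ch1 -> ch0 present
    assert res.F[0, 1] > res.F[1, 0]
    assert res.F[1, 0] >= 0
    assert np.all((res.pvalues_raw >= 0) & (res.pvalues_raw <= 1)
                  | np.isnan(res.pvalues_raw))
    assert np.isnan(res.F[0, 0]) and np.isnan(res.F[1, 1])


def test_gc_summary_shape_and_sorting():
    x = _one_edge_recording(3000, seed=1)
    res = pairwise_conditional_gc(x, 1)
    df = res.summary()
    assert len(df) == res.n_hypotheses == 2
    assert df["p_by"].is_monotonic_increasing


def test_n_hypotheses_for_roster(roster_windows):
    w = roster_windows.windows[0]
    res = pairwise_conditional_gc(w.data.T, w.order)
    assert res.n_hypotheses == 90
    assert res.adjacency.shape == (10, 10)
    assert np.all(np.diag(res.adjacency) == 0)


def test_model_class_matches_function(roster_windows):
    w = roster_windows.windows[0]
    res_fn = pairwise_conditional_gc(w.data.T, w.order)
    res_cls = PairwiseGranger(w, order=w.order).fit()
    np.testing.assert_allclose(res_fn.F, res_cls.F, equal_nan=True)
    auto = PairwiseGranger(w, max_order=4).fit()  # order=None -> AICc choice
    assert auto.order_used == w.order


def test_adjustment_flag_controls_correction():
    x = _one_edge_recording(3000, seed=2)
    raw = pairwise_conditional_gc(x, 1, adjust=False)
    adj = pairwise_conditional_gc(x, 1, adjust=True)
    assert np.isnan(raw.pvalues_adjusted).all()   # left for a pooling caller
    assert not raw.adjacency.any()
    mask = ~np.isnan(adj.pvalues_adjusted)
    assert np.all(adj.pvalues_adjusted[mask] >= raw.pvalues_raw[mask] - 1e-15)


def test_pool_by_across_windows():
    results = [pairwise_conditional_gc(_one_edge_recording(3000, seed=s), 1)
               for s in range(3, 6)]
    pooled = pool_by_across_windows(results)
    assert len(pooled) == len(results)
    for orig, re_adj in zip(results, pooled):
        assert re_adj.adjacency.shape == orig.adjacency.shape
        # pooling can only make individual corrections more conservative
        mask = ~np.isnan(re_adj.pvalues_adjusted)
        assert np.all(re_adj.pvalues_adjusted[mask]
                      >= orig.pvalues_raw[mask] - 1e-15)
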