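"""Cohort aggregation, consensus thresholding and the screen/confirm protocol."""
import numpy as np
import pandas as pd
import pytest

from psgcausal.cohort import (AssociationFinding, SubjectLinkFrequency,
                              boxplot_data, cohort_heatmap_and_consensus,
                              confirm_associations, covariate_screen,
                              findings_to_frame, frequencies_to_frame,
                              link_frequencies, stratified_view)
from psgcausal.exceptions import ConfigError


def _freqs(count_list, quota=10):
    out = []
    for i, counts in enumerate(count_list):
        c = np.asarray(counts)
        np.fill_diagonal(c, 0)
        out.append(SubjectLinkFrequency(f"S{i:04d}", c, quota))
    return out


def test_link_frequencies_sums_and_quota_check():
    d = 3
    adj = np.zeros((d, d), dtype=int)
    adj[0, 1] = 1
    mats = [adj] * 4 + [np.zeros((d, d), dtype=int)]
    freqs = link_frequencies({"S0": mats}, quota=5)
    assert freqs[0].counts[0, 1] == 4
    assert freqs[0].counts.sum() == 4
    with pytest.raises(ConfigError):
        link_frequencies({"S0": mats[:3]}, quota=5)


def test_subject_link_frequency_validation():
    with pytest.raises(ConfigError):
        SubjectLinkFrequency("S0", np.full((2, 2), 11), quota=10)
    bad = np.zeros((2, 2), dtype=int)
    bad[0, 0] = 1
    with pytest.raises(ConfigError):
        SubjectLinkFrequency("S0", bad, quota=10)


def test_heatmap_conservation_and_consensus_threshold():
    a = np.zeros((3, 3), dtype=int)
    a[0, 1] = 10          # always found for subject 0
    b = np.zeros((3, 3), dtype=int)
    b[0, 1] = 10
    b[2, 0] = 9           # 19/20 overall for (0 -> 2)? no: 9/20
    res = cohort_heatmap_and_consensus(_freqs([a, b]))
    # conservation: heatmap * total windows == summed counts, exactly
    total = res.total_windows
    np.testing.assert_array_equal(res.heatmap * total, a + b)
    assert res.heatmap[0, 1] == pytest.approx(1.0)
    assert res.consensus[0, 1] == 1
    assert res.heatmap[2, 0] == pytest.approx(0.45)
    assert res.consensus[2, 0] == 0          # just below 50% is excluded
    exact = cohort_heatmap_and_consensus(_freqs([a, b]),
                                         consensus_threshold=0.45)
    assert exact.consensus[2, 0] == 1        # threshold is inclusive


def test_consensus_monotone_in_threshold():
    rng = np.random.default_rng(0)
    counts = [rng.integers(0, 11, size=(4, 4)) for _ in range(6)]
    freqs = _freqs(counts)
    prev = None
    for thr in (0.2, 0.4, 0.6, 0.8):
        res = cohort_heatmap_and_consensus(freqs, consensus_threshold=thr)
        if prev is not None:
            assert np.all(res.consensus <= prev)   # raising never adds edges
        prev = res.consensus


def _monotone_cohort(n=24, quota=10, seed=0, sign=+1):
    """Counts on link 1 -> 0 increase (or decrease) with the covariate."""
    rng = np.random.default_rng(seed)
    cov = np.linspace(60, 150, n) + rng.normal(0, 1, n)
    freqs = []
    rows = []
    for i in range(n):
        c = np.zeros((3, 3), dtype=int)
        frac = (cov[i] - 60) / 90 if sign > 0 else (150 - cov[i]) / 90
        c[0, 1] = int(np.clip(round(frac * quota), 0, quota))
        freqs.append(SubjectLinkFrequency(f"S{i:04d}", c, quota))
        rows.append({"subject_id": f"S{i:04d}", "waist": cov[i],
                     "sex": "F" if i % 2 else "M"})
    return freqs, pd.DataFrame(rows)


def test_screen_finds_planted_monotone_link():
    freqs, table = _monotone_cohort()
    found = covariate_screen(freqs, table, covariates=["waist"])
    assert found
    top = found[0]
    assert top.link == (1, 0)
    assert top.statistic > 0.9


def test_screen_skips_constant_covariate_and_drops_missing():
    freqs, table = _monotone_cohort()
    table["flat"] = 1.0
    found = covariate_screen(freqs, table, covariates=["flat"])
    assert found == []
    table2 = table.copy()
    table2.loc[0, "waist"] = np.nan      # subject dropped for this covariate
    found2 = covariate_screen(freqs, table2, covariates=["waist"])
    assert found2 and found2[0].link == (1, 0)


def test_screen_needs_three_subjects():
    freqs, table = _monotone_cohort(n=5)
    table.loc[1:, "waist"] = np.nan
    with pytest.raises(ConfigError):
        covariate_screen(freqs, table, covariates=["waist"])


def test_confirm_requires_same_sign_everywhere():
    vfreqs, vtable = _monotone_cohort(seed=1)
    cands = covariate_screen(vfreqs, vtable, covariates=["waist"])
    same1, t1 = _monotone_cohort(seed=2)
    same2, t2 = _monotone_cohort(seed=3)
    flipped, t3 = _monotone_cohort(seed=4, sign=-1)
    confirmed = confirm_associations(
        cands, {"t1": same1, "t2": same2}, {"t1": t1, "t2": t2})
    assert any(f.confirmed and f.link == (1, 0) for f in confirmed)
    rejected = confirm_associations(
        cands, {"t1": same1, "t3": flipped}, {"t1": t1, "t3": t3})
    assert not any(f.confirmed for f in rejected)
    # missing covariate table in a test cohort blocks confirmation
    blocked = confirm_associations(
        cands, {"t1": same1}, {"t1": t1.drop(columns=["waist"])})
    assert not any(f.confirmed for f in blocked)


def test_confirm_never_rescreens():
    vfreqs, vtable = _monotone_cohort(seed=5)
    t1, tab1 = _monotone_cohort(seed=6)
    out = confirm_associations([], {"t1": t1}, {"t1": tab1})
    assert out == []     # no candidates in, no findings out


def test_boxplot_and_stratified_views():
    freqs, table = _monotone_cohort()
    df = boxplot_data(freqs, table, "waist", link=(1, 0), n_bins=4)
    assert {"subject_id", "count", "waist", "bin"} <= set(df.columns)
    per_bin = df.groupby("bin", sort=False)["count"].mean()
    assert len(per_bin) >= 2
    strata = stratified_view(freqs, table, "sex", "waist", link=(1, 0))
    assert set(strata) == {"F", "M"}
    with pytest.raises(ConfigError):
        stratified_view(freqs, table, "nope", "waist", link=(1, 0))


def test_frames_have_stable_headers():
    empty = findings_to_frame([])
    assert list(empty.columns) == ["source", "target", "covariate",
                                   "statistic", "p_value", "cohort",
                                   "confirmed"]
    f = AssociationFinding(link=(1, 0), covariate="waist", statistic=0.8,
                           p_value=0.001, per_cohort={"t1": (0.7, 0.01)})
    df = findings_to_frame([f], channel_names=["a", "b", "c"])
    assert df.loc[0, "source"] == "b" and df.loc[0, "target"] == "a"
    assert df.loc[0, "rho_t1"] == 0.7
    freqs, _ = _monotone_cohort(n=3)
    long = frequencies_to_frame(freqs)
    assert len(long) == 3 * 6            # d(d-1) rows per subject
    assert (long["quota"] == 10).all()


def test_plot_helpers_render(tmp_path):
    from psgcausal.plots import plot_heatmap, plot_link_boxplot
    freqs, table = _monotone_cohort()
    res = cohort_heatmap_and_consensus(freqs, channel_names=["a", "b", "c"])
    fig = plot_heatmap(res, tmp_path / "heat.png")
    assert (tmp_path / "heat.png").stat().st_size > 0
    df = boxplot_data(freqs, table, "waist", link=(1, 0))
    plot_link_boxplot(df, "waist", "b -> a", tmp_path / "box.png")
    assert (tmp_path / "box.png").stat().st_size > 0
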