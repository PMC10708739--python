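"""Cohort-level aggregation and covariate association screening.

Per-window binary adjacencies (from either discovery method) are summed into
per-subject link counts ("out of how many of this subject's windows was the
link found"), pooled into cohort heatmaps and 50%-consensus graphs, and
screened for association with subject covariates by Spearman rank
correlation. Candidate associations found in a validation cohort are only
*confirmed* if they reappear, significant and with the same sign, in every
held-out test cohort — the firewall against selection effects: test cohorts
are never used to generate candidates.

All adjacency/count matrices are oriented ``[target, source]``: entry
``[x, y]`` refers to the directed link y -> x.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError

DEFAULT_CONSENSUS = 0.5
DEFAULT_MIN_ABS_STAT = 0.3
DEFAULT_ALPHA = 0.05


@dataclass
class SubjectLinkFrequency:
    """Windows (out of ``quota``) in which each directed link was found."""

    subject_id: str
    counts: np.ndarray            # (d, d) ints, [target, source], zero diagonal
    quota: int
    method: str = "granger"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.min() < 0 or self.counts.max() > self.quota:
            raise ConfigError(
                f"{self.subject_id}: counts must lie in [0, {self.quota}]")
        if np.any(np.diag(self.counts) != 0):
            raise ConfigError(f"{self.subject_id}: diagonal counts must be 0")


@dataclass
class CohortResult:
    frequencies: list[SubjectLinkFrequency]
    heatmap: np.ndarray           # (d, d) fraction of all windows with the link
    consensus: np.ndarray         # (d, d) binary at the consensus threshold
    method: str
    consensus_threshold: float = DEFAULT_CONSENSUS
    channel_names: list[str] | None = None

    @property
    def total_windows(self) -> int:
        return sum(f.quota for f in self.frequencies)


@dataclass
class AssociationFinding:
    link: tuple[int, int]          # (source, target)
    covariate: str
    statistic: float               # Spearman rho on the screening cohort
    p_value: float
    cohort: str = "validation"
    confirmed: bool = False
    per_cohort: dict = field(default_factory=dict)   # cohort -> (rho, p)


def link_frequencies(per_window_adjacencies: Mapping[str, Sequence[np.ndarray]],
                     quota: int, method: str = "granger",
                     ) -> list[SubjectLinkFrequency]:
    """Sum each subject's binary window adjacencies into link counts.

    Every subject must contribute exactly ``quota`` windows.
    """
    out = []
    for sid, mats in per_window_adjacencies.items():
        if len(mats) != quota:
            raise ConfigError(
                f"subject {sid} has {len(mats)} windows, expected {quota}")
        counts = np.sum([np.asarray(m, dtype=int) for m in mats], axis=0)
        np.fill_diagonal(counts, 0)
        out.append(SubjectLinkFrequency(subject_id=sid, counts=counts,
                                        quota=quota, method=method))
    return out


def cohort_heatmap_and_consensus(frequencies: Sequence[SubjectLinkFrequency],
                                 consensus_threshold: float = DEFAULT_CONSENSUS,
                                 channel_names: list[str] | None = None,
                                 ) -> CohortResult:
    """Pool subjects: fraction of all windows with each link, plus consensus.

    A link enters the consensus graph iff it was identified in at least the
    threshold fraction (default 50%) of all the cohort's windows; a fraction
    just below the threshold is excluded.
    """
    if not frequencies:
        raise ConfigError("at least one subject is required")
    total = sum(f.quota for f in frequencies)
    heat = np.sum([f.counts for f in frequencies], axis=0) / total
    consensus = (heat >= consensus_threshold).astype(int)
    np.fill_diagonal(consensus, 0)
    return CohortResult(frequencies=list(frequencies), heatmap=heat,
                        consensus=consensus, method=frequencies[0].method,
                        consensus_threshold=consensus_threshold,
                        channel_names=channel_names)


def frequencies_to_frame(frequencies: Sequence[SubjectLinkFrequency],
                         channel_names: list[str] | None = None) -> pd.DataFrame:
    """Long-format table: subject_id, source, target, count, quota."""
    rows = []
    for f in frequencies:
        d = f.counts.shape[0]
        names = channel_names or [f"ch{i}" for i in range(d)]
        for x in range(d):
            for y in range(d):
                if x == y:
                    continue
                rows.append({"subject_id": f.subject_id, "source": names[y],
                             "target": names[x], "source_idx": y,
                             "target_idx": x, "count": int(f.counts[x, y]),
                             "quota": f.quota})
    return pd.DataFrame(rows)


def _counts_vector(frequencies, source, target):
    return np.array([f.counts[target, source] for f in frequencies], dtype=float)


def _aligned_covariate(frequencies, covariate_table, name):
    """Covariate values aligned to the frequency list; NaN where missing."""
    tab = covariate_table.set_index("subject_id")[name]
    vals = []
    for f in frequencies:
        if f.subject_id in tab.index:
            vals.append(tab.loc[f.subject_id])
        else:
            vals.append(np.nan)
    return pd.to_numeric(pd.Series(vals), errors="coerce").to_numpy()


def covariate_screen(frequencies: Sequence[SubjectLinkFrequency],
                     covariate_table: pd.DataFrame,
                     covariates: Sequence[str] | None = None,
                     min_abs_stat: float = DEFAULT_MIN_ABS_STAT,
                     alpha: float = DEFAULT_ALPHA,
                     ) -> list[AssociationFinding]:
    """Rank-correlation screen of every (link, covariate) pair.

    Subjects missing a covariate are dropped for that covariate only. Pairs
    with a constant count vector or constant covariate are skipped. Returns
    the findings with |rho| >= min_abs_stat and p < alpha, ranked by |rho|.
    """
    if "subject_id" not in covariate_table.columns:
        raise ConfigError("covariate table must have a subject_id column")
    if covariates is None:
        covariates = [c for c in covariate_table.columns if c != "subject_id"]
    d = frequencies[0].counts.shape[0]
    findings = []
    for name in covariates:
        cov = _aligned_covariate(frequencies, covariate_table, name)
        mask = np.isfinite(cov)
        if mask.sum() < 3:
            raise ConfigError(
                f"covariate {name!r}: need >= 3 subjects with values, "
                f"have {int(mask.sum())}")
        if np.unique(cov[mask]).size < 2:
            continue  # constant covariate: no rank ordering to correlate
        for y in range(d):          # source
            for x in range(d):      # target
                if x == y:
                    continue
                counts = _counts_vector(frequencies, y, x)[mask]
                if np.unique(counts).size < 2:
                    continue
                rho, p = stats.spearmanr(counts, cov[mask])
                if np.isfinite(rho) and abs(rho) >= min_abs_stat and p < alpha:
                    findings.append(AssociationFinding(
                        link=(y, x), covariate=name, statistic=float(rho),
                        p_value=float(p), cohort="validation"))
    findings.sort(key=lambda f: -abs(f.statistic))
    return findings


def confirm_associations(candidates: Sequence[AssociationFinding],
                         test_cohort_frequencies: Mapping[str, Sequence[SubjectLinkFrequency]],
                         covariate_tables: Mapping[str, pd.DataFrame],
                         alpha: float = DEFAULT_ALPHA,
                         ) -> list[AssociationFinding]:
    """Re-test validation candidates on held-out cohorts.

    A candidate is confirmed iff its rank correlation is significant at
    ``alpha`` *and* of the same sign in every test cohort. No screening is
    performed on the test cohorts (only the fixed candidate list is
    evaluated), so the confirmation step cannot introduce new selection.
    """
    out = []
    for cand in candidates:
        y, x = cand.link
        per_cohort = {}
        confirmed = True
        for cname, freqs in test_cohort_frequencies.items():
            table = covariate_tables.get(cname)
            if table is None or cand.covariate not in table.columns:
                per_cohort[cname] = (np.nan, np.nan)
                confirmed = False
                continue
            cov = _aligned_covariate(freqs, table, cand.covariate)
            mask = np.isfinite(cov)
            counts = _counts_vector(freqs, y, x)[mask]
            if np.unique(counts).size < 2 or np.unique(cov[mask]).size < 2:
                per_cohort[cname] = (np.nan, np.nan)
                confirmed = False
                continue
            rho, p = stats.spearmanr(counts, cov[mask])
            per_cohort[cname] = (float(rho), float(p))
            if not (np.isfinite(rho) and p < alpha
                    and np.sign(rho) == np.sign(cand.statistic)):
                confirmed = False
        out.append(AssociationFinding(
            link=cand.link, covariate=cand.covariate,
            statistic=cand.statistic, p_value=cand.p_value,
            cohort="validation", confirmed=confirmed, per_cohort=per_cohort))
    return out


def boxplot_data(frequencies: Sequence[SubjectLinkFrequency],
                 covariate_table: pd.DataFrame, covariate: str,
                 link: tuple[int, int], n_bins: int = 4) -> pd.DataFrame:
    """Per-subject counts of one link binned by covariate quantiles (tidy)."""
    y, x = link
    cov = _aligned_covariate(frequencies, covariate_table, covariate)
    counts = _counts_vector(frequencies, y, x)
    mask = np.isfinite(cov)
    df = pd.DataFrame({
        "subject_id": [f.subject_id for f in frequencies],
        "count": counts, covariate: cov,
    })[mask]
    df["bin"] = pd.qcut(df[covariate], q=n_bins, duplicates="drop")
    df["bin"] = df["bin"].astype(str)
    return df.reset_index(drop=True)


def stratified_view(frequencies: Sequence[SubjectLinkFrequency],
                    covariate_table: pd.DataFrame, stratify_by: str,
                    covariate: str, link: tuple[int, int],
                    n_bins: int = 4) -> dict[str, pd.DataFrame]:
    """Box-plot data for one link, split by a categorical covariate."""
    if stratify_by not in covariate_table.columns:
        raise ConfigError(f"unknown stratification covariate {stratify_by!r}")
    strata = covariate_table[stratify_by].dropna().unique()
    out = {}
    for value in strata:
        keep_ids = set(covariate_table.loc[
            covariate_table[stratify_by] == value, "subject_id"])
        sub = [f for f in frequencies if f.subject_id in keep_ids]
        if not sub:
            continue
        out[str(value)] = boxplot_data(sub, covariate_table, covariate, link,
                                       n_bins=n_bins)
    return out


def findings_to_frame(findings: Sequence[AssociationFinding],
                      channel_names: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for f in findings:
        y, x = f.link
        names = channel_names
        row = {
            "source": names[y] if names else y,
            "target": names[x] if names else x,
            "covariate": f.covariate, "statistic": f.statistic,
            "p_value": f.p_value, "cohort": f.cohort, "confirmed": f.confirmed,
        }
        for cname, (rho, p) in f.per_cohort.items():
            row[f"rho_{cname}"] = rho
            row[f"p_{cname}"] = p
        rows.append(row)
    base_cols = ["source", "target", "covariate", "statistic", "p_value",
                 "cohort", "confirmed"]
    if not rows:
        return pd.DataFrame(columns=base_cols)
    return pd.DataFrame(rows)
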