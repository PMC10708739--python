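"""Pairwise-conditional Granger causality on centered VAR windows.

For each ordered pair (source y, target x) the statistic is the
log-likelihood ratio

    F[x, y] = ln( Sigma'_xx / Sigma_xx ),

where Sigma_xx is the target's residual variance under the full VAR and
Sigma'_xx under the reduced VAR in which every lag of the source has been
excised from every equation (all other regressors retained — the
pairwise-conditional construction, not bivariate GC). Both models share the
same lag order, which keeps them nested and the ratio exact.

Significance: the monotone transform (exp(F) - 1) * den/num follows an F
distribution under the null, with numerator dof p (the excised lags in the
target equation) and denominator dof n_eff - p*d. Raw p-values over the
d*(d-1) ordered pairs are adjusted by the Benjamini–Yekutieli step-up rule,
which controls FDR under arbitrary dependence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import ConfigError, PsgCausalError, RankDeficientError
from .var import MAX_ORDER_DEFAULT, build_var_design, select_order

DEFAULT_ALPHA = 0.05


def by_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values.

    adj_(i) = min_{j >= i} min(1, p_(j) * q * c(q) / j) with the harmonic
    correction c(q) = sum_{i<=q} 1/i; monotone in the input ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ConfigError("by_adjust expects a flat vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    q = p.size
    if q == 0:
        return p.copy()
    c_q = np.sum(1.0 / np.arange(1, q + 1))
    order = np.argsort(p, kind="stable")
    scaled = p[order] * q * c_q / np.arange(1, q + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(q)
    adj[order] = adj_sorted
    return adj


@dataclass(frozen=True)
class GrangerResults:
    """Granger-causality statistics for one window.

    ``F[x, y]`` is the statistic for source ``y`` -> target ``x``; the
    diagonal is NaN (self-causality is assumed, not tested). ``adjacency``
    is 1 where the BY-adjusted p-value falls below ``alpha``.
    """

    F: np.ndarray
    pvalues_raw: np.ndarray
    pvalues_adjusted: np.ndarray
    adjacency: np.ndarray
    order_used: int
    alpha: float
    n_effective: int
    dof_num: int
    dof_den: int
    channel_names: list[str] | None = field(default=None, compare=False)

    @property
    def d(self) -> int:
        return self.F.shape[0]

    @property
    def n_hypotheses(self) -> int:
        return self.d * (self.d - 1)

    def summary(self) -> pd.DataFrame:
        """Long-format table: one row per tested ordered pair."""
        names = self.channel_names or [f"ch{i}" for i in range(self.d)]
        rows = []
        for x in range(self.d):
            for y in range(self.d):
                if x == y:
                    continue
                rows.append({
                    "source": names[y], "target": names[x],
                    "F": self.F[x, y], "p_raw": self.pvalues_raw[x, y],
                    "p_by": self.pvalues_adjusted[x, y],
                    "significant": bool(self.adjacency[x, y]),
                })
        return pd.DataFrame(rows).sort_values("p_by", ignore_index=True)


def _partial_resid_cov(gram, cross, s_mat, idx, n):
    """Residual covariance of the OLS fit restricted to design columns idx."""
    g = gram[np.ix_(idx, idx)]
    c = cross[idx]
    try:
        cf = linalg.cho_factor(g, lower=True, check_finite=False)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise RankDeficientError(f"singular reduced design: {exc}") from exc
    cov = (s_mat - c.T @ linalg.cho_solve(cf, c, check_finite=False)) / n
    return 0.5 * (cov + cov.T)


def pairwise_conditional_gc(x: np.ndarray, order: int,
                            alpha: float = DEFAULT_ALPHA,
                            channel_names: list[str] | None = None,
                            adjust: bool = True) -> GrangerResults:
    """Compute the full d x d pairwise-conditional GC matrix for one window.

    ``x`` is a centered time-major window (m x d). Setting ``adjust=False``
    leaves the adjusted matrix and adjacency to be filled by a caller that
    pools hypotheses across windows.
    """
    x = np.asarray(x, dtype=float)
    m, d = x.shape
    p = order
    n = m - p
    dof_den = n - p * d
    if dof_den <= 0:
        raise ConfigError(
            f"order {p} leaves no denominator degrees of freedom "
            f"({n} rows, {p * d} regressors)")
    targets, design = build_var_design(x, p)
    gram = design.T @ design
    cross = design.T @ targets
    s_mat = targets.T @ targets

    full_idx = np.arange(p * d)
    sigma_full = _partial_resid_cov(gram, cross, s_mat, full_idx, n)
    var_full = np.diag(sigma_full).copy()
    if np.any(var_full <= 0):
        raise RankDeficientError("full model has zero residual variance")

    F = np.full((d, d), np.nan)
    for y in range(d):
        keep = np.array([j for j in range(p * d) if j % d != y])
        sigma_red = _partial_resid_cov(gram, cross, s_mat, keep, n)
        var_red = np.diag(sigma_red)
        ratio = var_red / var_full
        if np.any(ratio < 1.0 - 1e-8):
            raise PsgCausalError(
                "internal consistency failure: reduced-model residual variance "
                f"below full-model variance for source {y} "
                f"(min ratio {ratio.min():.3e})")
        vals = np.log(np.maximum(ratio, 1.0))
        F[:, y] = vals
        F[y, y] = np.nan

    off = ~np.eye(d, dtype=bool)
    f_stat = (np.exp(F[off]) - 1.0) * dof_den / p
    p_raw = np.full((d, d), np.nan)
    p_raw[off] = stats.f.sf(f_stat, p, dof_den)

    p_adj = np.full((d, d), np.nan)
    adjacency = np.zeros((d, d), dtype=int)
    if adjust:
        p_adj[off] = by_adjust(p_raw[off])
        adjacency[off] = (p_adj[off] < alpha).astype(int)
    return GrangerResults(F=F, pvalues_raw=p_raw, pvalues_adjusted=p_adj,
                          adjacency=adjacency, order_used=p, alpha=alpha,
                          n_effective=n, dof_num=p, dof_den=dof_den,
                          channel_names=channel_names)


class PairwiseGranger:
    """Model object: pairwise-conditional GC for one (centered) window.

    Parameters
    ----------
    data : (m, d) time-major array, or a windowing.Window (centered).
    order : fixed lag order; if None, selected by AICc over 1..max_order.
    """

    def __init__(self, data, order: int | None = None,
                 max_order: int = MAX_ORDER_DEFAULT,
                 alpha: float = DEFAULT_ALPHA,
                 channel_names: list[str] | None = None):
        from .windowing import Window  # local import to avoid a cycle
        if isinstance(data, Window):
            if channel_names is None:
                channel_names = data.channel_names
            data = data.data.T
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("data must be a 2-D time-major array")
        self.order = order
        self.max_order = max_order
        self.alpha = alpha
        self.channel_names = channel_names

    def fit(self) -> GrangerResults:
        order = self.order
        if order is None:
            order, _ = select_order(self.data, self.max_order)
        return pairwise_conditional_gc(self.data, order, alpha=self.alpha,
                                       channel_names=self.channel_names)


def pool_by_across_windows(results: list[GrangerResults],
                           alpha: float = DEFAULT_ALPHA) -> list[GrangerResults]:
    """Re-adjust p-values pooling all windows' hypotheses into one BY family.

    Offered as an alternative scope for the multiplicity correction; the
    default pipeline adjusts per window.
    """
    from dataclasses import replace
    if not results:
        return []
    d = results[0].d
    off = ~np.eye(d, dtype=bool)
    pooled = np.concatenate([r.pvalues_raw[off] for r in results])
    adj = by_adjust(pooled)
    out = []
    k = off.sum()
    for i, r in enumerate(results):
        p_adj = np.full((d, d), np.nan)
        p_adj[off] = adj[i * k:(i + 1) * k]
        adjacency = np.zeros((d, d), dtype=int)
        adjacency[off] = (p_adj[off] < alpha).astype(int)
        out.append(replace(r, pvalues_adjusted=p_adj, adjacency=adjacency,
                           alpha=alpha))
    return out
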