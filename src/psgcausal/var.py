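"""Least-squares VAR fitting, companion form, and AICc order selection.

Data enter time-major (m x d) and are assumed centered: the VAR is fitted
without an intercept. The residual covariance uses the maximum-likelihood
divisor (the effective row count m - p), so likelihood ratios between nested
models are exact — the Granger statistic and the information criteria both
depend on that consistency.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import ConfigError, RankDeficientError

MAX_ORDER_DEFAULT = 19

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class VarModel:
    """An estimated VAR(p): ``x_t = sum_k A_k x_{t-k} + e_t``.

    ``coeffs[k-1][i, j]`` is the effect of channel ``j`` at lag ``k`` on
    channel ``i``. ``resid_cov`` is the ML residual covariance estimate.
    """

    order: int
    coeffs: np.ndarray            # (p, d, d)
    resid_cov: np.ndarray         # (d, d)
    n_effective: int
    loglik: float
    d: int

    def companion_matrix(self) -> np.ndarray:
        """First-order (companion) form: top block row [A_1 ... A_p],
        identity blocks on the subdiagonal."""
        p, d = self.order, self.d
        comp = np.zeros((p * d, p * d))
        comp[:d] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[d:, :-d] = np.eye((p - 1) * d)
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion_matrix())).max())

    @property
    def n_params(self) -> int:
        """Total free mean parameters K = p * d^2."""
        return self.order * self.d * self.d

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def aicc(self) -> float:
        """Corrected AIC with the small-sample penalty.

        AICc = AIC + 2K(K+1) / (n_eff * d - K - 1); the denominator must be
        positive, otherwise the order is inadmissible for this window.
        """
        K = self.n_params
        denom = self.n_effective * self.d - K - 1
        if denom <= 0:
            raise ConfigError(
                f"order {self.order} too high for {self.n_effective} rows: "
                f"AICc correction denominator {denom} <= 0")
        return self.aic() + 2.0 * K * (K + 1) / denom


def build_var_design(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Targets and lag design for OLS: rows t = p..m-1.

    Returns (targets (m-p, d), design (m-p, p*d)); design columns are lag
    blocks, most recent lag first.
    """
    x = np.asarray(x, dtype=float)
    m, d = x.shape
    p = order
    if p < 1:
        raise ConfigError("order must be >= 1")
    if m <= p:
        raise ConfigError(f"window of {m} samples cannot support order {p}")
    targets = x[p:]
    design = np.empty((m - p, p * d))
    for k in range(1, p + 1):
        design[:, (k - 1) * d:k * d] = x[p - k:m - k]
    return targets, design


def _gaussian_loglik(resid_cov: np.ndarray, n: int, d: int) -> float:
    sign, logdet = np.linalg.slogdet(resid_cov)
    if sign <= 0:
        return -np.inf
    return -0.5 * n * (d * _LOG_2PI + logdet + d)


def _solve_ols(gram: np.ndarray, cross: np.ndarray) -> np.ndarray:
    """Solve gram @ B = cross via Cholesky; raises on rank deficiency."""
    try:
        c, low = linalg.cho_factor(gram, lower=True, check_finite=False)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise RankDeficientError(f"singular design matrix: {exc}") from exc
    return linalg.cho_solve((c, low), cross, check_finite=False)


def _describe_degenerate_channels(x: np.ndarray) -> str:
    stds = x.std(axis=0)
    bad = [str(i) for i in np.nonzero(stds < 1e-12)[0]]
    if bad:
        return f"constant channel(s): {', '.join(bad)}"
    return "collinear channels (design matrix not full rank)"


def fit_var(x: np.ndarray, order: int) -> VarModel:
    """OLS fit of a VAR(p) on centered time-major data (m x d), no intercept."""
    x = np.asarray(x, dtype=float)
    m, d = x.shape
    if m <= order * d + 1:
        raise ConfigError(
            f"window too short ({m} samples) for order {order} with {d} channels")
    targets, design = build_var_design(x, order)
    n = m - order
    gram = design.T @ design
    cross = design.T @ targets
    try:
        B = _solve_ols(gram, cross)
    except RankDeficientError:
        raise RankDeficientError(
            f"VAR({order}) fit failed: {_describe_degenerate_channels(x)}")
    resid = targets - design @ B
    resid_cov = resid.T @ resid / n
    resid_cov = 0.5 * (resid_cov + resid_cov.T)
    # design column blocks are (lag k, source channel); equation for channel i
    # reads row i of A_k, hence the reshape/transpose below
    coeffs = B.reshape(order, d, d).transpose(0, 2, 1)
    loglik = _gaussian_loglik(resid_cov, n, d)
    return VarModel(order=order, coeffs=coeffs, resid_cov=resid_cov,
                    n_effective=n, loglik=loglik, d=d)


def select_order(x: np.ndarray, max_order: int = MAX_ORDER_DEFAULT,
                 criterion: str = "aicc") -> tuple[int, dict[int, float]]:
    """Fit orders 1..max_order, return (argmin order, score table).

    All candidate orders are scored on the same effective sample — the rows
    from ``max_order`` onward, with shallower candidates conditioning on the
    extra pre-sample values — so their log-likelihoods are comparable. Scoring
    each order on its own (m - p)-row sample instead makes the criterion
    nearly flat in p for small channel counts, because the likelihood terms
    dropped with the longer pre-sample almost cancel the parameter penalty.

    Ties break toward the smaller order; orders whose AICc correction is
    inadmissible for the window length are skipped.
    """
    if criterion not in ("aicc", "aic"):
        raise ConfigError(f"unknown criterion {criterion!r}")
    x = np.asarray(x, dtype=float)
    scores: dict[int, float] = {}
    best_order, best_score = None, np.inf
    for p in range(1, max_order + 1):
        try:
            model = fit_var(x[max_order - p:], p)
            score = model.aicc() if criterion == "aicc" else model.aic()
        except ConfigError:
            continue
        except RankDeficientError:
            raise
        scores[p] = score
        if score < best_score:
            best_order, best_score = p, score
    if best_order is None:
        raise ConfigError(
            f"no admissible order in 1..{max_order} for a window of "
            f"{x.shape[0]} samples")
    return best_order, scores
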