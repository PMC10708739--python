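"""Dynamic Bayesian network structure learning by continuous optimisation.

Learns a contemporaneous weight matrix W (d x d, acyclicity-constrained) and
stacked lagged weights A ((p*d) x d) by minimising

    (1/2n) ||X - X W - Y A||_F^2 + lambda_W ||W||_1 + lambda_A ||A||_1
    subject to   h(W) = tr(e^{W o W}) - d = 0,

where Y is the lag matrix built from the p preceding steps of X and ``o``
is the elementwise product. h is the smooth acyclicity function: it is zero
iff the weighted graph of W has no directed cycle. The constraint is
enforced with an augmented Lagrangian; the l1 terms are handled by splitting
every weight into nonnegative positive/negative parts so the inner problem
is smooth and box-constrained (solved with L-BFGS-B).

Terminology note: W is the *contemporaneous* (same-time-slice) matrix and A
holds the *lagged* blocks. ``W[i, j]`` means channel i -> channel j at the
same time step; lag-k block ``A[(k-1)*d:k*d, j]`` holds the effects of every
channel k steps back on channel j (most recent lag first).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .exceptions import ConfigError, ConvergenceError

#: Penalty weights: documented defaults for 20-s z-scored windows.
LAMBDA_W_DEFAULT = 0.0005
LAMBDA_A_DEFAULT = 0.005

#: Edge thresholds: the method family's customary low default, and the
#: value at which thresholded DBN graphs best match the Granger graphs.
TAU_DEFAULT = 0.01
TAU_GC_MATCHED = 0.018

_LOG_2PI = float(np.log(2.0 * np.pi))


def build_lag_matrix(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Current-step matrix X (n x d) and lag matrix Y (n x p*d), n = m+1-p.

    Row t of Y concatenates the p preceding steps of row t of X, most recent
    lag first. The row count m+1-p means the earliest retained row is one
    step short of a full lag history; its missing deepest-lag entry is
    zero-padded (data are centered, so zero is the unconditional mean).
    """
    x = np.asarray(x, dtype=float)
    m, d = x.shape
    p = order
    if p < 1:
        raise ConfigError("order must be >= 1")
    if m <= p:
        raise ConfigError(f"need more than {p} samples, got {m}")
    n = m + 1 - p
    X = x[p - 1:]
    Y = np.zeros((n, p * d))
    for k in range(1, p + 1):
        blk = Y[:, (k - 1) * d:k * d]
        lo = p - 1 - k
        if lo >= 0:
            blk[:] = x[lo:m - k]
        else:  # first row lacks lag p; leave its zero pad
            blk[1:] = x[0:m - k]
    return X, Y


def acyclicity(W: np.ndarray) -> float:
    """h(W) = tr(exp(W o W)) - d; zero iff the graph of W is acyclic."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ConfigError("acyclicity expects a square matrix")
    E = linalg.expm(W * W)
    return float(np.trace(E) - W.shape[0])


def _acyclicity_with_grad(W: np.ndarray) -> tuple[float, np.ndarray]:
    E = linalg.expm(W * W)
    h = float(np.trace(E) - W.shape[0])
    return h, 2.0 * E.T * W


@dataclass(frozen=True)
class DbnResults:
    """Fitted DBN weights plus optimiser diagnostics."""

    W: np.ndarray                 # (d, d) contemporaneous, zero diagonal
    A: np.ndarray                 # (p*d, d) lagged, most recent lag first
    lambda_w: float
    lambda_a: float
    order: int
    n_rows: int
    objective: float              # loss + l1 penalties at the solution
    h_final: float
    channel_names: list[str] | None = field(default=None, compare=False)

    @property
    def d(self) -> int:
        return self.W.shape[0]

    def lag_block(self, k: int) -> np.ndarray:
        """Lag-k block of A as a d x d matrix (source row, target column)."""
        d = self.d
        if not (1 <= k <= self.order):
            raise ConfigError(f"lag {k} outside 1..{self.order}")
        return self.A[(k - 1) * d:k * d]

    def threshold(self, tau: float = TAU_DEFAULT) -> "DbnSummary":
        return threshold_and_collapse(self, tau)

    def summary(self, tau: float = TAU_DEFAULT) -> pd.DataFrame:
        """Long-format edge table of weights surviving |w| >= tau."""
        names = self.channel_names or [f"ch{i}" for i in range(self.d)]
        rows = []
        for lag in range(0, self.order + 1):
            M = self.W if lag == 0 else self.lag_block(lag)
            src, tgt = np.nonzero(np.abs(M) >= tau)
            for s, t in zip(src, tgt):
                rows.append({"source": names[s], "target": names[t],
                             "lag": lag, "weight": M[s, t]})
        return pd.DataFrame(rows, columns=["source", "target", "lag", "weight"])


@dataclass(frozen=True)
class DbnSummary:
    """Thresholded adjacencies and the lag-collapsed comparison graph."""

    W_binary: np.ndarray            # (d, d)
    A_binary: np.ndarray            # (p, d, d) per-lag blocks
    collapsed: np.ndarray           # (d, d), rows = target, cols = source
    tau: float


def threshold_and_collapse(result: DbnResults, tau: float) -> DbnSummary:
    """Absolute-value thresholding plus the lag-collapsed graph.

    ``collapsed[x, y] = 1`` iff any contemporaneous or lagged link y -> x
    survives the threshold; self-links (a channel's own past) are omitted,
    matching the orientation of the Granger adjacency for comparison.
    """
    if tau < 0:
        raise ConfigError("tau must be >= 0")
    d, p = result.d, result.order
    w_bin = (np.abs(result.W) >= tau).astype(int) if tau > 0 else \
        (result.W != 0).astype(int)
    a_bin = np.zeros((p, d, d), dtype=int)
    for k in range(1, p + 1):
        blk = result.lag_block(k)
        a_bin[k - 1] = (np.abs(blk) >= tau).astype(int) if tau > 0 else \
            (blk != 0).astype(int)
    any_link = w_bin | np.bitwise_or.reduce(a_bin, axis=0)  # [source, target]
    collapsed = any_link.T.copy()                            # [target, source]
    np.fill_diagonal(collapsed, 0)
    return DbnSummary(W_binary=w_bin, A_binary=a_bin, collapsed=collapsed,
                      tau=tau)


def _inner_objective(theta, X, Y, n, d, pd_, lw, la, rho, alpha_m):
    dd = d * d
    ad = pd_ * d
    wp = theta[:dd].reshape(d, d)
    wn = theta[dd:2 * dd].reshape(d, d)
    ap = theta[2 * dd:2 * dd + ad].reshape(pd_, d)
    an = theta[2 * dd + ad:].reshape(pd_, d)
    W = wp - wn
    A = ap - an
    R = X - X @ W - Y @ A
    loss = 0.5 / n * float(np.sum(R * R))
    h, gh = _acyclicity_with_grad(W)
    obj = (loss + lw * float(np.sum(wp + wn)) + la * float(np.sum(ap + an))
           + 0.5 * rho * h * h + alpha_m * h)
    gW = -(X.T @ R) / n + (rho * h + alpha_m) * gh
    gA = -(Y.T @ R) / n
    grad = np.concatenate([
        (gW + lw).ravel(), (-gW + lw).ravel(),
        (gA + la).ravel(), (-gA + la).ravel(),
    ])
    return obj, grad


def fit_dynotears(x: np.ndarray, order: int,
                  lambda_w: float = LAMBDA_W_DEFAULT,
                  lambda_a: float = LAMBDA_A_DEFAULT,
                  tol_h: float = 1e-8, max_outer: int = 100,
                  rho_init: float = 1.0, rho_mult: float = 10.0,
                  h_factor: float = 0.25, rho_max: float = 1e16,
                  constrain: bool = True,
                  channel_names: list[str] | None = None) -> DbnResults:
    """Augmented-Lagrangian fit of the penalised DBN objective.

    ``x`` is a z-scored time-major window (m x d). The outer loop raises the
    quadratic penalty by ``rho_mult`` whenever the acyclicity residual fails
    to shrink to ``h_factor`` of its previous value, updates the multiplier
    by rho * h each round, and stops once h <= tol_h. ``constrain=False``
    drops the acyclicity machinery entirely (used for the unconstrained
    cross-check against plain OLS).
    """
    x = np.asarray(x, dtype=float)
    d = x.shape[1]
    X, Y = build_lag_matrix(x, order)
    return _fit_on_design(X, Y, d, order, lambda_w, lambda_a, tol_h=tol_h,
                          max_outer=max_outer, rho_init=rho_init,
                          rho_mult=rho_mult, h_factor=h_factor,
                          rho_max=rho_max, constrain=constrain,
                          channel_names=channel_names)


def select_order_dbn(x: np.ndarray, max_order: int = 19,
                     lambda_w: float = LAMBDA_W_DEFAULT,
                     lambda_a: float = LAMBDA_A_DEFAULT,
                     tau: float = TAU_DEFAULT,
                     **fit_kwargs) -> tuple[int, dict[int, float]]:
    """AIC order selection for the DBN fit.

    AIC = -2 loglik + 2k with a Gaussian residual log-likelihood and k the
    count of weights surviving the active threshold. Ties break toward the
    smaller order.
    """
    x = np.asarray(x, dtype=float)
    d = x.shape[1]
    scores: dict[int, float] = {}
    best, best_score = None, np.inf
    for p in range(1, max_order + 1):
        try:
            res = fit_dynotears(x, p, lambda_w=lambda_w, lambda_a=lambda_a,
                                **fit_kwargs)
        except ConfigError:
            continue
        X, Y = build_lag_matrix(x, p)
        R = X - X @ res.W - Y @ res.A
        n = X.shape[0]
        sigma = R.T @ R / n
        sigma = 0.5 * (sigma + sigma.T)
        sign, logdet = np.linalg.slogdet(sigma)
        loglik = -np.inf if sign <= 0 else -0.5 * n * (d * _LOG_2PI + logdet + d)
        k = int((np.abs(res.W) >= tau).sum() + (np.abs(res.A) >= tau).sum())
        aic = -2.0 * loglik + 2.0 * k
        scores[p] = aic
        if aic < best_score:
            best, best_score = p, aic
    if best is None:
        raise ConfigError(f"no admissible order in 1..{max_order}")
    return best, scores


def cv_hyperparams(windows: list, grid: list[tuple[float, float]],
                   orders: range | list[int] = range(1, 11),
                   k_folds: int = 10, seed: int = 0,
                   **fit_kwargs) -> tuple[tuple[float, float], pd.DataFrame]:
    """K-fold cross-validation of the two penalty weights.

    For every (lambda_w, lambda_a) cell the held-out root-mean-squared
    reconstruction error ||X - XW - YA|| is averaged over folds and over the
    candidate orders; the argmin cell and the full score table are returned.
    ``windows`` may be Window objects (z-scored) or plain (m x d) arrays.
    """
    if not grid:
        raise ConfigError("hyperparameter grid is empty")
    arrays = []
    for w in windows:
        if isinstance(w, np.ndarray):
            arr = np.asarray(w, dtype=float)
        else:                       # windowing.Window: channels x samples
            arr = np.asarray(w.data, dtype=float).T
        arrays.append(arr)
    if len(arrays) < k_folds:
        raise ConfigError(
            f"need at least k_folds={k_folds} windows, got {len(arrays)}")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(len(arrays)) % k_folds
    orders = list(orders)
    rows = []
    for lw, la in grid:
        fold_scores = []
        for fold in range(k_folds):
            train = [a for a, f in zip(arrays, assignment) if f != fold]
            test = [a for a, f in zip(arrays, assignment) if f == fold]
            if not train or not test:
                continue
            for p in orders:
                xt = np.vstack([build_lag_matrix(a, p)[0] for a in train])
                yt = np.vstack([build_lag_matrix(a, p)[1] for a in train])
                res = _fit_stacked(xt, yt, p, lw, la, **fit_kwargs)
                xs = np.vstack([build_lag_matrix(a, p)[0] for a in test])
                ys = np.vstack([build_lag_matrix(a, p)[1] for a in test])
                resid = xs - xs @ res.W - ys @ res.A
                rmse = float(np.sqrt(np.mean(resid ** 2)))
                fold_scores.append(rmse)
        rows.append({"lambda_w": lw, "lambda_a": la,
                     "rmse": float(np.mean(fold_scores))})
    table = pd.DataFrame(rows)
    best_row = table.loc[table["rmse"].idxmin()]
    return (float(best_row["lambda_w"]), float(best_row["lambda_a"])), table


def _fit_stacked(X: np.ndarray, Y: np.ndarray, order: int,
                 lambda_w: float, lambda_a: float, **fit_kwargs) -> DbnResults:
    """Fit the DBN objective on pre-built (possibly stacked) X/Y matrices."""
    d = X.shape[1]
    return _fit_on_design(X, Y, d, order, lambda_w, lambda_a, **fit_kwargs)


def _fit_on_design(X, Y, d, order, lambda_w, lambda_a, tol_h=1e-8,
                   max_outer=100, rho_init=1.0, rho_mult=10.0, h_factor=0.25,
                   rho_max=1e16, constrain=True, channel_names=None):
    n = X.shape[0]
    pd_ = order * d
    dd, ad = d * d, pd_ * d
    theta = np.zeros(2 * dd + 2 * ad)
    bounds = [(0.0, None)] * theta.size
    for i in range(d):
        bounds[i * d + i] = (0.0, 0.0)
        bounds[dd + i * d + i] = (0.0, 0.0)

    def solve_inner(theta0, rho, alpha_m):
        res = optimize.minimize(
            _inner_objective, theta0, jac=True, method="L-BFGS-B",
            bounds=bounds,
            args=(X, Y, n, d, pd_, lambda_w, lambda_a, rho, alpha_m),
            options={"maxiter": 1000})
        if not np.isfinite(res.fun):
            raise ConvergenceError(f"inner solver diverged: {res.message}")
        return res.x

    if not constrain:
        theta = solve_inner(theta, 0.0, 0.0)
        h_val = np.nan
    else:
        rho, alpha_m = rho_init, 0.0
        h_prev, h_val = np.inf, np.inf
        for _ in range(max_outer):
            while rho < rho_max:
                theta_new = solve_inner(theta, rho, alpha_m)
                W_new = (theta_new[:dd] - theta_new[dd:2 * dd]).reshape(d, d)
                h_val = acyclicity(W_new)
                if h_val > h_factor * h_prev:
                    rho *= rho_mult
                else:
                    break
            theta = theta_new
            h_prev = h_val
            alpha_m += rho * h_val
            if h_val <= tol_h:
                break
        if h_val > tol_h:
            raise ConvergenceError(
                f"acyclicity residual {h_val:.3e} > {tol_h:.1e}")
    W = (theta[:dd] - theta[dd:2 * dd]).reshape(d, d)
    A = (theta[2 * dd:2 * dd + ad] - theta[2 * dd + ad:]).reshape(pd_, d)
    R = X - X @ W - Y @ A
    objective = (0.5 / n * float(np.sum(R * R))
                 + lambda_w * float(np.abs(W).sum())
                 + lambda_a * float(np.abs(A).sum()))
    return DbnResults(W=W, A=A, lambda_w=lambda_w, lambda_a=lambda_a,
                      order=order, n_rows=n, objective=objective,
                      h_final=float(acyclicity(W)), channel_names=channel_names)


class DynamicBayesianNetwork:
    """Model object: DBN structure learning for one (z-scored) window.

    Parameters mirror :func:`fit_dynotears`; ``order=None`` triggers AIC
    order selection over 1..max_order.
    """

    def __init__(self, data, order: int | None = None, max_order: int = 19,
                 lambda_w: float = LAMBDA_W_DEFAULT,
                 lambda_a: float = LAMBDA_A_DEFAULT,
                 channel_names: list[str] | None = None, **fit_kwargs):
        from .windowing import Window
        if isinstance(data, Window):
            if channel_names is None:
                channel_names = data.channel_names
            data = data.data.T
        self.data = np.asarray(data, dtype=float)
        self.order = order
        self.max_order = max_order
        self.lambda_w = lambda_w
        self.lambda_a = lambda_a
        self.channel_names = channel_names
        self.fit_kwargs = fit_kwargs

    def fit(self) -> DbnResults:
        order = self.order
        if order is None:
            order, _ = select_order_dbn(self.data, self.max_order,
                                        self.lambda_w, self.lambda_a,
                                        **self.fit_kwargs)
        return fit_dynotears(self.data, order, lambda_w=self.lambda_w,
                             lambda_a=self.lambda_a,
                             channel_names=self.channel_names,
                             **self.fit_kwargs)
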