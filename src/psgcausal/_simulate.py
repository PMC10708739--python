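"""Low-level structural-VAR simulation kernels.

The recursion is sequential in time, so it is JIT-compiled with numba when
available; a pure-Python loop with identical arithmetic is the fallback.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _svar_loop(out, coeffs, minv_t, eps, p):
    """x_t = Minv @ (sum_k C_k @ x_{t-k} + eps_t), written into ``out``.

    ``out`` is (n_total, d) with the first ``p`` rows pre-filled (initial
    state, normally zeros). ``coeffs[k-1]`` maps lag k to the current step in
    column-vector convention. ``minv_t`` is (I - W^T)^{-1}.
    """
    n_total, d = out.shape
    for t in range(p, n_total):
        acc = eps[t].copy()
        for k in range(p):
            acc = acc + coeffs[k] @ out[t - 1 - k]
        out[t] = minv_t @ acc
    return out


if _HAVE_NUMBA:
    _svar_loop_jit = njit(cache=False)(_svar_loop)
else:  # pragma: no cover
    _svar_loop_jit = _svar_loop


def simulate_svar(coeffs: np.ndarray, minv_t: np.ndarray, eps: np.ndarray,
                  p: int) -> np.ndarray:
    """Run the structural-VAR recursion over pre-drawn innovations.

    Parameters
    ----------
    coeffs : (p, d, d) array, lag-k block at index k-1, column-vector form.
    minv_t : (d, d) array, inverse of (I - W^T) for contemporaneous effects.
    eps : (n_total, d) innovations; the first p rows are ignored.
    p : lag order (0 allowed: pure contemporaneous noise).

    Returns the full (n_total, d) trajectory starting from a zero state.
    """
    n_total, d = eps.shape
    out = np.zeros((n_total, d), dtype=np.float64)
    if p == 0:
        return (minv_t @ eps.T).T
    out = _svar_loop_jit(out, np.ascontiguousarray(coeffs),
                         np.ascontiguousarray(minv_t),
                         np.ascontiguousarray(eps), p)
    return out
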