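"""Window selection with a covariance-stationarity screen.

Overnight recordings are not stationary as a whole (sleep stages, arousals,
position changes), so VAR modelling is done on short windows: 20-s spans
whose start times sit on a 10-s grid, drawn uniformly without replacement
and kept only if the fitted VAR, rewritten in first-order (companion) form,
has spectral radius below 1. Selection continues until a quota (50 by
default) of accepted windows is reached. With 20-s windows on a 10-s grid,
any two distinct windows overlap by exactly 50% or not at all.

Each candidate is mean-centered, its lag order chosen by AICc, and the
stationarity test run at that order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigError, RankDeficientError, WindowQuotaError
from .synthetic import Recording
from .var import MAX_ORDER_DEFAULT, fit_var, select_order

DEFAULT_WINDOW_S = 20.0
DEFAULT_GRID_S = 10.0
DEFAULT_QUOTA = 50


@dataclass
class Window:
    """One standardized analysis window (channels x samples)."""

    recording_id: str
    start_sample: int
    data: np.ndarray                       # (d, L)
    rate_hz: float
    standardization: str = "none"          # none | centered | zscored
    channel_names: list[str] | None = None
    order: int | None = None               # AICc-selected order, if known
    spectral_radius: float | None = None

    @property
    def d(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowSet:
    """Accepted stationary windows for one recording."""

    recording_id: str
    windows: list[Window]
    rejected_count: int
    seed: int
    rejection_reasons: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.windows)

    def to_manifest(self) -> pd.DataFrame:
        rows = [{"recording_id": w.recording_id, "start_sample": w.start_sample,
                 "order": w.order, "spectral_radius": w.spectral_radius,
                 "accepted": True} for w in self.windows]
        rows += [{"recording_id": self.recording_id, "start_sample": s,
                  "order": None, "spectral_radius": None, "accepted": False,
                  "reason": reason}
                 for s, reason in sorted(self.rejection_reasons.items())]
        return pd.DataFrame(rows)


def resample_to_common_rate(recording: Recording, target_hz: float) -> Recording:
    """Downsample (with anti-aliasing) to the common analysis rate.

    Identity when the rates already match; upsampling is refused — analyses
    are defined at or below the acquisition rate.
    """
    if recording.rate_hz == target_hz:
        return recording
    if recording.rate_hz < target_hz:
        raise ConfigError(
            f"cannot upsample {recording.subject_id} from {recording.rate_hz} "
            f"to {target_hz} Hz")
    from fractions import Fraction
    frac = Fraction(target_hz / recording.rate_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(recording.data, up, down, axis=1)
    return replace(recording, data=data, rate_hz=target_hz)


def standardize(window: Window, mode: str = "centered") -> Window:
    """Per-channel affine standardization: 'centered' or 'zscored'."""
    if mode not in ("centered", "zscored"):
        raise ConfigError(f"unknown standardization mode {mode!r}")
    data = window.data - window.data.mean(axis=1, keepdims=True)
    if mode == "zscored":
        sd = window.data.std(axis=1)
        zero = np.nonzero(sd <= 0)[0]
        if zero.size:
            names = (window.channel_names or [str(i) for i in range(window.d)])
            bad = ", ".join(names[i] for i in zero)
            raise ConfigError(
                f"zero-variance channel(s) cannot be z-scored: {bad}")
        data = data / sd[:, None]
    return replace(window, data=data, standardization=mode)


def is_stationary(window: Window, order: int) -> tuple[bool, float]:
    """Fit a VAR at ``order`` and test companion spectral radius < 1.

    The window is centered first (the radius is shift invariant, but the
    no-intercept fit requires it). Raises RankDeficientError for degenerate
    windows (e.g. a constant channel) so callers can log a distinct reason.
    """
    L = window.n_samples
    if L <= order * window.d:
        raise ConfigError(
            f"window of {L} samples too short for a VAR({order}) in "
            f"{window.d} channels")
    x = window.data.T
    x = x - x.mean(axis=0)
    model = fit_var(x, order)
    radius = model.spectral_radius()
    return bool(radius < 1.0), float(radius)


def grid_starts(n_samples: int, window_len: int, grid_step: int) -> np.ndarray:
    """All admissible start samples (multiples of the grid step)."""
    last = n_samples - window_len
    if last < 0:
        return np.array([], dtype=int)
    return np.arange(0, last + 1, grid_step, dtype=int)


def select_windows(recording: Recording, window_s: float = DEFAULT_WINDOW_S,
                   grid_s: float = DEFAULT_GRID_S, quota: int = DEFAULT_QUOTA,
                   seed: int = 0, max_order: int = MAX_ORDER_DEFAULT,
                   standardization: str = "centered") -> WindowSet:
    """Randomly draw grid-aligned candidates until ``quota`` pass the screen.

    Candidates are drawn uniformly without replacement from the start grid;
    each is centered, order-selected by AICc over 1..max_order, and accepted
    iff the fitted VAR is stable. Deterministic given ``seed``. Raises
    WindowQuotaError when the grid is exhausted first.
    """
    L = int(round(window_s * recording.rate_hz))
    step = int(round(grid_s * recording.rate_hz))
    starts = grid_starts(recording.n_samples, L, step)
    if starts.size < quota:
        raise WindowQuotaError(
            f"{recording.subject_id}: only {starts.size} grid positions for a "
            f"quota of {quota} windows")
    rng = np.random.default_rng(seed)
    candidate_order = rng.permutation(starts)
    accepted: list[Window] = []
    reasons: dict[int, str] = {}
    for start in candidate_order:
        raw = Window(recording_id=recording.subject_id, start_sample=int(start),
                     data=recording.data[:, start:start + L],
                     rate_hz=recording.rate_hz,
                     channel_names=recording.channel_names)
        win = standardize(raw, "centered")
        try:
            order, _ = select_order(win.data.T, max_order=max_order)
            ok, radius = is_stationary(win, order)
        except RankDeficientError:
            reasons[int(start)] = "rank-deficient"
            continue
        if not ok:
            reasons[int(start)] = "nonstationary"
            continue
        if standardization == "zscored":
            win = standardize(raw, "zscored")
        win.order = order
        win.spectral_radius = radius
        accepted.append(win)
        if len(accepted) == quota:
            break
    if len(accepted) < quota:
        counts = pd.Series(list(reasons.values())).value_counts().to_dict()
        raise WindowQuotaError(
            f"{recording.subject_id}: grid exhausted with {len(accepted)} of "
            f"{quota} windows accepted; rejections: {counts}")
    return WindowSet(recording_id=recording.subject_id, windows=accepted,
                     rejected_count=len(reasons), seed=seed,
                     rejection_reasons=reasons)


def write_windows_manifest(window_sets: list[WindowSet], path: str | Path) -> None:
    frames = [ws.to_manifest() for ws in window_sets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
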