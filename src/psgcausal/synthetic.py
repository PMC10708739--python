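"""Synthetic polysomnography-like cohorts with known causal structure.

Generates stable structural vector-autoregressive (SVAR) ground-truth models
with sparse lagged and contemporaneous (DAG) effects, simulates multichannel
recordings from them, and assembles whole cohorts in which a subject-level
covariate (a waist-girth analogue) monotonically modulates the strength of a
single designated lagged link. Because real overnight sleep-study datasets
are access restricted, these cohorts are the test bed for every downstream
stage: the windowing screen, Granger causality, DBN structure learning and
the cohort-level covariate association protocol.

Conventions
-----------
* ``lagged_coeffs[k-1]`` is the lag-``k`` matrix ``A_k`` in column-vector
  form: entry ``[i, j]`` is the effect of channel ``j`` at lag ``k`` on
  channel ``i`` now (``x_t = C x_t + sum_k A_k x_{t-k} + eps_t``).
* ``contemporaneous`` uses the same target-row convention: ``C[i, j]`` is
  the instantaneous effect of channel ``j`` on channel ``i``; its nonzero
  pattern is acyclic by construction.
* ``edge_list`` stores ``(source, target, lag)`` with ``lag == 0`` meaning
  contemporaneous.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ._simulate import simulate_svar
from .exceptions import ConfigError, InstabilityError

#: The ten-channel roster of a typical overnight sleep study.
DEFAULT_CHANNELS = [
    "EOG_1", "EOG_2", "EEG_LC", "EEG_LO", "EMG_Leg",
    "Snore", "ECG", "Nasal_Pressure", "Position", "Blood_Oxygen",
]

DEFAULT_RATE_HZ = 100.0
DEFAULT_BURN_IN = 1000


@dataclass(frozen=True)
class GroundTruthModel:
    """A stable SVAR generative law with known causal edges."""

    d: int
    p: int
    lagged_coeffs: np.ndarray          # (p, d, d), A_k at index k-1
    contemporaneous: np.ndarray        # (d, d), acyclic, zero diagonal
    noise_cov: np.ndarray              # (d, d), symmetric positive definite
    edge_list: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        lag = np.asarray(self.lagged_coeffs, dtype=float)
        if lag.shape != (self.p, self.d, self.d):
            raise ConfigError(
                f"lagged_coeffs must have shape ({self.p}, {self.d}, {self.d})")
        C = np.asarray(self.contemporaneous, dtype=float)
        if C.shape != (self.d, self.d):
            raise ConfigError("contemporaneous matrix has wrong shape")
        S = np.asarray(self.noise_cov, dtype=float)
        if not np.allclose(S, S.T, atol=1e-12):
            raise ConfigError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ConfigError("noise_cov must be positive definite")

    @property
    def structural_inverse(self) -> np.ndarray:
        """(I - C)^{-1}: maps structural shocks to reduced-form effects."""
        return np.linalg.inv(np.eye(self.d) - self.contemporaneous)

    def reduced_form_coeffs(self) -> np.ndarray:
        """Reduced-form VAR matrices B_k = (I - C)^{-1} A_k, shape (p, d, d)."""
        minv = self.structural_inverse
        return np.einsum("ij,kjl->kil", minv, self.lagged_coeffs)

    def spectral_radius(self) -> float:
        """Companion-form spectral radius of the reduced-form VAR."""
        B = self.reduced_form_coeffs()
        if self.p == 0 or not np.any(B):
            return 0.0
        comp = _companion(B)
        return float(np.abs(np.linalg.eigvals(comp)).max())

    def stationary_covariance(self) -> np.ndarray:
        """Model-implied stationary covariance (discrete Lyapunov solve)."""
        B = self.reduced_form_coeffs()
        d, p = self.d, self.p
        minv = self.structural_inverse
        q_small = minv @ self.noise_cov @ minv.T
        comp = _companion(B)
        Q = np.zeros((p * d, p * d))
        Q[:d, :d] = q_small
        big = linalg.solve_discrete_lyapunov(comp, Q)
        return big[:d, :d]


@dataclass
class Recording:
    """One subject's multichannel recording plus covariates."""

    subject_id: str
    data: np.ndarray               # (d, m) channels x samples
    rate_hz: float
    channel_names: list[str]
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("Recording data must be a 2-D channels x samples array")
        if len(self.channel_names) != self.data.shape[0]:
            raise ConfigError("channel_names length must equal the channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigError("channel_names must be unique")
        if not np.isfinite(self.data).all():
            raise ConfigError(f"recording {self.subject_id} contains non-finite values")

    @property
    def d(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class CovariateSpec:
    """A subject covariate that scales one designated lagged edge.

    ``effect`` maps the covariate value to a nonnegative multiplier applied
    to the target edge's generative weight; it must be monotone over the
    covariate's support.
    """

    name: str
    distribution: stats.rv_continuous | object   # frozen scipy distribution
    target_edge: tuple[int, int, int]            # (source, target, lag >= 1)
    effect: Callable[[float], float]

    def __post_init__(self):
        s, t, lag = self.target_edge
        if lag < 1:
            raise ConfigError("the modulated edge must be a lagged link (lag >= 1)")


def logistic_ramp(midpoint: float, scale: float, max_mult: float) -> Callable[[float], float]:
    """Monotone multiplier ramp: max_mult / (1 + exp(-(c - midpoint)/scale))."""

    def effect(c: float) -> float:
        return max_mult / (1.0 + np.exp(-(c - midpoint) / scale))

    return effect


def default_waist_covariate(channel_names: Sequence[str] = DEFAULT_CHANNELS,
                            ) -> CovariateSpec:
    """Waist-girth analogue modulating the ECG -> EEG_LO lag-1 link.

    A truncated normal (mean 95 cm, sd 15 cm, support 60-150 cm) is a
    realistic adult waist-girth distribution; the logistic ramp makes the
    link essentially absent for the smallest waists and close to full
    strength (x1.8 of baseline) for the largest, a strongly monotone effect.
    """
    loc, scale_, lo, hi = 95.0, 15.0, 60.0, 150.0
    dist = stats.truncnorm((lo - loc) / scale_, (hi - loc) / scale_,
                           loc=loc, scale=scale_)
    src = list(channel_names).index("ECG")
    tgt = list(channel_names).index("EEG_LO")
    return CovariateSpec(
        name="waist_girth_cm",
        distribution=dist,
        target_edge=(src, tgt, 1),
        effect=logistic_ramp(midpoint=95.0, scale=8.0, max_mult=1.8),
    )


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------

def _companion(B: np.ndarray) -> np.ndarray:
    """First-order companion matrix of reduced-form lag matrices (p, d, d)."""
    p, d, _ = B.shape
    comp = np.zeros((p * d, p * d))
    comp[:d] = np.concatenate(list(B), axis=1)
    if p > 1:
        comp[d:, :-d] = np.eye((p - 1) * d)
    return comp


def _radius_of(lagged: np.ndarray, contemporaneous: np.ndarray) -> float:
    d = contemporaneous.shape[0]
    minv = np.linalg.inv(np.eye(d) - contemporaneous)
    B = np.einsum("ij,kjl->kil", minv, lagged)
    if not np.any(B):
        return 0.0
    return float(np.abs(np.linalg.eigvals(_companion(B))).max())


def _edges_from_matrices(lagged: np.ndarray, contemporaneous: np.ndarray) -> frozenset:
    edges = set()
    p = lagged.shape[0]
    for k in range(p):
        tgt, src = np.nonzero(lagged[k])
        edges.update((int(s), int(t), k + 1) for s, t in zip(src, tgt))
    tgt, src = np.nonzero(contemporaneous)
    edges.update((int(s), int(t), 0) for s, t in zip(src, tgt))
    return frozenset(edges)


def make_ground_truth(d: int = 10, p: int = 2, lag_density: float = 0.1,
                      contemp_density: float = 0.05,
                      target_spectral_radius: float = 0.9,
                      seed: int = 0) -> GroundTruthModel:
    """Sample a sparse, stable SVAR ground truth.

    Lagged coefficients are drawn on a Bernoulli(lag_density) mask with
    magnitudes in [0.3, 0.9] and random signs, then rescaled by a common
    factor until the companion spectral radius of the reduced form hits
    ``target_spectral_radius`` (within 1e-3). Contemporaneous edges are
    sampled only "upward" along a random permutation of the channels, which
    guarantees the instantaneous graph is a DAG.
    """
    if not (0.0 < target_spectral_radius < 1.0):
        raise ConfigError("target_spectral_radius must lie in (0, 1)")
    if not (0.0 <= lag_density <= 1.0 and 0.0 <= contemp_density <= 1.0):
        raise ConfigError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    # cross-channel effects on a Bernoulli mask; every channel additionally
    # keeps a lag-1 autoregressive term (physiological signals are strongly
    # autocorrelated, and a purely nilpotent cross pattern would make the
    # target radius unreachable)
    mask = rng.random((p, d, d)) < lag_density
    for k in range(p):
        np.fill_diagonal(mask[k], False)
    mags = rng.uniform(0.3, 0.9, size=(p, d, d))
    signs = np.where(rng.random((p, d, d)) < 0.5, -1.0, 1.0)
    lagged = np.where(mask, mags * signs, 0.0)
    if lag_density > 0:
        np.fill_diagonal(lagged[0], rng.uniform(0.3, 0.9, size=d))

    order = rng.permutation(d)
    pos = np.empty(d, dtype=int)
    pos[order] = np.arange(d)
    contemporaneous = np.zeros((d, d))
    for j in range(d):          # source
        for i in range(d):      # target
            if pos[j] < pos[i] and rng.random() < contemp_density:
                w = rng.uniform(0.3, 0.8) * (1 if rng.random() < 0.5 else -1)
                contemporaneous[i, j] = w

    noise_cov = np.diag(rng.uniform(0.8, 1.2, size=d))

    if np.any(lagged):
        lagged = _rescale_to_radius(lagged, contemporaneous,
                                    target_spectral_radius)
    return GroundTruthModel(
        d=d, p=p, lagged_coeffs=lagged, contemporaneous=contemporaneous,
        noise_cov=noise_cov,
        edge_list=_edges_from_matrices(lagged, contemporaneous),
    )


def _rescale_to_radius(lagged: np.ndarray, contemporaneous: np.ndarray,
                       target: float, tol: float = 1e-3,
                       max_doublings: int = 60) -> np.ndarray:
    """Uniformly rescale lag matrices so the companion radius equals target."""

    def rho(s: float) -> float:
        return _radius_of(s * lagged, contemporaneous)

    hi = 1.0
    n = 0
    while rho(hi) < target:
        hi *= 2.0
        n += 1
        if n > max_doublings or not np.isfinite(rho(hi)):
            raise InstabilityError(
                "could not bracket the target spectral radius while rescaling")
    s_star = optimize.brentq(lambda s: rho(s) - target, 0.0, hi, xtol=1e-10)
    out = s_star * lagged
    achieved = _radius_of(out, contemporaneous)
    if abs(achieved - target) > tol:
        raise InstabilityError(
            f"rescaling failed: achieved radius {achieved:.6f}, target {target}")
    return out


def set_edge_weight(model: GroundTruthModel, source: int, target: int,
                    lag: int, weight: float) -> GroundTruthModel:
    """Return a copy of ``model`` with one edge weight replaced.

    Used to plant a designated link before cohort generation. Raises if the
    change destabilizes the process.
    """
    if lag < 0 or lag > model.p:
        raise ConfigError(f"lag {lag} outside the model's order range")
    lagged = model.lagged_coeffs.copy()
    contemporaneous = model.contemporaneous.copy()
    if lag == 0:
        contemporaneous[target, source] = weight
    else:
        lagged[lag - 1][target, source] = weight
    radius = _radius_of(lagged, contemporaneous)
    if radius >= 1.0:
        raise InstabilityError(
            f"setting edge ({source}->{target}, lag {lag}) to {weight} gives "
            f"spectral radius {radius:.4f} >= 1")
    return replace(model, lagged_coeffs=lagged, contemporaneous=contemporaneous,
                   edge_list=_edges_from_matrices(lagged, contemporaneous))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_recording(model: GroundTruthModel, n_seconds: float,
                       rate_hz: float = DEFAULT_RATE_HZ,
                       burn_in: int = DEFAULT_BURN_IN,
                       seed: int | np.random.SeedSequence = 0,
                       subject_id: str = "S0000",
                       channel_names: Sequence[str] | None = None,
                       covariates: dict | None = None) -> Recording:
    """Simulate one recording from a ground-truth model.

    The recursion starts from a zero state; the first ``burn_in`` samples are
    discarded so the returned span is (approximately) a draw from the
    stationary law. Deterministic given the seed.
    """
    m = int(round(n_seconds * rate_hz))
    if m <= 0:
        raise ConfigError("n_seconds * rate_hz must be positive")
    if burn_in < model.p:
        raise ConfigError("burn_in must be at least the model order")
    rng = np.random.default_rng(seed)
    n_total = burn_in + m
    chol = np.linalg.cholesky(model.noise_cov)
    eps = rng.standard_normal((n_total, model.d)) @ chol.T
    minv = model.structural_inverse
    traj = simulate_svar(model.lagged_coeffs, minv, eps, model.p)
    if not np.isfinite(traj).all():
        raise InstabilityError(
            f"simulation of {subject_id} produced non-finite values "
            f"(model spectral radius {model.spectral_radius():.4f})")
    if channel_names is None:
        channel_names = (DEFAULT_CHANNELS if model.d == len(DEFAULT_CHANNELS)
                         else [f"ch{i}" for i in range(model.d)])
    return Recording(subject_id=subject_id, data=traj[burn_in:].T,
                     rate_hz=rate_hz, channel_names=list(channel_names),
                     covariates=dict(covariates or {}))


def make_cohort(n_subjects: int, model: GroundTruthModel,
                covariate: CovariateSpec, n_seconds: float,
                seed: int = 0, rate_hz: float = DEFAULT_RATE_HZ,
                burn_in: int = DEFAULT_BURN_IN,
                channel_names: Sequence[str] | None = None,
                ) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a cohort whose covariate modulates the designated edge.

    Per-subject seeds derive from the master seed through counter-keyed
    ``SeedSequence`` children, so subject ``i`` is identical regardless of
    ``n_subjects``. Each subject also receives a balanced binary ``sex``
    covariate (independent of the signal law) for stratified views.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    src, tgt, lag = covariate.target_edge
    base_weight = model.lagged_coeffs[lag - 1][tgt, src]
    recordings: list[Recording] = []
    rows = []
    for i in range(n_subjects):
        sid = f"S{i:04d}"
        cov_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 0)))
        sim_seq = np.random.SeedSequence(seed, spawn_key=(i, 1))
        aux_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 2)))
        c = float(covariate.distribution.rvs(random_state=cov_rng))
        mult = float(covariate.effect(c))
        if mult < 0:
            raise ConfigError(f"covariate effect returned a negative multiplier for {sid}")
        try:
            subj_model = set_edge_weight(model, src, tgt, lag, base_weight * mult)
        except InstabilityError as exc:
            raise InstabilityError(
                f"covariate modulation destabilizes subject {sid}: {exc}") from exc
        sex = "F" if aux_rng.random() < 0.5 else "M"
        covs = {covariate.name: c, "sex": sex}
        rec = simulate_recording(subj_model, n_seconds, rate_hz=rate_hz,
                                 burn_in=burn_in, seed=sim_seq, subject_id=sid,
                                 channel_names=channel_names, covariates=covs)
        recordings.append(rec)
        # the realized multiplier is ground truth, not an observed covariate;
        # it is deliberately kept out of the covariate table
        rows.append({"subject_id": sid, covariate.name: c, "sex": sex})
    table = pd.DataFrame(rows)
    return recordings, table


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

SUPPORTED_FORMATS = ("csv", "npz")


def _model_to_json(model: GroundTruthModel) -> dict:
    return {
        "d": model.d, "p": model.p,
        "lagged_coeffs": model.lagged_coeffs.tolist(),
        "contemporaneous": model.contemporaneous.tolist(),
        "noise_cov": model.noise_cov.tolist(),
        "edge_list": sorted(list(e) for e in model.edge_list),
    }


def model_from_json(obj: dict) -> GroundTruthModel:
    return GroundTruthModel(
        d=obj["d"], p=obj["p"],
        lagged_coeffs=np.asarray(obj["lagged_coeffs"], dtype=float),
        contemporaneous=np.asarray(obj["contemporaneous"], dtype=float),
        noise_cov=np.asarray(obj["noise_cov"], dtype=float),
        edge_list=frozenset(tuple(e) for e in obj["edge_list"]),
    )


def write_cohort(recordings: Sequence[Recording], directory: str | Path,
                 fmt: str = "npz", ground_truth: GroundTruthModel | None = None,
                 covariate_table: pd.DataFrame | None = None,
                 extra_manifest: dict | None = None) -> dict:
    """Write a cohort to disk; returns the manifest (also saved as JSON).

    csv and npz round-trip the signal matrices bit-exactly (csv uses 17
    significant digits). The manifest records the ground truth and per-file
    layout so everything downstream can be re-derived.
    """
    if fmt not in SUPPORTED_FORMATS:
        raise ConfigError(
            f"unsupported format {fmt!r}; supported formats: {', '.join(SUPPORTED_FORMATS)}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for rec in recordings:
        if fmt == "npz":
            path = directory / f"{rec.subject_id}.npz"
            np.savez(path, data=rec.data, rate_hz=rec.rate_hz,
                     channel_names=np.array(rec.channel_names))
        else:
            path = directory / f"{rec.subject_id}.csv"
            df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
            df.to_csv(path, index=False, float_format="%.17g")
        files[rec.subject_id] = path.name
    if covariate_table is not None:
        covariate_table.to_csv(directory / "covariates.csv", index=False,
                               float_format="%.17g")
    manifest = {
        "format": fmt,
        "rate_hz": recordings[0].rate_hz if recordings else None,
        "channel_names": recordings[0].channel_names if recordings else [],
        "files": files,
        "n_subjects": len(recordings),
    }
    if ground_truth is not None:
        manifest["ground_truth"] = _model_to_json(ground_truth)
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_cohort(directory: str | Path) -> tuple[list[Recording], pd.DataFrame | None, dict]:
    """Read a cohort written by :func:`write_cohort`.

    Returns (recordings, covariate table or None, manifest).
    """
    directory = Path(directory)
    manifest_path = directory / "ground_truth.json"
    if not manifest_path.exists():
        raise ConfigError(f"no cohort manifest at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cov_path = directory / "covariates.csv"
    table = pd.read_csv(cov_path) if cov_path.exists() else None
    cov_by_id = {}
    if table is not None:
        cov_by_id = {row["subject_id"]: {k: row[k] for k in table.columns
                                         if k != "subject_id"}
                     for _, row in table.iterrows()}
    recordings = []
    for sid, name in manifest["files"].items():
        path = directory / name
        if manifest["format"] == "npz":
            with np.load(path, allow_pickle=False) as z:
                data = z["data"]
                rate = float(z["rate_hz"])
                names = [str(s) for s in z["channel_names"]]
        else:
            df = pd.read_csv(path)
            data = df.to_numpy().T
            rate = float(manifest["rate_hz"])
            names = list(df.columns)
        recordings.append(Recording(subject_id=sid, data=data, rate_hz=rate,
                                    channel_names=names,
                                    covariates=cov_by_id.get(sid, {})))
    return recordings, table, manifest
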