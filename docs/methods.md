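# Methods

This note records the models, estimators, parameter defaults, and numerical
choices behind `psgcausal`, and what the synthetic data generator does and
does not emulate.

## Synthetic generative model

Each subject's recording is drawn from a structural VAR (SVAR):

```
x_t = C x_t + Σ_{k=1..p} A_k x_{t−k} + ε_t,     ε_t ~ N(0, Σ)
```

with `C` the instantaneous (contemporaneous) coefficient matrix and `A_k` the
lag-k matrices, both stored `[target, source]`. `C` is constrained acyclic by
sampling edges only "upward" with respect to a random permutation of the
channels, so `(I − C)` is invertible and the reduced form
`x_t = (I − C)^{-1}(Σ A_k x_{t−k} + ε_t)` is well defined.

Construction (`make_ground_truth`):

- Off-diagonal lagged edges appear with probability `lag_density` and
  magnitudes uniform on [0.3, 0.9] with random sign; contemporaneous edges
  with probability `contemp_density`, magnitudes on [0.3, 0.8].
- Whenever `lag_density > 0`, every channel also receives a lag-1
  self-coefficient on [0.3, 0.9]. Physiological signals are strongly
  autocorrelated, and without self-terms a sparse draw can be nilpotent
  (spectral radius exactly zero for every scaling), which makes a spectral
  radius target unattainable.
- The lagged block is then rescaled by a single scalar (Brent root-finding,
  tolerance 1e−3) so the companion-form spectral radius of the reduced-form
  VAR hits `target_spectral_radius` (default 0.85): comfortably stationary
  yet strongly autocorrelated.
- Noise is independent across channels with variances uniform on [0.8, 1.2].

Simulation starts from a zero state and discards a 1000-sample burn-in; the
recursion kernel is JIT-compiled (numba) with a pure-Python fallback. A
non-finite trajectory raises `InstabilityError` rather than returning garbage.

**Covariate modulation.** A cohort plants one association: a waist-girth
analogue drawn from a truncated normal (mean 95 cm, sd 15 cm, support 60–150
cm) multiplies the generative weight of one designated lagged edge (default
ECG → EEG_LO at lag 1) through a monotone logistic ramp saturating at 1.8×.
Subjects with small waists effectively lack the link; subjects with large
waists have it at close to double strength. The realized multiplier is ground
truth and is deliberately *not* written to the covariate table — analyses see
only the covariate itself, plus an independent balanced `sex` column for
stratified views. Per-subject seeds are counter-keyed `SeedSequence` children
of the cohort seed, so subject `i` is bit-identical regardless of cohort size.

**What the generator does not emulate.** Signals are linear, Gaussian, and
stationary within a recording: there are no sleep-stage regimes, movement
artifacts, oscillatory spectral peaks (spindles, alpha), heavy tails,
measurement drift, or inter-subject topology differences (only the planted
edge's strength varies). It validates the *estimators* — directed-link
recovery, calibration, and the screen/confirm protocol — not the physiology.

## Windowing and the stationarity screen

Whole-night physiological signals are nonstationary, so all model fitting
happens on 20-s windows whose starts lie on a 10-s grid (any two distinct
windows overlap exactly 50% or not at all). Candidates are drawn uniformly
without replacement from the grid until a quota (default 50) is accepted;
selection is deterministic given the seed. Each candidate is mean-centered,
its VAR order chosen by AICc over 1–19, and accepted iff the fitted VAR's
companion matrix has spectral radius < 1. Rejections are logged with a reason
(`nonstationary` or `rank-deficient`); exhausting the grid before the quota
raises an error rather than silently under-filling. Recordings at higher
rates are downsampled (polyphase anti-aliased) to the 100-Hz common rate;
upsampling is refused.

## VAR estimation and order selection

VARs are fit by ordinary least squares without intercept on centered data,
solving the normal equations by Cholesky factorization; the residual
covariance uses the maximum-likelihood divisor `n_eff = m − p`. With
`K = p·d²` coefficients,

```
AIC  = −2ℓ + 2K
AICc = AIC + 2K(K+1) / (n_eff·d − K − 1)
```

Orders whose AICc correction denominator is non-positive are inadmissible and
skipped. All candidate orders are scored on the same effective sample (rows
from `max_order` onward, shallower candidates conditioning on the extra
pre-sample values); scoring each candidate on its own `m − p` rows makes the
criterion nearly flat in `p` for small `d`, because the likelihood terms
dropped with a longer pre-sample almost cancel the parameter penalty. Ties
break toward the smaller order.

## Pairwise-conditional Granger causality

For source `y` → target `x` the statistic is `F[x,y] = ln(Σ'_xx / Σ_xx)`: the
log ratio of the target's residual variance under the reduced model (every
lag of `y` excised, all other regressors kept) to the full model, both at the
same order. The reduced fits reuse the full design's Gram matrix, so one
window costs a single factorization per excised source. Under the null the
monotone transform `(exp(F) − 1)·dof_den/dof_num` is F-distributed with
`dof_num = p` and `dof_den = n_eff − p·d`. The `d(d−1)` raw p-values per
window are adjusted by Benjamini–Yekutieli (step-up with the harmonic
correction `c(q)`), valid under arbitrary dependence; significance at
`alpha = 0.05` yields the window's binary adjacency. The correction scope is
per window by default; `by_scope = "cohort"` pools every window's hypotheses
into one BY family instead.

## DBN structure learning

Per (z-scored) window the objective over instantaneous weights `W` and lagged
weights `A` (stored `[source, target]`, acting as `X ≈ XW + YA`) is

```
(1/2n)‖X − XW − YA‖²_F + λ_W‖W‖₁ + λ_A‖A‖₁   s.t.   h(W) = tr(e^{W∘W}) − d = 0
```

Defaults `λ_W = 0.0005`, `λ_A = 0.005`. The equality constraint is handled by
an augmented Lagrangian: inner problems are solved by L-BFGS-B on a
positive/negative variable splitting (making the ℓ1 term smooth), the penalty
weight ρ starts at 1 and is multiplied by 10 whenever `h` fails to shrink to
¼ of its previous value, the multiplier is updated by `ρ·h` per round, and
the loop stops at `h ≤ 1e−8` (hard failure past `ρ = 1e16`). The diagonal of
`W` is pinned to zero by box bounds. The lag design keeps `n = m + 1 − p`
rows by zero-padding the single missing deepest-lag entry in the first row,
trading one slightly-biased row for `p − 1` extra samples on short windows.

Edges are read off by absolute thresholding at `τ`; two presets exist:
`0.01` (customary low threshold for this method family) and `0.018` (the
pipeline default, at which collapsed DBN graphs best track the Granger
graphs). `τ = 0` keeps exact nonzeros. A collapsed graph marks `y → x` if any
instantaneous or lagged link survives, oriented `[target, source]` to match
the Granger adjacency. Utilities provide AIC-based order selection and
K-fold cross-validation of `(λ_W, λ_A)` by held-out reconstruction error.

**Identifiability and standardization.** With equal innovation variances
across channels, the direction of instantaneous edges is identifiable from
the least-squares score; rescaling channels to unit variance destroys exactly
that condition, and in the recovery battery every miss was a contemporaneous
edge fitted in reverse. The validation battery therefore runs on centered
(not variance-rescaled) data, where mean edge-set F1 is ≈ 0.99. The pipeline
z-scores windows for the DBN stage — real channels have wildly different
scales, and a shared `τ` is only meaningful on comparable weights — at the
documented cost that instantaneous orientation is no longer guaranteed.

## Cohort aggregation and the association screen

Per-window binary adjacencies are summed into per-subject link counts (out of
that subject's quota), pooled into a cohort heatmap (fraction of all windows
containing the link; heatmap × total windows reproduces the summed counts
exactly) and a consensus graph at an inclusive 50% threshold. The covariate
screen computes the Spearman rank correlation between per-subject counts of
each link and each numeric covariate (missing-covariate subjects dropped per
covariate; constant vectors skipped), gating candidates at `|ρ| ≥ 0.3` and
`p < 0.05`. Candidates found on the **validation** cohort are *confirmed*
only if significant with the same sign in **every** held-out test cohort; the
confirmation step evaluates the fixed candidate list and never re-screens, so
test cohorts cannot introduce new selection.

## Problem sizes

Reference sizes are this package's own choices, set to finish on a single CPU
in minutes: a 10-channel roster at 100 Hz (90 evaluated directed links per
window), 620-s recordings (61 grid slots for a 50-window quota), 200-recording
structural counts, and an end-to-end experiment with a 6-channel roster, 60
subjects per cohort (one validation + two test), 360-s recordings, a 25-window
quota, and VAR orders capped at 4. The planted edge weight is 0.35. Over 20
seeded end-to-end runs at these sizes the planted link–covariate pair is the
top confirmed finding in 16 runs (80%); in three of the misses the planted
pair is still confirmed but an *indirect* association from the same source
channel outranks it — strengthening ECG → EEG_LO genuinely changes other
ECG-rooted paths' window frequencies, so they also track the covariate — and
in one run no candidate clears the `|ρ| ≥ 0.3` gate. At this scaled-down
power the 20-run recovery rate is therefore noticeably below a 90% bar; the
per-run outcomes are reproducible from `scripts/acceptance.py`.

## Limitations

- Linear Gaussian models throughout; nonlinear or nonstationary coupling
  within a window is out of scope.
- Granger and DBN links are statistical, not interventional, claims; the
  covariate screen is an association protocol, not a causal identification
  of the covariate's effect.
- The consensus and screen thresholds (50%, `|ρ| ≥ 0.3`, `α = 0.05`) are
  configurable conventions, not derived quantities.
- The stationarity screen tests the fitted VAR's stability, an OLS-estimated
  proxy: near-unit-root windows can pass (estimated radius just below 1), and
  the screen's power is validated only in aggregate (acceptance-rate
  monotonicity across generator radii, including a random-walk condition).
- DBN instantaneous-edge direction is identifiable only under equal noise
  variances; on z-scored pipeline data orientation of contemporaneous links
  should not be over-interpreted.
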