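# Methods

This note documents the statistical model, the estimators, the synthetic
data generators and the numerical choices behind `cagc`, in the package's
own terms.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model and estimators

Granger causality is estimated from nested ordinary-least-squares
autoregressions of each target trace on lags `1..L` of itself, of the
candidate driver, and — in the multivariate (MVGC) mode — of every other
recorded neuron and any declared stimulus series, plus an intercept.
Stimulus regressors enter the reduced and the full model symmetrically,
exactly like conditional neurons.  Each target's regression is fitted
independently (intercept included per pair); the regression window is
`t = L..T-1`, so `T_regr = T - L` samples enter every fit.

Parameter counts are `M_r = L + 1` and `M_f = 2L + 1` in the bivariate
unconditioned case and grow by `L` per conditional series.  The
F-statistic uses `(M_f - M_r, T_regr - M_f)` degrees of freedom; the GC
value is the log-ratio of degree-of-freedom-corrected residual variances
clipped at zero, and the two are related by a strictly monotone map that
the test suite verifies to 1e-10.  Significance is tested on the
F-statistic *before* the GC clipping, so a link whose corrected variance
ratio rounds to zero can still be flagged (the clip only affects the
reported effect size).

**Least-squares solver.** Designs built from lagged calcium traces are
near-collinear, and duplicated neurons (which the package must handle,
since redundant cells are a real feature of population recordings) make
them exactly rank-deficient.  The solver is SVD-based least squares
(minimum-norm solution): with rank-revealing QR the truncation decision
can differ between the nested models and produce a *negative* F beyond
floating-point error, which SVD avoids.  Residual negative F from benign
cancellation is clipped to zero below a relative 1e-12; anything larger
raises.

**Diagonal convention.** Self-causality is undefined; diagonals of all
matrices are NaN, never 0, because 0 is a meaningful GC value.

**Multiple comparisons.** The naive rule tests each pair against the
analytic F null with a Bonferroni factor `m = N(N-1)` over ordered
pairs, applied separately per analysis mode.

## Lag selection

The mean GC value over ordered pairs rises steeply with `L` up to the
true interaction extent and then plateaus before overfitting lifts it
again.  The knee is formalized as the smallest scanned lag whose forward
increment falls below a fraction `theta = 0.2` (configurable) of the
largest forward increment.  The rule is deterministic and scale
invariant; a curve that never flattens returns the largest scanned lag
with a warning.  The 20% fraction is one formalization of a visual
criterion; on the benchmark VAR network with a 3-step kernel it recovers
`L = 3` in at least 8 of 10 seeds (tested).

## Surrogate nulls and adaptive significance

Calcium traces violate the Gaussian-i.i.d. residual assumption behind
the analytic F-test: slow decay, pseudo-periodic bursting and shared
noise shift the true null of F to the right, making the naive test
permissive.  The package builds the null per ordered pair by shuffling
**only the driver trace** (target and conditionals fixed):

* **cyclic** — rotation by a random offset drawn uniformly from
  `[T/10, 9T/10]` samples (avoiding near-identity shifts), preserving
  the driver's autocorrelation while destroying alignment; default
  ensemble size m = 500;
* **epoch** — for stimulus-locked recordings, permutation of
  period-length blocks (one stimulus onset + offset per block, default
  10 s + 5 s, rounded to the nearest sample).  Because every block
  carries the same internal stimulus phase, the permutation preserves
  the stimulus-driven component and destroys only coupling beyond it;
  defaults m = 1000 (bivariate) / 100 (multivariate).

Since only the driver varies across the ensemble, the reduced model is
shared: each shuffle is evaluated by projecting the shuffled driver's
lag block onto the reduced-model residual space (Frisch–Waugh), which is
algebraically identical to refitting the full model (unit-tested to
1e-8) and makes ensembles of hundreds of shuffles cheap.

The tail of the shuffled-F distribution is what sets thresholds, and
estimating it non-parametrically would need very large ensembles, so a
two-parameter F-distribution (both degrees of freedom free, location 0,
scale 1) is ML-fitted to the ensemble.  The denominator dof has a flat
likelihood, so the optimizer is started from method-of-moments values
(the ensemble mean pins the denominator dof via `mean = b/(b-2)`, the
variance relation then gives the numerator).  On fit failure the code
falls back to the empirical quantile and flags it.  A link is
significant when its observed F exceeds the fitted `(1-p)` quantile.

**Normalized GC.**  When the shuffled ensemble is well described by a
constant rescaling of an F-distribution, applying the adaptive threshold
is equivalent to dividing F by the ensemble mean and re-applying the
analytic threshold.  `normalize_f` implements this: `F~ = F / <F_shuffled>`
per pair, GC recomputed from `F~` through the monotone map (all `F~`
computed first, clipping after), significance from the analytic null on
`F~`.  This removes the coupling between a neuron's summed outgoing GC
(its *drive*) and the signal-to-noise ratio of its trace; the acceptance
suite constructs stimulus-locked data with heterogeneous per-neuron
noise and verifies the drive–SNR Pearson correlation drops.

## Preprocessing

**Motion artifacts** are simultaneous single-timepoint excursions.  A
timepoint is flagged when the cross-neuron median of the deviation from
the two-neighbor mean exceeds `z = 6` robust (MAD-based) standard
deviations, more than half the neurons exceed it individually, and the
two neighbors agree with each other (this last condition separates a
one-sample excursion from a shared burst onset, which is a step).
Adjacent flags are collapsed to the local maximum, since a true artifact
perturbs its neighbors' scores.  Correction replaces the flagged sample
in every neuron by the mean of its neighbors (boundary samples copy the
single existing neighbor — the interior rule has no boundary analogue),
and is idempotent.

**Atypical neurons.**  Events are rises of the smoothed trace of at
least `3 sigma_n` (noise sd from the spectral floor, with a 5%-of-range
fallback).  Decay epochs are maximal runs of negative derivative; a
single exponential timescale is fitted by pooled log-linear regression
of the baseline-subtracted decay segments.  A neuron is flagged when the
fitted decay exceeds `max_decay = 10 s` or it has fewer than
`min_events = 3` onsets.  Both thresholds are configurable; the defaults
separate bursting motoneuron-like cells (decay ≈ 2.5 s, many events)
from slow non-neuronal transients and flat traces.

**Denoising.**  The trace model is an episodic signal whose derivative
has sparse (exponentially distributed, weakly correlated — treated as
independent) variations, observed under additive Gaussian white noise.
The maximum-likelihood reconstruction minimizes an L1 penalty on the
variation of the derivative plus an L2 fidelity term.  Substituting the
reconstruction `g` (the antiderivative of the derivative signal) turns
this into L1 trend filtering: `min_g 0.5||g - f||^2 + lam ||D2 g||_1`
with `D2` the second difference and
`lam = tau_f * (sigma_n^2 tau_n) / (sigma_f * dt^2)`.

* The noise spectral density `sigma_n^2 tau_n` is half the mean one-sided
  periodogram over the **top quartile** of frequencies ("high frequencies" needs a
  concrete convention; the quartile rule is this package's).
* `sigma_f` is the trace standard deviation.
* `tau_f`, the variation timescale, is scanned over 10 log-spaced values
  between `dt` and a quarter of the record length; the selected value
  minimizes the RMS difference between the residual's cumulative
  periodogram and the extrapolated white-noise line.
* The solver is ADMM with the pentadiagonal system factored by banded
  Cholesky, warm-started across the `tau_f` grid, with Boyd-style
  residual balancing of the penalty parameter every 25 iterations;
  relative tolerance 1e-4, at most 4000 iterations, non-convergence
  raises with diagnostics.  Traces with no detectable noise floor are
  returned unchanged.
* Smoothing is applied per neuron independently; joint multi-neuron
  smoothing under a shared-noise model is a known extension and out of
  scope.

A property of this estimator worth stating plainly: the residual
`g - f` is a *shrinkage* of the noise, not the noise itself.  Its power
matches the injected noise power (tested to 20%) and its spectrum is
approximately flat, but it retains small systematic autocorrelation
(|acf| ≲ 0.1) at every regularization level, so it does not pass a
strict portmanteau whiteness test at realistic record lengths.  The
tests assert the achievable properties (power recovery, bounded
autocorrelation, spectral flatness).

**SNR.**  Noise power is the spectral floor extrapolated over the full
band; signal power is total variance minus noise power (clipped at 0);
SNR is their ratio.  This is accurate for band-limited signals and
biased low for signals with genuine high-frequency content (sharp
onsets leak into the floor estimate).

## Synthetic generators — what they emulate

**Benchmark network.**  A fixed 10-neuron topology with 5 excitatory and
5 inhibitory cells (sign carried by the source neuron), 16 directed
links, no self-loops: a bipartite E→I→E loop through all ten cells plus
cross-links that create *parallel two-step indirect paths* — the motif
that makes pairwise GC report spurious links while conditioned GC does
not.  The kernel is a 2-step boxcar, `Gamma_ij,q = A_ij s_j c`.  The fixture
is version-pinned and is the single source of truth for all
link-recovery benchmarks in the package.  It is VAR-stationary at the benchmark strength c = 0.1265
(companion spectral radius 0.50) and dynamically stable under the GLM at
c = 0.9.  Pure excitatory chains are not usable here: under the GLM at
strong coupling they amplify rates multiplicatively and diverge, which
is why the topology alternates E and I along every path.

**Dynamics.**  (i) VAR with unit-variance Gaussian innovations;
(ii) Poisson GLM, `lambda_{i,t} = exp(mu + sum Gamma sigma_{j,t-q})`,
with base rate `exp(mu) = 0.25` spikes/step — the sparse-firing regime
typical of imaging-rate binning, and the regime in which strong
inhibition modulates rather than silences its targets; (iii) GLM-calcium,
the spike counts convolved with `exp(-q*dt/tau_ca)` (the exponent in
time units over `tau_ca`; written dimensionally consistently).  Burn-in
of `10*Ltrue` samples is discarded; VAR simulation refuses non-stationary
kernels; the GLM guards against rate overflow.  All generators are
bit-reproducible under a seed.

**Global noise.**  One shared Gaussian white series added to every
neuron — the system-wide measurement noise (laser fluctuation, motion)
that is the dominant source of spurious GC links in imaging data.

**Two-chain motoneuron generator.**  Two chains of 5 neurons gated by
binary block stimuli; on/off durations uniform on (1, 10) s, the
right-side block trailing the left block's offset by a delay uniform on
(0.25, 1) s; neuron of rank k sees its side's stimulus delayed by
`k * tau_info`; Poisson spikes at `lambda_0 = 32/s` while gated
(`lambda_0 * delta_sim = 0.4 < 1` keeps per-step stochasticity);
exponential calcium convolution at `tau_ca` (default 2.5 s, the
empirical indicator timescale); downsampling by decimation (every
`round(tau_sampling/delta_sim)`-th sample, no anti-alias filter — this
mimics imaging acquisition) to `tau_sampling = 0.25 s`.  Simulation step
`delta_sim = 12.5 ms`; default duration 1000 s.  Chain neurons couple
only through the shared delayed stimulus; the ground truth used for
scoring is the expected ipsilateral rostral-to-caudal flow.

What this generator does **not** emulate: indicator saturation and
nonlinearity, bleaching drifts, spatially structured noise, neuron-to-
neuron synapses within a chain.  Passing tests on it therefore show the
pipeline recovers stimulus-chain information flow at realistic
timescales, not that it handles every artifact of real recordings.

One property of the defaults deserves emphasis: the right stimulus is
*constructed from* the left one with a 0.25–1 s delay, which overlaps a
one-sample regression window at 4 Hz.  A small contralateral information
flow is therefore genuinely present in the generative model, and the
conditioned analysis correctly finds a little of it: the ipsilateral
ratio converges to ≈ 0.98–1.00, not identically 1, at
`tau_info = tau_sampling`.  The timescale-robustness tests accordingly
require WIC within 0.02 of 1 (matching the reproduction tolerance used
for the directional ratios elsewhere in the suite) rather than exact
unity.  At `tau_info = 0.025 s` — forty times faster than sampling — the
recovered network is exactly ipsilateral in every tested seed.

## Problem sizes

The validation suite runs entirely on synthetic data at the following
sizes, chosen to give each statistical assertion adequate power while
keeping a full run on one core in minutes: benchmark recovery at
T = 5000 with 10 realizations per dynamics; lag scans at T = 4000;
null-test calibration over 1000 independent pairs with 500 shuffles
each; chain simulations of 1000 s (4000 frames) with 100 shuffles per
pair; smoothing benchmarks at T = 3000 with shared noise at half the
signal scale.  The acceptance script uses the same sizes.

## Known limitations

* MVGC with many neurons and lags overfits; the overfitting guard
  rejects `T_regr <= M_f`, but well before that point estimates get
  noisy.  Tens of neurons at a few lags is the intended regime.
* Exactly duplicated activity splits predictive credit: MVGC
  underestimates links out of duplicated sources (tested); pairwise GC
  still sees them.
* The adaptive threshold calibrates the per-pair type-I error, not a
  network-level error rate; with 90 pairs at p = 0.05, a few false
  links per recording are expected unless p is tightened.
* Frequency-domain (spectral) GC, state-space GC and sparsity-
  regularized variants are out of scope.
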