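"""Data-driven significance for GC links via driver-trace shuffles.

The analytic F-test null is exact only for Gaussian i.i.d. residuals.
Calcium traces are autocorrelated, pseudo-periodic and share correlated
noise, which shifts the true null of the F-statistic to the right and
makes the naive test permissive.  The remedy implemented here:

1. destroy the temporal alignment between driver and target while keeping
   each trace's autocorrelation — by cyclic rotation of the driver
   (spontaneous activity) or by permuting stimulus-locked epochs
   (stimulus-driven activity);
2. recompute the pair's F-statistic over ``m`` such shuffles;
3. fit a two-parameter F-distribution to the shuffled ensemble by maximum
   likelihood and threshold the observed F at its (1-p) quantile
   (adaptive threshold), or
4. divide the observed F by the ensemble mean (normalized F-statistic)
   and re-apply the analytic threshold — equivalent when the shuffled
   ensemble is a constant-rescaled F-distribution.

Only the driver trace is ever shuffled; the target and all conditional
series stay fixed, so the reduced model (and its residual) is shared
across the whole ensemble.  Each shuffle therefore only requires
projecting the shuffled driver's lag block out of the reduced-model
residual space, which makes ensembles of hundreds of shuffles cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .gc import GCResult, gc_from_f, lag_matrix
from .recording import FluorescenceRecording

__all__ = [
    "NullEnsemble",
    "cyclic_shuffle",
    "epoch_shuffle",
    "stimulus_epochs",
    "null_f_ensemble",
    "build_null_ensembles",
    "fit_null_f",
    "adaptive_significance",
    "normalize_f",
]


def cyclic_shuffle(y: np.ndarray, delta: int) -> np.ndarray:
    """Rotate a series by ``delta`` samples: out(t) = y(t - delta), with the
    tail wrapped to the front.  Preserves the value multiset and the
    autocorrelation (up to the wrap point) while destroying alignment."""
    y = np.asarray(y)
    T = y.shape[-1]
    if not (0 <= delta < T):
        raise ValueError(f"delta={delta} out of range [0, {T})")
    return np.roll(y, delta, axis=-1)


def epoch_shuffle(
    y: np.ndarray,
    epochs: Sequence[tuple[int, int]],
    seed: Optional[int | np.random.Generator] = None,
) -> np.ndarray:
    """Permute the order of epoch blocks of a series.

    ``epochs`` are half-open [start, end) sample intervals that must tile
    [0, T) without overlap; block interiors are untouched.
    """
    y = np.asarray(y)
    T = y.shape[-1]
    epochs = sorted((int(a), int(b)) for a, b in epochs)
    covered = 0
    for a, b in epochs:
        if a != covered or b <= a:
            raise ValueError(f"epochs must tile [0, {T}) without overlap; got {epochs}")
        covered = b
    if covered != T:
        raise ValueError(f"epochs cover [0, {covered}) but the series has length {T}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(epochs))
    return np.concatenate([y[..., epochs[k][0] : epochs[k][1]] for k in order], axis=-1)


def stimulus_epochs(
    T: int, dt: float, on_duration: float = 10.0, off_duration: float = 5.0
) -> list[tuple[int, int]]:
    """Tile [0, T) with stimulus epochs of one on+off period each.

    Each epoch spans one consecutive stimulus onset (``on_duration``
    seconds) plus offset (``off_duration`` seconds), rounded to the
    nearest sample; the final epoch is truncated at T.  Permuting such
    period-length blocks preserves the stimulus-locked component of a
    trace while destroying any coupling beyond it, which is exactly the
    null wanted for stimulus-driven recordings.
    """
    period = on_duration + off_duration
    edges = [0]
    k = 1
    while True:
        idx = int(round(k * period / dt))
        k += 1
        if idx >= T:
            edges.append(T)
            break
        edges.append(idx)
    return [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]


@dataclass(frozen=True)
class NullEnsemble:
    """Shuffled-driver F-statistic ensemble for one ordered pair.

    ``pair`` is (driver j, target i).  ``fitted_alpha``/``fitted_beta``
    are the ML degrees of freedom of the F-distribution fitted to
    ``f_samples`` (NaN until :func:`fit_null_f` runs); ``threshold`` is
    the (1-p) quantile of the fitted null.
    """

    pair: tuple[int, int]
    f_samples: np.ndarray
    shuffle_kind: str
    shifts: np.ndarray
    seed: Optional[int]
    fitted_alpha: float = float("nan")
    fitted_beta: float = float("nan")
    threshold: float = float("nan")
    p: float = float("nan")
    fit_converged: bool = False

    @property
    def mean_f(self) -> float:
        """Ensemble mean of the shuffled F-statistics."""
        return float(np.mean(self.f_samples))

    @property
    def n_samples(self) -> int:
        return int(self.f_samples.size)


def _shuffled_f_samples(
    target: np.ndarray,
    driver: np.ndarray,
    conditionals: Sequence[np.ndarray],
    L: int,
    m: int,
    shuffle_kind: str,
    rng: np.random.Generator,
    epochs: Optional[Sequence[tuple[int, int]]],
) -> tuple[np.ndarray, np.ndarray]:
    """F-statistics of ``m`` driver shuffles via residual projection.

    The reduced model (target + conditional lags) is fitted once; each
    shuffle residualizes the shuffled driver's lag block against it and
    measures the residual variance it removes — algebraically identical to
    refitting the full model from scratch.
    """
    T = target.shape[0]
    cols = [np.ones(T - L), lag_matrix(target, L)]
    cols += [lag_matrix(np.asarray(c, dtype=float), L) for c in conditionals]
    Xr = np.column_stack(cols)
    T_regr, Mr = Xr.shape
    Mf = Mr + L
    if T_regr <= Mf:
        raise ValueError(f"overfitting guard: T_regr={T_regr} <= Mf={Mf}")
    Q, _ = np.linalg.qr(Xr)
    y = target[L:]
    e_y = y - Q @ (Q.T @ y)
    rss_r = float(e_y @ e_y)
    dfd = T_regr - Mf

    if shuffle_kind == "cyclic":
        lo, hi = max(1, T // 10), max(2, (9 * T) // 10)
        shifts = rng.integers(lo, hi, size=m)
    elif shuffle_kind == "epoch":
        if epochs is None:
            raise ValueError("epoch shuffling requires stimulus epochs")
        shifts = np.array([rng.permutation(len(epochs)) for _ in range(m)])
    else:
        raise ValueError(f"unknown shuffle kind {shuffle_kind!r}")

    samples = np.empty(m)
    for k in range(m):
        if shuffle_kind == "cyclic":
            d = cyclic_shuffle(driver, int(shifts[k]))
        else:
            d = np.concatenate([driver[epochs[e][0] : epochs[e][1]] for e in shifts[k]])
        D = lag_matrix(d, L)
        E = D - Q @ (Q.T @ D)
        beta, _, _, _ = np.linalg.lstsq(E, e_y, rcond=None)
        r = e_y - E @ beta
        rss_f = float(r @ r)
        num = max(rss_r - rss_f, 0.0)
        samples[k] = (num / L) / (rss_f / dfd)
    return samples, shifts


def null_f_ensemble(
    rec: FluorescenceRecording,
    pair: tuple[int, int],
    L: int,
    mode: str = "mvgc",
    m: int = 500,
    shuffle_kind: str = "cyclic",
    seed: Optional[int] = None,
    epochs: Optional[Sequence[tuple[int, int]]] = None,
    stimuli: Sequence[np.ndarray] = (),
) -> NullEnsemble:
    """Shuffled-driver null ensemble for the ordered pair (driver, target).

    Only the driver trace is shuffled; in MVGC mode the conditionals are
    every remaining neuron (plus any stimulus series) and stay fixed.
    Deterministic given ``seed``.
    """
    if m < 20:
        raise ValueError("need at least 20 shuffles for a usable null")
    j, i = pair
    if j == i:
        raise ValueError("driver and target must differ")
    rng = np.random.default_rng(seed)
    sig = rec.signal
    if mode == "bvgc":
        conds = list(stimuli)
    elif mode == "mvgc":
        conds = [sig[k] for k in range(rec.n_neurons) if k not in (i, j)] + list(stimuli)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    samples, shifts = _shuffled_f_samples(
        sig[i], sig[j], conds, L, m, shuffle_kind, rng, epochs
    )
    return NullEnsemble(
        pair=(j, i),
        f_samples=samples,
        shuffle_kind=shuffle_kind,
        shifts=shifts,
        seed=seed,
    )


def build_null_ensembles(
    rec: FluorescenceRecording,
    L: int,
    mode: str = "mvgc",
    m: int = 500,
    shuffle_kind: str = "cyclic",
    seed: Optional[int] = None,
    p: float = 0.05,
    epochs: Optional[Sequence[tuple[int, int]]] = None,
    stimuli: Sequence[np.ndarray] = (),
    fit: bool = True,
) -> dict[tuple[int, int], NullEnsemble]:
    """Null ensembles (optionally ML-fitted) for every ordered pair.

    Per-pair seeds are derived deterministically from ``seed``.
    """
    n = rec.n_neurons
    root = np.random.default_rng(seed)
    out: dict[tuple[int, int], NullEnsemble] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            sub = int(root.integers(0, 2**31 - 1))
            ens = null_f_ensemble(
                rec, (j, i), L, mode=mode, m=m, shuffle_kind=shuffle_kind,
                seed=sub, epochs=epochs, stimuli=stimuli,
            )
            out[(j, i)] = fit_null_f(ens, p=p) if fit else ens
    return out


def fit_null_f(ensemble: NullEnsemble, p: float = 0.05) -> NullEnsemble:
    """ML fit of a two-parameter F-distribution to the shuffled ensemble.

    Both degrees of freedom are free; location and scale are pinned at
    0 and 1.  On non-convergence the empirical (1-p) quantile is used and
    flagged via ``fit_converged=False``.
    """
    samples = ensemble.f_samples[np.isfinite(ensemble.f_samples)]
    samples = samples[samples > 0]
    if samples.size < 20:
        raise ValueError("need >= 20 finite positive samples to fit the null")
    # method-of-moments starting values: mean = b/(b-2) pins the
    # denominator dof, the variance relation then gives the numerator
    m = float(np.mean(samples))
    v = float(np.var(samples))
    beta0 = 2.0 * m / (m - 1.0) if m > 1.02 else 50.0
    beta0 = float(np.clip(beta0, 4.5, 1e4))
    k = v * (beta0 - 2.0) ** 2 * (beta0 - 4.0) / (2.0 * beta0**2)
    alpha0 = (beta0 - 2.0) / (k - 1.0) if k > 1.001 else 2.0
    alpha0 = float(np.clip(alpha0, 0.2, 1e3))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alpha, beta, _, _ = stats.f.fit(samples, alpha0, beta0, floc=0, fscale=1)
        if not (np.isfinite(alpha) and np.isfinite(beta) and alpha > 0 and beta > 0):
            raise RuntimeError("degenerate fit")
        threshold = float(stats.f.ppf(1.0 - p, alpha, beta))
        if not np.isfinite(threshold):
            raise RuntimeError("non-finite threshold")
        return replace(
            ensemble, fitted_alpha=float(alpha), fitted_beta=float(beta),
            threshold=threshold, p=p, fit_converged=True,
        )
    except (RuntimeError, ValueError, FloatingPointError):
        threshold = float(np.quantile(samples, 1.0 - p))
        return replace(
            ensemble, fitted_alpha=float("nan"), fitted_beta=float("nan"),
            threshold=threshold, p=p, fit_converged=False,
        )


def adaptive_significance(
    result: GCResult,
    nulls: dict[tuple[int, int], NullEnsemble],
    p: float = 0.05,
) -> GCResult:
    """Adaptive per-pair thresholding of a GC result.

    A link j -> i is significant iff its F-statistic exceeds the (1-p)
    quantile of that pair's fitted shuffled-driver null.  Nulls not yet
    fitted (or fitted at a different level) are (re)fitted here.
    """
    n = result.n_neurons
    significant = np.zeros((n, n), dtype=bool)
    thresholds = np.full((n, n), np.nan)
    fallback = 0
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(result.F[i, j]):
                continue
            if (j, i) not in nulls:
                raise KeyError(f"missing null ensemble for pair {j}->{i}")
            ens = nulls[(j, i)]
            if not np.isfinite(ens.threshold) or ens.p != p:
                ens = fit_null_f(ens, p=p)
            fallback += not ens.fit_converged
            thresholds[i, j] = ens.threshold
            significant[i, j] = result.F[i, j] > ens.threshold
    kind = next(iter(nulls.values())).shuffle_kind
    info = f"adaptive {kind}-shuffle threshold, p={p}"
    if fallback:
        info += f" ({fallback} pairs on empirical-quantile fallback)"
    return replace(result, significant=significant, thresholds=thresholds, threshold_info=info)


def normalize_f(
    result: GCResult,
    nulls: dict[tuple[int, int], NullEnsemble],
    p: float = 0.05,
    bonferroni: bool = True,
) -> GCResult:
    """Normalize F-statistics by the shuffled-ensemble mean.

    F~(j->i) = F(j->i) / <F_shuffled(j->i)>; GC values are recomputed from
    F~ through the monotone F-to-GC map, and significance is the original
    analytic threshold applied to F~.  This removes the per-pair
    signal-to-noise bias that otherwise couples a neuron's drive to its
    recording quality.
    """
    n = result.n_neurons
    F_norm = np.full((n, n), np.nan)
    gc_norm = np.full((n, n), np.nan)
    pvals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(result.F[i, j]):
                continue
            if (j, i) not in nulls:
                raise KeyError(f"missing null ensemble for pair {j}->{i}")
            mean_f = nulls[(j, i)].mean_f
            if not (mean_f > 0):
                raise ZeroDivisionError(f"null ensemble mean is zero for pair {j}->{i}")
            F_norm[i, j] = result.F[i, j] / mean_f
    for i in range(n):
        for j in range(n):
            if np.isfinite(F_norm[i, j]):
                gc_norm[i, j] = gc_from_f(F_norm[i, j], result.Mf, result.Mr, result.T_regr)
                pvals[i, j] = stats.f.sf(F_norm[i, j], result.Mf - result.Mr, result.T_regr - result.Mf)
    m = int(np.sum(np.isfinite(pvals)))
    thresh = p / m if (bonferroni and m > 0) else p
    with np.errstate(invalid="ignore"):
        significant = pvals < thresh
    kind = next(iter(nulls.values())).shuffle_kind
    info = f"normalized F ({kind}-shuffle mean), analytic threshold p={p}" + (
        f", Bonferroni m={m}" if bonferroni else ""
    )
    return replace(
        result, F=F_norm, gc=gc_norm, pvalues=pvals, significant=significant,
        threshold_info=info, thresholds=None,
    )
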