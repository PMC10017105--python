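"""Nested autoregressions, F-statistics and Granger-causality matrices.

Granger causality (GC) asks whether the past of a driver series Y improves
the linear prediction of a target series X beyond X's own past (bivariate
GC, BVGC) or beyond the past of every other recorded series (multivariate,
conditioned GC, MVGC).  The machinery is a pair of nested ordinary-least-
squares autoregressions:

* reduced model:  x_t = a0 + sum_q a_q x_{t-q} (+ conditional lags) + e_t
* full model:     reduced + sum_q b_q y_{t-q}

with maximum lag ``L``.  The residual comparison yields an F-statistic
with (Mf - Mr, Tregr - Mf) degrees of freedom, where Mr/Mf count the
parameters of the two models and Tregr = T - L is the number of regression
samples.  The GC value is the log-ratio of degree-of-freedom-corrected
residual variances, clipped at zero; it is a monotone transform of F.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .recording import FluorescenceRecording

__all__ = [
    "RegressionFit",
    "GCResult",
    "fit_ar",
    "f_statistic",
    "gc_value",
    "gc_from_f",
    "f_pvalue",
    "bvgc",
    "mvgc",
    "naive_significance",
]

#: negative F-statistics smaller than this (in magnitude) are attributed to
#: floating-point cancellation and clipped to zero; anything larger raises.
_NEG_F_TOL = 1e-12


@dataclass(frozen=True)
class RegressionFit:
    """One OLS autoregression (reduced or full model).

    ``coefficients`` is ordered [intercept, target lags 1..L, then each
    driver's lags 1..L, then each conditional's lags 1..L].
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    L: int
    n_params: int
    T_regr: int

    @property
    def rss(self) -> float:
        """Residual sum of squares over the regression samples."""
        return float(self.residuals @ self.residuals)

    @property
    def sigma2(self) -> float:
        """Degree-of-freedom-corrected residual variance."""
        dof = self.T_regr - self.n_params
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        return self.rss / dof


def lag_matrix(series: np.ndarray, L: int) -> np.ndarray:
    """Stack lags 1..L of ``series`` into a (T - L, L) design block.

    Row t corresponds to prediction target ``series[L + t]``; column q - 1
    holds ``series[L + t - q]``.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[0]
    if not (0 < L < T):
        raise ValueError(f"lag L={L} out of range for series of length {T}")
    return np.column_stack([series[L - q : T - q] for q in range(1, L + 1)])


def _design(
    target: np.ndarray,
    drivers: Sequence[np.ndarray],
    conditionals: Sequence[np.ndarray],
    L: int,
) -> tuple[np.ndarray, np.ndarray]:
    target = np.asarray(target, dtype=float)
    T = target.shape[0]
    for s in list(drivers) + list(conditionals):
        if np.asarray(s).shape[0] != T:
            raise ValueError("all series must have equal length")
    cols = [np.ones(T - L), lag_matrix(target, L)]
    cols += [lag_matrix(np.asarray(s, dtype=float), L) for s in drivers]
    cols += [lag_matrix(np.asarray(s, dtype=float), L) for s in conditionals]
    X = np.column_stack(cols)
    y = target[L:]
    return X, y


def fit_ar(
    target: np.ndarray,
    drivers: Sequence[np.ndarray] = (),
    conditionals: Sequence[np.ndarray] = (),
    L: int = 1,
) -> RegressionFit:
    """OLS fit of ``target[t]`` on lags 1..L of itself, each driver and each
    conditional series, plus an intercept.

    Residuals are returned for t = L..T-1 (0-based), i.e. the regression
    window t = L+1..T in 1-based notation.  Uses an orthogonal-
    factorization least-squares solver (SVD) rather than normal
    equations: lagged calcium traces are near-collinear, and duplicated
    neurons make the design exactly rank-deficient.
    """
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise ValueError("non-finite values in target series")
    for s in list(drivers) + list(conditionals):
        if not np.all(np.isfinite(np.asarray(s, dtype=float))):
            raise ValueError("non-finite values in regressor series")
    X, y = _design(target, drivers, conditionals, L)
    T_regr, n_params = X.shape
    if T_regr <= n_params:
        raise ValueError(
            f"underdetermined regression: T_regr={T_regr} <= {n_params} parameters"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ beta
    return RegressionFit(
        coefficients=beta, residuals=residuals, L=L, n_params=n_params, T_regr=T_regr
    )


def _check_nested(reduced: RegressionFit, full: RegressionFit) -> None:
    if reduced.T_regr != full.T_regr:
        raise ValueError(
            f"mismatched regression windows: {reduced.T_regr} vs {full.T_regr}"
        )
    if full.n_params <= reduced.n_params:
        raise ValueError("full model must have more parameters than the reduced model")
    if full.T_regr <= full.n_params:
        raise ValueError("full model has no residual degrees of freedom")


def f_statistic(reduced: RegressionFit, full: RegressionFit) -> float:
    """F-test statistic comparing nested reduced/full residuals.

    F = [(RSS_r - RSS_f)/(Mf - Mr)] / [RSS_f/(Tregr - Mf)].  Tiny negative
    numerators from floating-point cancellation are clipped to zero.
    """
    _check_nested(reduced, full)
    rss_r, rss_f = reduced.rss, full.rss
    dfn = full.n_params - reduced.n_params
    dfd = full.T_regr - full.n_params
    if rss_f <= 0:
        raise ZeroDivisionError("full-model residual sum of squares is zero")
    num = rss_r - rss_f
    scale = max(rss_r, rss_f)
    if num < 0:
        if -num > _NEG_F_TOL * scale:
            raise FloatingPointError(
                f"reduced RSS smaller than full RSS beyond tolerance ({num:g})"
            )
        num = 0.0
    return (num / dfn) / (rss_f / dfd)


def gc_value(reduced: RegressionFit, full: RegressionFit) -> float:
    """GC value: max(ln of the ratio of dof-corrected residual variances, 0)."""
    _check_nested(reduced, full)
    if full.rss <= 0:
        raise ZeroDivisionError("degenerate fit: full-model residual variance is zero")
    return max(float(np.log(reduced.sigma2 / full.sigma2)), 0.0)


def gc_from_f(F: float, Mf: int, Mr: int, T_regr: int) -> float:
    """Monotone map from the F-statistic to the GC value.

    GC = max( ln[ ((Mf-Mr)/(Tregr-Mf) F + 1) (Tregr-Mf)/(Tregr-Mr) ], 0 ).
    """
    if not (T_regr > Mf > Mr > 0):
        raise ValueError(f"invalid parameter counts: Tregr={T_regr}, Mf={Mf}, Mr={Mr}")
    if F < 0:
        raise ValueError(f"F must be non-negative, got {F}")
    dfn = Mf - Mr
    dfd = T_regr - Mf
    ratio = (dfn / dfd * F + 1.0) * dfd / (T_regr - Mr)
    return max(float(np.log(ratio)), 0.0)


def f_pvalue(F: float, Mf: int, Mr: int, T_regr: int) -> float:
    """Right-tail p-value of F under the analytic F(Mf-Mr, Tregr-Mf) null."""
    return float(stats.f.sf(F, Mf - Mr, T_regr - Mf))


# ---------------------------------------------------------------------------
# Pairwise GC matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GCResult:
    """Pairwise Granger-causality result for one recording and mode.

    Matrices are indexed ``[driver j, target i]`` is **not** the
    convention here: entry ``[i, j]`` of every matrix refers to the ordered
    link *j -> i* stored as ``F[i, j]``, i.e. rows are targets and columns
    are drivers.  Diagonals are NaN (self-causality is undefined).
    """

    F: np.ndarray
    gc: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    L: int
    mode: str
    Mf: int
    Mr: int
    T_regr: int
    threshold_info: str = "none"
    labels: Optional[tuple[str, ...]] = None
    thresholds: Optional[np.ndarray] = None  # per-pair F thresholds (adaptive)

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def gc_sig(self) -> np.ndarray:
        """Significant-only GC matrix: GC where significant, 0 elsewhere, NaN diagonal."""
        out = np.where(self.significant, self.gc, 0.0)
        np.fill_diagonal(out, np.nan)
        return out

    def link(self, driver: int, target: int) -> dict:
        """All statistics of the ordered link driver -> target."""
        return {
            "driver": driver,
            "target": target,
            "F": float(self.F[target, driver]),
            "gc": float(self.gc[target, driver]),
            "pvalue": float(self.pvalues[target, driver]),
            "significant": bool(self.significant[target, driver]),
        }

    def to_edge_dataframe(self):
        """Long-format table of all ordered pairs (driver, target, F, gc, ...)."""
        import pandas as pd

        n = self.n_neurons
        labels = self.labels or tuple(str(i) for i in range(n))
        rows = []
        for i in range(n):  # target
            for j in range(n):  # driver
                if i == j:
                    continue
                rows.append(
                    {
                        "driver": labels[j],
                        "target": labels[i],
                        "F": self.F[i, j],
                        "gc": self.gc[i, j],
                        "pvalue": self.pvalues[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table."""
        n = self.n_neurons
        n_pairs = n * (n - 1)
        n_sig = int(np.nansum(self.significant))
        with np.errstate(invalid="ignore"):
            mean_gc = float(np.nanmean(self.gc))
            mean_gc_sig = float(np.nanmean(self.gc_sig))
        lines = [
            "Granger causality results",
            "=" * 41,
            f"mode:                 {self.mode}",
            f"neurons:              {n}",
            f"maximum lag L:        {self.L}",
            f"regression samples:   {self.T_regr}",
            f"params (full/red.):   {self.Mf}/{self.Mr}",
            f"significance rule:    {self.threshold_info}",
            f"significant links:    {n_sig}/{n_pairs}",
            f"mean GC value:        {mean_gc:.6g}",
            f"mean significant GC:  {mean_gc_sig:.6g}",
            "=" * 41,
        ]
        return "\n".join(lines)


def _gc_matrices(
    rec: FluorescenceRecording,
    L: int,
    mode: str,
    stimuli: Sequence[np.ndarray] = (),
) -> GCResult:
    """Shared implementation behind :func:`bvgc` and :func:`mvgc`.

    For MVGC the full model of a fixed target is identical across drivers
    (it contains every neuron's lags), so it is fitted once per target and
    reused for all N-1 reduced comparisons.
    """
    sig = rec.signal
    n, T = sig.shape
    if mode == "mvgc" and n < 3:
        raise ValueError("multivariate GC needs at least 3 neurons")
    stimuli = [np.asarray(s, dtype=float) for s in stimuli]

    F = np.full((n, n), np.nan)
    gc = np.full((n, n), np.nan)
    pvals = np.full((n, n), np.nan)

    if mode == "bvgc":
        Mr = L + 1 + L * len(stimuli)
        Mf = Mr + L
    else:
        Mr = 1 + L * (n - 1) + L * len(stimuli)
        Mf = Mr + L
    T_regr = T - L
    if T_regr <= Mf:
        raise ValueError(
            f"overfitting guard: T_regr={T_regr} <= Mf={Mf} ({mode}, L={L}, N={n})"
        )

    for i in range(n):  # target
        target = sig[i]
        if mode == "bvgc":
            reduced = fit_ar(target, conditionals=stimuli, L=L)
            for j in range(n):
                if j == i:
                    continue
                try:
                    full = fit_ar(target, drivers=[sig[j]], conditionals=stimuli, L=L)
                    F[i, j] = f_statistic(reduced, full)
                    gc[i, j] = gc_value(reduced, full)
                except (ValueError, ZeroDivisionError, FloatingPointError) as err:
                    raise type(err)(f"pair {j}->{i}: {err}") from err
        else:
            others = [sig[k] for k in range(n) if k != i]
            full_all = fit_ar(target, drivers=others, conditionals=stimuli, L=L)
            for j in range(n):
                if j == i:
                    continue
                conds = [sig[k] for k in range(n) if k not in (i, j)]
                try:
                    reduced = fit_ar(target, conditionals=conds + stimuli, L=L)
                    F[i, j] = f_statistic(reduced, full_all)
                    gc[i, j] = gc_value(reduced, full_all)
                except (ValueError, ZeroDivisionError, FloatingPointError) as err:
                    raise type(err)(f"pair {j}->{i}: {err}") from err
        mask = np.arange(n) != i
        pvals[i, mask] = stats.f.sf(F[i, mask], Mf - Mr, T_regr - Mf)

    result = GCResult(
        F=F,
        gc=gc,
        pvalues=pvals,
        significant=np.zeros((n, n), dtype=bool),
        L=L,
        mode=mode,
        Mf=Mf,
        Mr=Mr,
        T_regr=T_regr,
        labels=tuple(rec.labels),
    )
    return naive_significance(result, p=0.05, bonferroni=True)


def bvgc(
    rec: FluorescenceRecording, L: int, stimuli: Sequence[np.ndarray] = ()
) -> GCResult:
    """Bivariate (pairwise, unconditioned) GC over all ordered neuron pairs.

    Significance defaults to the analytic F-test with a Bonferroni
    correction over the N(N-1) ordered pairs at p=0.05; re-threshold with
    :func:`naive_significance` or the adaptive machinery in
    :mod:`cagc.nulls`.
    """
    return _gc_matrices(rec, L, "bvgc", stimuli)


def mvgc(
    rec: FluorescenceRecording, L: int, stimuli: Sequence[np.ndarray] = ()
) -> GCResult:
    """Multivariate GC: each pair conditioned on all remaining neurons.

    External stimulus series, when given, enter both the reduced and full
    models exactly like conditional neurons.
    """
    return _gc_matrices(rec, L, "mvgc", stimuli)


def naive_significance(result: GCResult, p: float = 0.05, bonferroni: bool = True) -> GCResult:
    """Analytic F-test thresholding of a GC matrix.

    Marks link j->i significant when its p-value is below ``p / m`` with
    ``m`` the number of tested ordered pairs (if ``bonferroni``), else
    below ``p``.
    """
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0, 1), got {p}")
    m = int(np.sum(np.isfinite(result.pvalues)))
    thresh = p / m if (bonferroni and m > 0) else p
    with np.errstate(invalid="ignore"):
        significant = result.pvalues < thresh
    info = f"analytic F-test, p={p}" + (f", Bonferroni m={m}" if bonferroni else "")
    return replace(result, significant=significant, threshold_info=info, thresholds=None)
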