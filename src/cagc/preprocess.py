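"""Calcium-specific cleaning of fluorescence recordings.

Four concerns, in the order the pipeline applies them:

* atypical-neuron flagging — cells whose transients decay over tens of
  seconds (non-neuronal) or that never oscillate are removed before any
  multivariate analysis, where one bad trace contaminates every pair;
* motion artifacts — a simultaneous single-timepoint fluorescence jump in
  (almost) all neurons, corrected by neighbor interpolation;
* denoising — total-variation regularization of the *derivative* of each
  trace: the derivative's temporal variations are taken exponentially
  distributed (sparse), the measurement noise Gaussian and white, so the
  maximum-likelihood reconstruction minimizes an L1 penalty on the second
  difference of the trace plus an L2 fidelity term.  Unlike a low-pass
  filter this keeps the fast calcium onsets sharp while removing
  (correlated) noise;
* noise floor and SNR — the white-noise power is read off the
  high-frequency end of the periodogram and extrapolated across the band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg as sp_linalg
from scipy import signal as sp_signal
from scipy import sparse

from .recording import FluorescenceRecording

__all__ = [
    "ArtifactReport",
    "SmoothingResult",
    "detect_motion_artifacts",
    "correct_motion_artifact",
    "correct_motion_artifacts",
    "flag_atypical_neurons",
    "tv_smooth",
    "smooth_recording",
    "noise_floor",
    "snr",
]


# ---------------------------------------------------------------------------
# Motion artifacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactReport:
    """Global single-timepoint artifacts found in a recording."""

    artifact_times: np.ndarray  # sample indices
    deviations: np.ndarray      # cross-neuron median |deviation| (DF/F units)
    neurons_affected: np.ndarray  # per artifact, number of neurons over threshold

    @property
    def n_artifacts(self) -> int:
        return int(self.artifact_times.size)


def _neighbor_deviation(sig: np.ndarray) -> np.ndarray:
    """Per-neuron deviation of each interior timepoint from the mean of its
    two neighbors; zero-padded at the edges."""
    d = np.zeros_like(sig)
    d[:, 1:-1] = sig[:, 1:-1] - 0.5 * (sig[:, :-2] + sig[:, 2:])
    return d


def detect_motion_artifacts(
    rec: FluorescenceRecording, z_threshold: float = 6.0, majority: float = 0.5
) -> ArtifactReport:
    """Flag timepoints where most neurons deviate simultaneously.

    A timepoint is an artifact when the cross-neuron median of the
    one-step deviation from the local two-neighbor mean exceeds
    ``z_threshold`` robust standard deviations *and* more than
    ``majority`` of the neurons are individually above threshold.
    Single-neuron transients never qualify, and neither do shared burst
    onsets: an artifact is a single-timepoint excursion, so the two
    neighbors must agree with each other (the trace returns to its local
    level), unlike a step.
    """
    if rec.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    sig = rec.signal
    d = _neighbor_deviation(sig)
    mad = np.median(np.abs(d - np.median(d, axis=1, keepdims=True)), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf
    z = np.abs(d) / robust_sd
    # neighbor agreement: |x(t+1) - x(t-1)| must be small versus the excursion
    gap = np.zeros_like(sig)
    gap[:, 1:-1] = np.abs(sig[:, 2:] - sig[:, :-2])
    pointlike = gap < np.abs(d) + 1e-300
    over = (z > z_threshold) & pointlike
    median_z = np.median(np.where(pointlike, z, 0.0), axis=0)
    frac_over = np.mean(over, axis=0)
    hits = np.nonzero((median_z > z_threshold) & (frac_over > majority))[0]
    # a single-timepoint artifact also perturbs its neighbors' deviation
    # scores; keep only the local maximum of each adjacent run of hits
    if hits.size:
        keep = []
        run = [hits[0]]
        for t in hits[1:]:
            if t == run[-1] + 1:
                run.append(t)
            else:
                keep.append(run[int(np.argmax(median_z[run]))])
                run = [t]
        keep.append(run[int(np.argmax(median_z[run]))])
        hits = np.asarray(keep)
    return ArtifactReport(
        artifact_times=hits,
        deviations=np.median(np.abs(d[:, hits]), axis=0) if hits.size else np.empty(0),
        neurons_affected=(z[:, hits] > z_threshold).sum(axis=0) if hits.size else np.empty(0, dtype=int),
    )


def correct_motion_artifact(rec: FluorescenceRecording, t: int) -> FluorescenceRecording:
    """Replace every neuron's value at ``t`` by the mean of its neighbors.

    At the first/last timepoint the single existing neighbor is copied.
    Idempotent on the corrected index.
    """
    T = rec.n_timepoints
    if not (0 <= t < T):
        raise ValueError(f"t={t} outside [0, {T})")
    sig = rec.signal.copy()
    if t == 0:
        sig[:, 0] = sig[:, 1]
    elif t == T - 1:
        sig[:, -1] = sig[:, -2]
    else:
        sig[:, t] = 0.5 * (sig[:, t - 1] + sig[:, t + 1])
    return rec.with_signal(sig)


def correct_motion_artifacts(
    rec: FluorescenceRecording, report: Optional[ArtifactReport] = None, z_threshold: float = 6.0
) -> tuple[FluorescenceRecording, ArtifactReport]:
    """Detect (unless given a report) and correct all global artifacts."""
    if report is None:
        report = detect_motion_artifacts(rec, z_threshold=z_threshold)
    out = rec
    for t in report.artifact_times:
        out = correct_motion_artifact(out, int(t))
    return out, report


# ---------------------------------------------------------------------------
# Noise floor / SNR
# ---------------------------------------------------------------------------


def _periodogram(trace: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    freqs, pxx = sp_signal.periodogram(trace, fs=1.0 / dt)
    return freqs[1:], pxx[1:]  # drop DC


def noise_floor(trace: np.ndarray, dt: float) -> float:
    """One-sided spectral density of the white-noise floor.

    Estimated as the mean periodogram over the top quartile of
    frequencies, where the slow calcium signal has no power.  For white
    noise of variance s**2 this converges to 2 * s**2 * dt.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 16:
        raise ValueError("need at least 16 samples to estimate the noise floor")
    freqs, pxx = _periodogram(trace, dt)
    hi = freqs >= 0.75 * freqs[-1]
    return float(np.mean(pxx[hi]))


def snr(trace: np.ndarray, dt: float) -> float:
    """Signal-to-noise power ratio P_signal / P_noise of one trace.

    The noise power is the white-noise floor extrapolated over the full
    band; the signal power is the total variance minus the noise power
    (clipped at zero).
    """
    trace = np.asarray(trace, dtype=float)
    floor = noise_floor(trace, dt)
    f_nyq = 0.5 / dt
    p_noise = floor * f_nyq
    p_total = float(np.var(trace))
    if p_noise == 0:
        warnings.warn("zero noise floor; SNR is infinite")
        return float("inf")
    return max(p_total - p_noise, 0.0) / p_noise


# ---------------------------------------------------------------------------
# Total-variation differentiation smoothing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothingResult:
    """Denoised trace and the quantities derived from it.

    ``smoothed`` is the reconstruction (the antiderivative of the
    derivative signal ``u``); ``residual = smoothed - original`` is the
    removed noise; ``noise_floor`` is the spectral density sigma_n^2 tau_n
    of the white-noise model; ``tau_f`` the selected variation timescale.
    """

    smoothed: np.ndarray
    u: np.ndarray
    residual: np.ndarray
    noise_floor: float
    sigma_f: float
    tau_f: float
    snr: float
    n_iterations: int = 0


def _second_difference(T: int) -> sparse.csr_matrix:
    return sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(T - 2, T)).tocsr()


def _trend_filter(
    f: np.ndarray,
    lam: float,
    init: Optional[tuple[np.ndarray, np.ndarray]] = None,
    max_iter: int = 4000,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """ADMM solver for min_g 0.5||g - f||^2 + lam * ||D2 g||_1.

    Returns (g, z, w, iterations); raises on non-convergence.  The linear
    system (I + rho * D'D) is pentadiagonal and solved through a banded
    Cholesky factorization, refactored only when the residual-balancing
    rule rescales the penalty parameter rho.
    """
    T = f.size
    D = _second_difference(T)
    DT = D.T.tocsr()

    def factor(rho: float):
        M = (sparse.eye(T) + rho * (DT @ D)).todia()
        ab = np.zeros((3, T))
        for offset in (0, 1, 2):
            ab[2 - offset, offset:] = M.diagonal(offset)
        return sp_linalg.cholesky_banded(ab, lower=False)

    rho = max(lam, 1e-10)
    cb = factor(rho)
    if init is None:
        z = np.asarray(D @ f)
        w = np.zeros(T - 2)
    else:
        z, w = init[0].copy(), init[1].copy()
    g = f.copy()
    scale = max(float(np.linalg.norm(f)), 1.0)
    r_primal = r_dual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        rhs = f + rho * (DT @ (z - w))
        g = sp_linalg.cho_solve_banded((cb, False), rhs)
        Dg = D @ g
        z_old = z
        z = np.sign(Dg + w) * np.maximum(np.abs(Dg + w) - lam / rho, 0.0)
        w = w + Dg - z
        r_primal = float(np.linalg.norm(Dg - z))
        r_dual = float(rho * np.linalg.norm(z - z_old))
        if r_primal < tol * scale and r_dual < tol * scale:
            break
        if it % 25 == 0:  # residual balancing (Boyd et al. rule)
            if r_primal > 10 * r_dual:
                rho *= 2.0
                w /= 2.0
                cb = factor(rho)
            elif r_dual > 10 * r_primal:
                rho /= 2.0
                w *= 2.0
                cb = factor(rho)
    else:
        raise RuntimeError(
            f"trend-filter ADMM did not converge in {max_iter} iterations "
            f"(primal residual {r_primal:.3g}, dual {r_dual:.3g}, lam={lam:.3g})"
        )
    return g, z, w, it


def tv_smooth(
    trace: np.ndarray,
    dt: float,
    tau_f: Optional[float] = None,
    n_tau: int = 10,
    max_iter: int = 4000,
) -> SmoothingResult:
    """Denoise one trace by total-variation differentiation regularization.

    The reconstruction g minimizes an L1 penalty on the variation of its
    derivative plus an L2 data-fidelity term whose weight is set by the
    white-noise spectral density read off the high-frequency periodogram.
    The remaining free parameter — the variation timescale ``tau_f`` — is
    chosen so the residual's cumulative power spectrum best matches (least
    RMS difference) the extrapolated white-noise spectrum; pass ``tau_f``
    to pin it instead.

    Raises ``RuntimeError`` with iteration diagnostics if the inner ADMM
    solver fails to converge.
    """
    f = np.asarray(trace, dtype=float)
    if f.ndim != 1:
        raise ValueError("tv_smooth expects a single trace")
    if f.size < 16:
        raise ValueError("need at least 16 samples (spectral noise-floor estimate)")
    floor = noise_floor(f, dt)
    sigma_f = float(np.std(f))
    f_nyq = 0.5 / dt
    p_noise = floor * f_nyq

    if sigma_f == 0 or floor < 1e-12 * max(sigma_f**2 * dt, 1e-300):
        # no detectable noise: the trace is its own reconstruction
        g = f.copy()
        u = np.gradient(g, dt)
        return SmoothingResult(
            smoothed=g, u=u, residual=g - f, noise_floor=floor / 2.0,
            sigma_f=sigma_f, tau_f=0.0, snr=float("inf"),
        )

    freqs, _ = _periodogram(f, dt)
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    cum_white = floor * np.cumsum(np.full(freqs.size, df))

    def solve_for(tau: float, init):
        # lam in sample units: tau * (two-sided density) / (sigma_f * dt^2)
        lam = tau * (floor / 2.0) / (sigma_f * dt**2)
        return _trend_filter(f, lam, init=init, max_iter=max_iter)

    if tau_f is not None:
        g, _, _, it = solve_for(tau_f, None)
        best = (tau_f, g, it)
    else:
        taus = np.geomspace(dt, f.size * dt / 4.0, n_tau)
        best = None
        best_err = np.inf
        init = None
        for tau in taus:
            g, z, w, it = solve_for(tau, init)
            init = (z, w)
            r = f - g
            _, pr = _periodogram(r, dt)
            cum_r = np.cumsum(pr) * df
            err = float(np.sqrt(np.mean((cum_r - cum_white) ** 2)))
            if err < best_err:
                best_err = err
                best = (float(tau), g, it)
    tau, g, it = best
    u = np.gradient(g, dt)
    p_total = float(np.var(f))
    ratio = max(p_total - p_noise, 0.0) / p_noise if p_noise > 0 else float("inf")
    return SmoothingResult(
        smoothed=g, u=u, residual=g - f, noise_floor=floor / 2.0,
        sigma_f=sigma_f, tau_f=tau, snr=ratio, n_iterations=it,
    )


def smooth_recording(
    rec: FluorescenceRecording, **kwargs
) -> tuple[FluorescenceRecording, list[SmoothingResult]]:
    """Apply :func:`tv_smooth` to every neuron independently."""
    results = [tv_smooth(rec.signal[i], rec.dt, **kwargs) for i in range(rec.n_neurons)]
    smoothed = np.vstack([r.smoothed for r in results])
    return rec.with_signal(smoothed), results


# ---------------------------------------------------------------------------
# Atypical neurons
# ---------------------------------------------------------------------------


def _event_runs(u: np.ndarray, positive: bool) -> list[tuple[int, int]]:
    """Maximal runs where the derivative is strictly positive/negative."""
    mask = u > 0 if positive else u < 0
    runs = []
    start = None
    for t, m in enumerate(mask):
        if m and start is None:
            start = t
        elif not m and start is not None:
            runs.append((start, t))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def flag_atypical_neurons(
    rec: FluorescenceRecording,
    max_decay: float = 10.0,
    min_events: int = 3,
) -> list[int]:
    """Indices of neurons whose traces do not look like calcium transients.

    A neuron is flagged when its fitted single-exponential decay timescale
    exceeds ``max_decay`` seconds (slow, non-neuronal transients) or when
    fewer than ``min_events`` onset events are detected after smoothing
    (no oscillating activity).  An event is a rise of the smoothed trace
    by at least three noise standard deviations.
    """
    flagged = []
    for i in range(rec.n_neurons):
        trace = rec.signal[i]
        sm = tv_smooth(trace, rec.dt)
        g, u = sm.smoothed, sm.u
        sigma_n = np.sqrt(max(sm.noise_floor * 2.0, 0.0) * 0.5 / rec.dt)
        amp_min = max(3.0 * sigma_n, 0.05 * (np.max(g) - np.min(g) + 1e-300))

        onsets = [
            (a, b) for a, b in _event_runs(u, positive=True) if g[b - 1] - g[a] >= amp_min
        ]
        n_events = len(onsets)

        decays = [
            (a, b) for a, b in _event_runs(u, positive=False) if g[a] - g[b - 1] >= amp_min
        ]
        tau = np.nan
        if decays:
            baseline = float(np.percentile(g, 5))
            ts, ys = [], []
            for a, b in decays:
                y = g[a:b] - baseline
                keep = y > max(amp_min * 0.1, 1e-12)
                if keep.sum() < 3:
                    continue
                y = y[keep]
                t_rel = (np.arange(a, b)[keep] - a) * rec.dt
                ts.append(t_rel)
                ys.append(np.log(y) - np.log(y[0]))
            if ts:
                t_all = np.concatenate(ts)
                y_all = np.concatenate(ys)
                denom = float(t_all @ t_all)
                if denom > 0:
                    slope = float(t_all @ y_all) / denom
                    if slope < 0:
                        tau = -1.0 / slope

        if n_events < min_events or (np.isfinite(tau) and tau > max_decay):
            flagged.append(i)
    return flagged
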