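"""Scoring and summary statistics for GC networks.

Directional-bias ratios for chain-organized motor circuits:

* WIC — weight of ipsilateral links: mean GC over same-side ordered pairs
  divided by the sum of the same-side and cross-side means.  0.5 under
  uniform links, 1 when no contralateral flow exists.
* WRC — weight of rostral-to-caudal links among ipsilateral links;
  0.5 under symmetric flow, 1 for purely head-to-tail propagation.

plus the per-neuron *drive* (summed outgoing GC), link-recovery error
rates against a ground-truth adjacency, the lagged cross-correlation
baseline, and the position-normalized polar histogram of significant-link
angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gc import GCResult
from .recording import FluorescenceRecording
from .simulate import NetworkModel

__all__ = [
    "DirectionalMetrics",
    "RecoveryScore",
    "cross_correlation",
    "wic",
    "wrc",
    "drive",
    "directional_metrics",
    "recovery_score",
    "link_angle_histogram",
]


@dataclass(frozen=True)
class DirectionalMetrics:
    """Directional-bias summary of one GC network."""

    wic: float
    wrc: float
    drive: np.ndarray


@dataclass(frozen=True)
class RecoveryScore:
    """Link-recovery confusion rates over ordered pairs (diagonal excluded)."""

    fpr: float  # identified non-existing links / all negatives
    fnr: float  # missing true links / all positives


def cross_correlation(rec: FluorescenceRecording, lag: int = 0) -> np.ndarray:
    """Pearson-normalized lagged cross-correlation matrix.

    ``C[i, j]`` correlates neuron i at time t with neuron j at time
    t + lag, normalized by T and the population standard deviations, so
    that ``C[i, i]`` at lag 0 equals 1.  Symmetric at lag 0.
    """
    sig = rec.signal
    n, T = sig.shape
    if abs(lag) >= T:
        raise ValueError(f"|lag|={abs(lag)} must be < T={T}")
    mean = sig.mean(axis=1, keepdims=True)
    std = sig.std(axis=1)
    centered = sig - mean
    zero_var = std == 0
    if np.any(zero_var):
        warnings.warn(
            f"zero-variance trace(s) at index {np.nonzero(zero_var)[0].tolist()}; "
            "corresponding rows/columns are NaN"
        )
        std = np.where(zero_var, np.nan, std)
    if lag >= 0:
        a, b = centered[:, : T - lag], centered[:, lag:]
    else:
        a, b = centered[:, -lag:], centered[:, : T + lag]
    C = (a @ b.T) / (T * np.outer(std, std))
    return C


def _side_masks(sides: Sequence[str], n: int) -> np.ndarray:
    sides = np.asarray(sides)
    if sides.shape != (n,):
        raise ValueError(f"need one side per neuron ({n}), got shape {sides.shape}")
    if not set(np.unique(sides)) <= {"L", "R"}:
        raise ValueError("every neuron must have side 'L' or 'R'")
    if len(np.unique(sides)) < 2:
        raise ValueError("both sides must be non-empty")
    return sides


def wic(gc: np.ndarray, sides: Sequence[str]) -> float:
    """Weight of ipsilateral links.

    Mean GC over same-side ordered pairs over the sum of the same-side and
    cross-side means; the diagonal is excluded.  NaN (with a warning) when
    the matrix carries no weight at all.
    """
    gc = np.asarray(gc, dtype=float)
    n = gc.shape[0]
    sides = _side_masks(sides, n)
    off = ~np.eye(n, dtype=bool)
    same = (sides[:, None] == sides[None, :]) & off
    cross = (sides[:, None] != sides[None, :]) & off
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m_same = np.nanmean(gc[same])
        m_cross = np.nanmean(gc[cross])
    total = m_same + m_cross
    if not np.isfinite(total) or total == 0:
        warnings.warn("GC matrix carries no weight; WIC undefined")
        return float("nan")
    return float(m_same / total)


def wrc(gc: np.ndarray, sides: Sequence[str], ranks: Sequence[float]) -> float:
    """Weight of rostral-to-caudal links among ipsilateral links.

    Rostral-to-caudal means the driver's rostrocaudal rank is smaller than
    the target's (lower rank = more rostral).  Convention: ``gc[i, j]`` is
    the link j -> i.  Pairs on a side where either rank is undefined are
    excluded.
    """
    gc = np.asarray(gc, dtype=float)
    n = gc.shape[0]
    sides = _side_masks(sides, n)
    ranks = np.asarray(ranks, dtype=float)
    off = ~np.eye(n, dtype=bool)
    same = (sides[:, None] == sides[None, :]) & off
    defined = np.isfinite(ranks[:, None]) & np.isfinite(ranks[None, :])
    # gc[i, j]: driver j, target i; rostral->caudal <=> rank_j < rank_i
    r2c = same & defined & (ranks[None, :] < ranks[:, None])
    c2r = same & defined & (ranks[None, :] > ranks[:, None])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m_rc = np.nanmean(gc[r2c])
        m_cr = np.nanmean(gc[c2r])
    total = m_rc + m_cr
    if not np.isfinite(total) or total == 0:
        warnings.warn("no ipsilateral weight; WRC undefined")
        return float("nan")
    return float(m_rc / total)


def drive(gc: np.ndarray) -> np.ndarray:
    """Per-neuron drive: sum of outgoing GC links, drive_i = sum_j GC(i->j).

    With the j -> i link stored at ``gc[i, j]``, outgoing links of neuron i
    live in column i.
    """
    gc = np.asarray(gc, dtype=float)
    masked = gc.copy()
    np.fill_diagonal(masked, 0.0)
    return np.nansum(masked, axis=0)


def directional_metrics(
    result: GCResult,
    rec: FluorescenceRecording,
    significant_only: bool = True,
) -> DirectionalMetrics:
    """WIC, WRC and drive of a GC result, using the recording's metadata.

    By default the significant-only GC matrix (zeros on non-significant
    links) enters the averages, matching how network-level ratios are
    reported; set ``significant_only=False`` for raw-GC averaging.
    """
    g = result.gc_sig if significant_only else result.gc
    return DirectionalMetrics(
        wic=wic(g, rec.sides),
        wrc=wrc(g, rec.sides, rec.ranks),
        drive=drive(g),
    )


def recovery_score(significant: np.ndarray, truth: NetworkModel | np.ndarray) -> RecoveryScore:
    """False positive/negative rates of a significance mask against truth.

    ``truth`` may be a NetworkModel (its |A| support is used) or a boolean
    adjacency with the same target-row/driver-column convention.  The
    diagonal is excluded from both counts.
    """
    adj = truth.A if isinstance(truth, NetworkModel) else np.asarray(truth)
    adj = adj.astype(bool)
    mask = np.asarray(significant).astype(bool)
    if adj.shape != mask.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {adj.shape}")
    off = ~np.eye(adj.shape[0], dtype=bool)
    positives = adj & off
    negatives = ~adj & off
    fp = int(np.sum(mask & negatives))
    fn = int(np.sum(~mask & positives))
    n_pos, n_neg = int(positives.sum()), int(negatives.sum())
    return RecoveryScore(
        fpr=fp / n_neg if n_neg else 0.0,
        fnr=fn / n_pos if n_pos else 0.0,
    )


def link_angle_histogram(
    result: GCResult,
    positions: np.ndarray,
    n_bins: int = 18,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized polar histogram of significant-link directions.

    The angle of a link is the direction from the driver's position to the
    target's, counterclockwise from +x, binned over [0, 2pi).  The raw
    histogram of significant links is divided bin-wise by the histogram of
    all N(N-1) possible ordered-pair angles, removing the geometric bias of
    the neuron layout; bins with no possible pairs are NaN.

    Returns ``(bin_centers, density)``.
    """
    positions = np.asarray(positions, dtype=float)
    n = result.n_neurons
    if positions.shape != (n, 2):
        raise ValueError("positions must be (N, 2)")
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def angles(pairs: list[tuple[int, int]]) -> np.ndarray:
        d = np.array([positions[i] - positions[j] for j, i in pairs])
        return np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * np.pi)

    def displaced(j: int, i: int) -> bool:
        # coincident somata have no link direction; exclude such pairs
        return bool(np.any(positions[i] != positions[j]))

    all_pairs = [(j, i) for i in range(n) for j in range(n) if i != j and displaced(j, i)]
    sig_pairs = [
        (j, i) for (j, i) in all_pairs if result.significant[i, j]
    ]
    if not sig_pairs:
        warnings.warn("no significant links; empty density")
        return centers, np.zeros(n_bins)
    h_all, _ = np.histogram(angles(all_pairs), bins=edges)
    h_sig, _ = np.histogram(angles(sig_pairs), bins=edges)
    p_all = h_all / h_all.sum()
    p_sig = h_sig / h_sig.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(h_all > 0, p_sig / p_all, np.nan)
    return centers, density
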