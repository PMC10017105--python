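"""Matplotlib views of GC results, lag scans and null ensembles."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .gc import GCResult
from .lags import LagScanResult
from .nulls import NullEnsemble
from .recording import FluorescenceRecording

__all__ = ["plot_gc_matrix", "plot_network", "plot_lag_scan", "plot_null_ensemble", "plot_polar_density"]


def plot_gc_matrix(result: GCResult, significant_only: bool = True, ax=None):
    """Heatmap of the (significant-only) GC matrix; rows = targets."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mat = result.gc_sig if significant_only else result.gc
    im = ax.imshow(mat, cmap="viridis")
    ax.set_xlabel("driver")
    ax.set_ylabel("target")
    ax.set_title(f"{result.mode.upper()} (L={result.L})")
    ax.figure.colorbar(im, ax=ax, label="GC value")
    return ax


def plot_network(
    result: GCResult,
    rec: Optional[FluorescenceRecording] = None,
    ax=None,
):
    """Directed graph of significant links; layout from neuron positions
    when available, else circular."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots()
    n = result.n_neurons
    labels = list(result.labels) if result.labels else [str(i) for i in range(n)]
    G = nx.DiGraph()
    G.add_nodes_from(labels)
    for i in range(n):
        for j in range(n):
            if i != j and result.significant[i, j]:
                G.add_edge(labels[j], labels[i], weight=float(result.gc[i, j]))
    pos_arr = rec.positions if rec is not None else None
    if pos_arr is not None:
        pos = {labels[i]: pos_arr[i] for i in range(n)}
    else:
        pos = nx.circular_layout(G)
    weights = [G[u][v]["weight"] for u, v in G.edges]
    wmax = max(weights) if weights else 1.0
    nx.draw_networkx(
        G, pos=pos, ax=ax, node_color="lightsteelblue", arrows=True,
        width=[0.5 + 2.5 * w / wmax for w in weights],
    )
    ax.set_title(f"{result.mode.upper()} significant links")
    return ax


def plot_lag_scan(scan: LagScanResult, ax=None):
    """Mean GC value versus maximum lag, knee marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if np.any(np.isfinite(scan.mean_gc_bvgc)):
        ax.plot(scan.lags, scan.mean_gc_bvgc, "o-", label="BVGC")
    if np.any(np.isfinite(scan.mean_gc_mvgc)):
        ax.plot(scan.lags, scan.mean_gc_mvgc, "d-", label="MVGC")
    ax.axvline(scan.chosen_L, color="gray", ls="--", label=f"knee L={scan.chosen_L}")
    ax.set_xlabel("maximum lag (samples)")
    ax.set_ylabel("mean GC value")
    ax.legend()
    return ax


def plot_null_ensemble(ens: NullEnsemble, F_observed: Optional[float] = None, ax=None):
    """Histogram of shuffled F-statistics with the fitted null overlaid."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(ens.f_samples, bins=40, density=True, alpha=0.6, label="shuffled F")
    if np.isfinite(ens.fitted_alpha):
        x = np.linspace(0, np.max(ens.f_samples), 300)
        ax.plot(x, stats.f.pdf(x, ens.fitted_alpha, ens.fitted_beta), "k-", label="fitted F-dist")
    if np.isfinite(ens.threshold):
        ax.axvline(ens.threshold, color="gray", ls="--", label="threshold")
    if F_observed is not None:
        ax.axvline(F_observed, color="crimson", label="observed F")
    j, i = ens.pair
    ax.set_xlabel("F-statistic")
    ax.set_title(f"null ensemble {j}->{i} ({ens.shuffle_kind})")
    ax.legend()
    return ax


def plot_polar_density(centers: np.ndarray, density: np.ndarray, ax=None):
    """Normalized polar histogram of significant-link angles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    width = centers[1] - centers[0] if centers.size > 1 else 2 * np.pi
    vals = np.nan_to_num(density)
    ax.bar(centers, vals, width=width, alpha=0.7)
    ax.set_title("link-angle density (position-normalized)")
    return ax
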