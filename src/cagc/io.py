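"""Reading and writing recordings, results and null ensembles.

Two recording formats:

* CSV — first column ``time`` in seconds, one column per neuron with
  header ``label:side:rank`` (side/rank optional); positions are not
  representable in CSV.
* HDF5 — datasets ``signal`` (N x T), ``dt``, ``labels``, ``sides``,
  ``ranks`` (-1 = undefined) and ``positions`` (NaN = undefined).

GC results export as TSV edge lists and GraphML; null ensembles as HDF5
with one group per ordered pair.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .gc import GCResult
from .nulls import NullEnsemble
from .recording import FluorescenceRecording, NeuronMeta

__all__ = [
    "read_recording",
    "write_recording",
    "write_edge_list",
    "write_graphml",
    "write_null_ensembles",
    "read_null_ensembles",
]


def read_recording(path: str | Path) -> FluorescenceRecording:
    """Read a recording from CSV or HDF5 (dispatch on file extension)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_hdf5(path)
    return _read_csv(path)


def write_recording(rec: FluorescenceRecording, path: str | Path) -> None:
    """Write a recording to CSV or HDF5 (dispatch on file extension)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_hdf5(rec, path)
    else:
        rec.to_dataframe().to_csv(path, index=False)


def _read_csv(path: Path) -> FluorescenceRecording:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    labels = [c.split(":")[0] for c in header[1:]]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate neuron labels {dupes}")
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: first column must be 'time' (seconds)")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0])
        raise ValueError(f"{path}: NaN value at row {row}, column {col!r}")
    return FluorescenceRecording.from_dataframe(df)


def _write_hdf5(rec: FluorescenceRecording, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("signal", data=rec.signal)
        h5.create_dataset("dt", data=rec.dt)
        h5.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
        h5.create_dataset("sides", data=rec.sides.astype("S"))
        ranks = np.array(
            [-1 if m.rostrocaudal_rank is None else m.rostrocaudal_rank for m in rec.neuron_meta]
        )
        h5.create_dataset("ranks", data=ranks)
        pos = np.array(
            [(np.nan, np.nan) if m.position is None else m.position for m in rec.neuron_meta]
        )
        h5.create_dataset("positions", data=pos)


def _read_hdf5(path: Path) -> FluorescenceRecording:
    with h5py.File(path, "r") as h5:
        for name in ("signal", "dt"):
            if name not in h5:
                raise ValueError(f"{path}: missing dataset {name!r}")
        sig = np.asarray(h5["signal"], dtype=float)
        dt = float(h5["dt"][()])
        n = sig.shape[0]
        labels = [s.decode() for s in h5["labels"]] if "labels" in h5 else [f"n{i}" for i in range(n)]
        sides = [s.decode() for s in h5["sides"]] if "sides" in h5 else ["unknown"] * n
        ranks = np.asarray(h5["ranks"]) if "ranks" in h5 else np.full(n, -1)
        pos = np.asarray(h5["positions"]) if "positions" in h5 else np.full((n, 2), np.nan)
    if np.isnan(sig).any():
        i, t = np.argwhere(np.isnan(sig))[0]
        raise ValueError(f"{path}: NaN value at neuron {i}, timepoint {t}")
    meta = tuple(
        NeuronMeta(
            label=labels[i],
            side=sides[i],
            rostrocaudal_rank=None if ranks[i] < 0 else int(ranks[i]),
            position=None if np.isnan(pos[i]).any() else (float(pos[i, 0]), float(pos[i, 1])),
        )
        for i in range(n)
    )
    return FluorescenceRecording(signal=sig, dt=dt, neuron_meta=meta)


# ---------------------------------------------------------------------------
# Result exports
# ---------------------------------------------------------------------------


def write_edge_list(result: GCResult, path: str | Path) -> None:
    """TSV edge list: driver, target, F, gc, pvalue, significant."""
    result.to_edge_dataframe().to_csv(path, sep="\t", index=False)


def write_graphml(
    result: GCResult,
    path: str | Path,
    rec: Optional[FluorescenceRecording] = None,
    significant_only: bool = True,
) -> None:
    """Export the GC network as GraphML (nodes carry metadata when given)."""
    import networkx as nx

    n = result.n_neurons
    labels = list(result.labels) if result.labels else [str(i) for i in range(n)]
    G = nx.DiGraph(mode=result.mode, lag=result.L, threshold=result.threshold_info)
    for i in range(n):
        attrs = {}
        if rec is not None:
            m = rec.neuron_meta[i]
            attrs["side"] = m.side
            if m.rostrocaudal_rank is not None:
                attrs["rank"] = m.rostrocaudal_rank
            if m.position is not None:
                attrs["x"], attrs["y"] = m.position
        G.add_node(labels[i], **attrs)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(result.F[i, j]):
                continue
            if significant_only and not result.significant[i, j]:
                continue
            G.add_edge(
                labels[j],
                labels[i],
                gc=float(result.gc[i, j]),
                F=float(result.F[i, j]),
                pvalue=float(result.pvalues[i, j]),
                significant=bool(result.significant[i, j]),
            )
    nx.write_graphml(G, path)


# ---------------------------------------------------------------------------
# Null ensembles
# ---------------------------------------------------------------------------


def write_null_ensembles(nulls: dict[tuple[int, int], NullEnsemble], path: str | Path) -> None:
    """Serialize per-pair shuffle ensembles and their fits to HDF5."""
    with h5py.File(path, "w") as h5:
        for (j, i), ens in nulls.items():
            grp = h5.create_group(f"{j}->{i}")
            grp.create_dataset("f_samples", data=ens.f_samples)
            grp.create_dataset("shifts", data=np.asarray(ens.shifts))
            grp.attrs.update(
                {
                    "shuffle_kind": ens.shuffle_kind,
                    "fitted_alpha": ens.fitted_alpha,
                    "fitted_beta": ens.fitted_beta,
                    "threshold": ens.threshold,
                    "p": ens.p,
                    "fit_converged": ens.fit_converged,
                    "seed": -1 if ens.seed is None else ens.seed,
                }
            )


def read_null_ensembles(path: str | Path) -> dict[tuple[int, int], NullEnsemble]:
    out: dict[tuple[int, int], NullEnsemble] = {}
    with h5py.File(path, "r") as h5:
        for key, grp in h5.items():
            j, i = (int(x) for x in key.split("->"))
            seed = int(grp.attrs["seed"])
            out[(j, i)] = NullEnsemble(
                pair=(j, i),
                f_samples=np.asarray(grp["f_samples"]),
                shuffle_kind=str(grp.attrs["shuffle_kind"]),
                shifts=np.asarray(grp["shifts"]),
                seed=None if seed < 0 else seed,
                fitted_alpha=float(grp.attrs["fitted_alpha"]),
                fitted_beta=float(grp.attrs["fitted_beta"]),
                threshold=float(grp.attrs["threshold"]),
                p=float(grp.attrs["p"]),
                fit_converged=bool(grp.attrs["fit_converged"]),
            )
    return out
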