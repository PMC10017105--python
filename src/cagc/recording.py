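"""Container for multivariate fluorescence recordings.

A :class:`FluorescenceRecording` holds the N x T matrix of normalized
fluorescence traces (DF/F) together with the sampling interval and
per-neuron anatomical metadata (side of the body, rostrocaudal rank,
2-D position).  It is the universal input type of every analysis stage
in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["NeuronMeta", "FluorescenceRecording"]


@dataclass(frozen=True)
class NeuronMeta:
    """Anatomical metadata for one neuron.

    Parameters
    ----------
    label : str
        Free-form identifier (e.g. ``"m3"``).
    side : {"L", "R", "unknown"}
        Side of the body the soma sits on.
    rostrocaudal_rank : int, optional
        Position along the rostrocaudal axis within the neuron's side;
        smaller rank = more rostral.  Must be a strict ordering within
        each side when present.
    position : (float, float), optional
        (x, y) position in micrometers.
    """

    label: str
    side: str = "unknown"
    rostrocaudal_rank: Optional[int] = None
    position: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.side not in ("L", "R", "unknown"):
            raise ValueError(f"side must be 'L', 'R' or 'unknown', got {self.side!r}")


@dataclass(frozen=True)
class FluorescenceRecording:
    """An N-neuron, T-timepoint DF/F recording sampled every ``dt`` seconds.

    Attributes
    ----------
    signal : ndarray, shape (N, T)
        DF/F traces, one row per neuron.  All values must be finite.
    dt : float
        Sampling interval in seconds (> 0).
    neuron_meta : tuple of NeuronMeta
        One record per neuron; generated labels if not supplied.
    """

    signal: np.ndarray
    dt: float
    neuron_meta: tuple[NeuronMeta, ...] = field(default=())

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError(f"signal must be 2-D (neurons x time), got shape {sig.shape}")
        n, t = sig.shape
        if n < 2:
            raise ValueError(f"need at least 2 neurons, got {n}")
        if t < 1:
            raise ValueError("need at least 1 timepoint")
        if not np.all(np.isfinite(sig)):
            bad = np.argwhere(~np.isfinite(sig))[0]
            raise ValueError(f"non-finite signal value at neuron {bad[0]}, timepoint {bad[1]}")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        meta = self.neuron_meta
        if not meta:
            meta = tuple(NeuronMeta(label=f"n{i}") for i in range(n))
        elif len(meta) != n:
            raise ValueError(f"{len(meta)} metadata records for {n} neurons")
        labels = [m.label for m in meta]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate neuron labels")
        # rank must be a strict ordering within each side
        for side in ("L", "R"):
            ranks = [m.rostrocaudal_rank for m in meta if m.side == side and m.rostrocaudal_rank is not None]
            if len(ranks) != len(set(ranks)):
                raise ValueError(f"duplicate rostrocaudal ranks on side {side}")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "neuron_meta", tuple(meta))

    # -- basic introspection ------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_timepoints * self.dt

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.neuron_meta]

    @property
    def sides(self) -> np.ndarray:
        """Per-neuron side as an array of 'L'/'R'/'unknown'."""
        return np.array([m.side for m in self.neuron_meta])

    @property
    def ranks(self) -> np.ndarray:
        """Per-neuron rostrocaudal rank (NaN when undefined)."""
        return np.array(
            [np.nan if m.rostrocaudal_rank is None else float(m.rostrocaudal_rank) for m in self.neuron_meta]
        )

    @property
    def positions(self) -> Optional[np.ndarray]:
        """(N, 2) positions in micrometers, or None if any is missing."""
        if any(m.position is None for m in self.neuron_meta):
            return None
        return np.array([m.position for m in self.neuron_meta], dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt

    # -- derived recordings -------------------------------------------------

    def with_signal(self, signal: np.ndarray) -> "FluorescenceRecording":
        """Return a copy with a new signal matrix (same metadata if N unchanged)."""
        signal = np.asarray(signal, dtype=float)
        meta = self.neuron_meta if signal.shape[0] == self.n_neurons else ()
        return FluorescenceRecording(signal=signal, dt=self.dt, neuron_meta=meta)

    def select_neurons(self, indices: Sequence[int]) -> "FluorescenceRecording":
        """Return the sub-recording containing only ``indices`` (in order)."""
        idx = list(indices)
        return FluorescenceRecording(
            signal=self.signal[idx],
            dt=self.dt,
            neuron_meta=tuple(self.neuron_meta[i] for i in idx),
        )

    def drop_neurons(self, indices: Sequence[int]) -> "FluorescenceRecording":
        keep = [i for i in range(self.n_neurons) if i not in set(indices)]
        return self.select_neurons(keep)

    @classmethod
    def from_dataframe(cls, df, dt: Optional[float] = None) -> "FluorescenceRecording":
        """Build a recording from a tidy DataFrame.

        The frame must have a ``time`` column (seconds) and one column per
        neuron.  Column names of the form ``label:side:rank`` populate the
        metadata; bare names give side='unknown'.
        """
        import pandas as pd  # local import keeps pandas optional at runtime

        df = pd.DataFrame(df)
        if "time" in df.columns:
            time = df["time"].to_numpy(dtype=float)
            df = df.drop(columns=["time"])
            steps = np.diff(time)
            if len(steps) == 0:
                raise ValueError("need at least 2 timepoints to infer dt")
            inferred = float(np.median(steps))
            if np.max(np.abs(steps - inferred)) > 0.01 * inferred:
                raise ValueError("non-uniform time base (jitter exceeds 1% of dt)")
            dt = inferred if dt is None else dt
        if dt is None:
            raise ValueError("dt is required when no time column is present")
        meta = []
        for col in df.columns:
            parts = str(col).split(":")
            label = parts[0]
            side = parts[1] if len(parts) > 1 and parts[1] else "unknown"
            rank = int(parts[2]) if len(parts) > 2 and parts[2] != "" else None
            meta.append(NeuronMeta(label=label, side=side, rostrocaudal_rank=rank))
        return cls(signal=df.to_numpy(dtype=float).T, dt=float(dt), neuron_meta=tuple(meta))

    def to_dataframe(self):
        """Inverse of :meth:`from_dataframe` (column names encode metadata)."""
        import pandas as pd

        cols = {}
        cols["time"] = self.times
        for i, m in enumerate(self.neuron_meta):
            rank = "" if m.rostrocaudal_rank is None else str(m.rostrocaudal_rank)
            name = m.label if m.side == "unknown" and not rank else f"{m.label}:{m.side}:{rank}"
            cols[name] = self.signal[i]
        return pd.DataFrame(cols)
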