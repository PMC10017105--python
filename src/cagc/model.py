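"""Model-style front end over the functional GC machinery.

``GrangerCausality`` is constructed from a :class:`FluorescenceRecording`
(or a tidy DataFrame) and fitted like a statsmodels model::

    model = GrangerCausality(recording, lag=3, mode="mvgc")
    result = model.fit(significance="adaptive", n_shuffles=200, seed=0)
    print(result.summary())

``fit`` returns the :class:`~cagc.gc.GCResult` results object carrying the
F-statistic, GC-value, p-value and significance matrices.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .gc import GCResult, bvgc, mvgc, naive_significance
from .lags import gc_vs_lag
from .nulls import build_null_ensembles, adaptive_significance, normalize_f
from .recording import FluorescenceRecording

__all__ = ["GrangerCausality"]


class GrangerCausality:
    """Pairwise Granger-causality model for a fluorescence recording.

    Parameters
    ----------
    recording : FluorescenceRecording
        The N x T DF/F recording to analyze.
    lag : int, optional
        Maximum regression lag in samples.  When omitted, :meth:`fit`
        selects it at the knee of the mean GC-versus-lag curve.
    mode : {"mvgc", "bvgc"}
        Conditioned (multivariate) or pairwise (bivariate) analysis.
    stimuli : sequence of arrays, optional
        External stimulus series entered as conditional regressors in
        both the reduced and full models.
    """

    def __init__(
        self,
        recording: FluorescenceRecording,
        lag: Optional[int] = None,
        mode: str = "mvgc",
        stimuli: Sequence[np.ndarray] = (),
    ) -> None:
        if mode not in ("bvgc", "mvgc"):
            raise ValueError(f"mode must be 'bvgc' or 'mvgc', got {mode!r}")
        self.recording = recording
        self.lag = lag
        self.mode = mode
        self.stimuli = tuple(np.asarray(s, dtype=float) for s in stimuli)

    @classmethod
    def from_dataframe(cls, df, dt: Optional[float] = None, **kwargs) -> "GrangerCausality":
        """Build the model from a tidy DataFrame (see
        :meth:`FluorescenceRecording.from_dataframe` for the column
        conventions)."""
        return cls(FluorescenceRecording.from_dataframe(df, dt=dt), **kwargs)

    def select_lag(self, lags: Sequence[int] = range(1, 7), theta: float = 0.2) -> int:
        """Choose the maximum lag at the knee of the mean-GC curve."""
        scan = gc_vs_lag(self.recording, lags, mode=self.mode, theta=theta)
        self.lag = scan.chosen_L
        return self.lag

    def fit(
        self,
        p: float = 0.05,
        significance: str = "naive",
        bonferroni: bool = True,
        n_shuffles: Optional[int] = None,
        shuffle_kind: str = "cyclic",
        epochs: Optional[Sequence[tuple[int, int]]] = None,
        seed: Optional[int] = None,
    ) -> GCResult:
        """Compute the GC matrices and test link significance.

        ``significance`` selects the rule: ``"naive"`` (analytic F-test,
        Bonferroni over ordered pairs), ``"adaptive"`` (per-pair
        shuffled-driver null, ML-fitted F-distribution threshold) or
        ``"normalized"`` (F divided by the shuffle-ensemble mean, analytic
        threshold on the normalized statistic).  ``n_shuffles`` defaults
        to 500 for cyclic shuffles and to 1000 (BVGC) / 100 (MVGC) for
        epoch shuffles.
        """
        if self.lag is None:
            self.select_lag()
        compute = mvgc if self.mode == "mvgc" else bvgc
        result = compute(self.recording, self.lag, stimuli=self.stimuli)
        if significance == "naive":
            return naive_significance(result, p=p, bonferroni=bonferroni)
        if significance not in ("adaptive", "normalized"):
            raise ValueError(f"unknown significance rule {significance!r}")
        if n_shuffles is None:
            if shuffle_kind == "epoch":
                n_shuffles = 1000 if self.mode == "bvgc" else 100
            else:
                n_shuffles = 500
        nulls = build_null_ensembles(
            self.recording,
            self.lag,
            mode=self.mode,
            m=n_shuffles,
            shuffle_kind=shuffle_kind,
            seed=seed,
            p=p,
            epochs=epochs,
            stimuli=self.stimuli,
            fit=(significance == "adaptive"),
        )
        if significance == "adaptive":
            return adaptive_significance(result, nulls, p=p)
        return normalize_f(result, nulls, p=p, bonferroni=bonferroni)
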