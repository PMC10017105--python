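"""End-to-end analysis pipeline.

The stage order is fixed — atypical-neuron removal, motion-artifact
correction, smoothing, lag selection, GC, shuffle nulls, adaptive
significance (optionally normalized F), directional metrics — because the
corrections assume it (smoothing, for instance, must see artifact-free
traces).  Individual stages can be toggled but not reordered.  Every run
writes its resolved configuration and seeds next to the outputs so any
output file is regenerable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as cagc_io
from .gc import bvgc, mvgc, naive_significance
from .lags import gc_vs_lag
from .metrics import directional_metrics
from .nulls import adaptive_significance, build_null_ensembles, normalize_f, stimulus_epochs
from .preprocess import correct_motion_artifacts, flag_atypical_neurons, smooth_recording
from .recording import FluorescenceRecording

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cagc.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (JSON-serializable)."""

    input: str = ""
    output_dir: str = "cagc_out"
    lag: int | str = "auto"  # samples, or "auto" for knee selection
    lag_scan: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    mode: str = "both"  # bvgc | mvgc | both
    remove_atypical: bool = True
    artifact_correction: bool = True
    smoothing: bool = True
    max_decay: float = 10.0
    min_events: int = 3
    z_threshold: float = 6.0
    significance: str = "adaptive"  # naive | adaptive | normalized
    shuffle_kind: str = "cyclic"  # cyclic | epoch
    n_shuffles: Optional[int] = None
    epoch_on: float = 10.0
    epoch_off: float = 5.0
    p: float = 0.05
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _default_shuffles(kind: str, mode: str) -> int:
    if kind == "epoch":
        return 1000 if mode == "bvgc" else 100
    return 500


def run_pipeline(
    config: PipelineConfig,
    recording: Optional[FluorescenceRecording] = None,
) -> dict:
    """Run the full pipeline and persist outputs under ``output_dir``.

    ``recording`` bypasses file input when given.  Returns a dict with the
    cleaned recording, chosen lag, per-mode :class:`GCResult` and metrics.
    On stage failure, partial outputs are flagged invalid and a
    :class:`PipelineError` naming the stage is raised.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())
    results: dict = {}

    def stage(name: str):
        log.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    (out_dir / "INVALID").write_text(f"failed at stage {name}: {exc}\n")
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read"):
        rec = recording if recording is not None else cagc_io.read_recording(config.input)
        log.info("recording: %d neurons x %d timepoints, dt=%.4fs", rec.n_neurons, rec.n_timepoints, rec.dt)

    if config.remove_atypical:
        with stage("remove_atypical"):
            flagged = flag_atypical_neurons(rec, max_decay=config.max_decay, min_events=config.min_events)
            if flagged:
                log.info("removing atypical neurons: %s", [rec.labels[i] for i in flagged])
                rec = rec.drop_neurons(flagged)
            results["atypical_neurons"] = flagged

    if config.artifact_correction:
        with stage("motion_artifacts"):
            rec, report = correct_motion_artifacts(rec, z_threshold=config.z_threshold)
            log.info("corrected %d motion artifact(s)", report.n_artifacts)
            results["artifact_report"] = report
            (out_dir / "artifacts.json").write_text(
                json.dumps(
                    {
                        "artifact_times": report.artifact_times.tolist(),
                        "deviations": report.deviations.tolist(),
                        "neurons_affected": report.neurons_affected.tolist(),
                    },
                    indent=2,
                )
            )

    if config.smoothing:
        with stage("smoothing"):
            rec, smooth_info = smooth_recording(rec)
            results["smoothing"] = smooth_info

    with stage("lag_selection"):
        if config.lag == "auto":
            scan = gc_vs_lag(rec, config.lag_scan, mode="mvgc" if config.mode != "bvgc" else "bvgc")
            lag = scan.chosen_L
            results["lag_scan"] = scan
        else:
            lag = int(config.lag)
        log.info("maximum lag L=%d (%.3f s)", lag, lag * rec.dt)
        results["lag"] = lag

    modes = ["bvgc", "mvgc"] if config.mode == "both" else [config.mode]
    epochs = (
        stimulus_epochs(rec.n_timepoints, rec.dt, config.epoch_on, config.epoch_off)
        if config.shuffle_kind == "epoch"
        else None
    )
    metrics_out: dict = {}
    root = np.random.default_rng(config.seed)
    for mode in modes:
        with stage(f"gc_{mode}"):
            result = (mvgc if mode == "mvgc" else bvgc)(rec, lag)
        if config.significance == "naive":
            result = naive_significance(result, p=config.p)
        else:
            with stage(f"null_{mode}"):
                m = config.n_shuffles or _default_shuffles(config.shuffle_kind, mode)
                nulls = build_null_ensembles(
                    rec, lag, mode=mode, m=m, shuffle_kind=config.shuffle_kind,
                    seed=int(root.integers(0, 2**31 - 1)), p=config.p, epochs=epochs,
                    fit=(config.significance == "adaptive"),
                )
                cagc_io.write_null_ensembles(nulls, out_dir / f"nulls_{mode}.h5")
            with stage(f"significance_{mode}"):
                if config.significance == "adaptive":
                    result = adaptive_significance(result, nulls, p=config.p)
                else:
                    result = normalize_f(result, nulls, p=config.p)
        results[mode] = result
        with stage(f"metrics_{mode}"):
            cagc_io.write_edge_list(result, out_dir / f"gc_{mode}_edges.tsv")
            cagc_io.write_graphml(result, out_dir / f"gc_{mode}.graphml", rec=rec)
            entry: dict = {
                "n_significant": int(np.nansum(result.significant)),
                "mean_gc": float(np.nanmean(result.gc)),
                "threshold_info": result.threshold_info,
            }
            sides = set(rec.sides)
            if sides <= {"L", "R"} and len(sides) == 2:
                dm = directional_metrics(result, rec)
                entry.update(wic=dm.wic, wrc=dm.wrc, drive=dm.drive.tolist())
            metrics_out[mode] = entry

    results["recording"] = rec
    results["metrics"] = metrics_out
    payload = {"lag": int(lag), "seed": config.seed, "modes": metrics_out}
    (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    log.info("outputs written to %s", out_dir)
    return results
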