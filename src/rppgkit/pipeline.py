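"""End-to-end orchestration: source -> ROI -> traces -> pulse -> report.

One :class:`RunConfig` fully describes a run; the config is archived next
to the outputs so every result is reproducible.  Per-stage wall-clock
timings are logged for information only.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from rppgkit import enhancement as enh
from rppgkit import face_roi, video_io
from rppgkit.evaluation import EvalReport, score
from rppgkit.preprocess import BandLimits, PreprocessConfig, condition_window
from rppgkit.pulse import HREstimate, window_to_estimate
from rppgkit.synthetic_data import GroundTruthSeries
from rppgkit.traces import RGBTrace, extract_mean_rgb, window_stream

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run; JSON-serializable."""

    source: str
    resolution: Optional[tuple[int, int]] = None
    fps: Optional[float] = None
    window_s: float = 30.0
    slide_s: float = 1.0
    f_low: float = 0.7
    f_high: float = 4.0
    order: int = 3
    smooth_w: int = 5
    filter: str = "butterworth"
    mean_normalize: bool = False
    enhance: bool = False
    cs_seed: int = 0
    cs_iterations: int = 50
    backend: str = "fixture"
    roi_box: Optional[tuple[int, int, int, int]] = None
    model_path: Optional[str] = None
    out_dir: Optional[str] = None
    truth: Optional[str] = None
    tol_bpm: float = 3.0

    @property
    def band(self) -> BandLimits:
        return BandLimits(self.f_low, self.f_high)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class PipelineResult:
    estimates: list[HREstimate]
    trace: RGBTrace
    report: Optional[EvalReport] = None
    timings_s: dict = field(default_factory=dict)


def _enhanced_mean(frame: np.ndarray, mask: np.ndarray,
                   config: RunConfig) -> tuple[float, float, float]:
    """ROI mean after double-plateau enhancement of the masked region."""
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    sub = frame[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    submask = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    y = enh.luminance(sub)
    y_idx = np.clip(np.rint(y), 0, 255).astype(np.uint8)
    hist = np.bincount(y_idx[submask].ravel(), minlength=256).astype(float)
    level = enh.segment_histogram(hist)
    params = enh.optimize_plateaus(
        hist, level, enh.CSConfig(seed=config.cs_seed,
                                  iterations=config.cs_iterations))
    result = enh.apply_double_plateau_equalization(sub, params)
    return extract_mean_rgb(result.enhanced, submask)


def extract_trace(config: RunConfig) -> RGBTrace:
    """Run the spatial half of the pipeline: frames -> mean-color trace.

    When detection fails on a frame the last valid mask is reused for at
    most one second of frames, after which samples are marked invalid
    (their windows are dropped downstream).
    """
    backend = face_roi.make_backend(
        config.backend,
        box=face_roi.FaceBox(*config.roi_box) if config.roi_box else None,
        model_path=config.model_path)

    src = video_io.open_source(config.source, config.resolution, config.fps)
    reuse_limit = int(round(src.fps))
    r, g, b, valid = [], [], [], []
    last_mask: Optional[np.ndarray] = None
    last_box = None
    reused = 0
    with src:
        for _, frame in video_io.read_frames(src):
            box = face_roi.detect_face(frame, backend)
            mask = None
            if box is not None:
                if box == last_box and last_mask is not None and reused == 0:
                    mask = last_mask  # static detection: mask unchanged
                else:
                    lm = face_roi.extract_landmarks(frame, box, backend)
                    roi = face_roi.forehead_mask(lm, frame.shape[:2])
                    mask = None if roi.empty else roi.mask
            if mask is not None:
                last_mask, last_box, reused = mask, box, 0
            elif last_mask is not None and reused < reuse_limit:
                mask = last_mask
                reused += 1
            if mask is None:
                r.append(np.nan), g.append(np.nan), b.append(np.nan)
                valid.append(False)
                continue
            if config.enhance:
                mr, mg, mb = _enhanced_mean(frame, mask, config)
            else:
                mr, mg, mb = extract_mean_rgb(frame, mask)
            r.append(mr), g.append(mg), b.append(mb)
            valid.append(True)
    return RGBTrace(fps=src.fps, r=np.array(r), g=np.array(g),
                    b=np.array(b), valid=np.array(valid, dtype=bool))


def estimate_from_trace(trace: RGBTrace, config: RunConfig) -> list[HREstimate]:
    """Run the temporal half: trace -> per-window heart-rate estimates."""
    pp = PreprocessConfig(band=config.band, order=config.order,
                          smooth_w=config.smooth_w, filter=config.filter)
    estimates = []
    for window in window_stream(trace, config.window_s, config.slide_s):
        conditioned = condition_window(window, pp)
        estimates.append(window_to_estimate(
            conditioned, config.band, mean_normalize=config.mean_normalize))
    return estimates


def estimates_to_csv(estimates: list[HREstimate], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["window_start_s", "f_hr_hz", "hr_bpm", "quality"])
        for e in estimates:
            writer.writerow([
                f"{e.window_start_s:.3f}",
                "" if e.f_hr is None else f"{e.f_hr:.6f}",
                "" if e.hr_bpm is None else f"{e.hr_bpm:.4f}",
                f"{e.peak_power_fraction:.6f}",
            ])


def estimates_from_csv(path) -> list[HREstimate]:
    estimates = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            f_hr = float(row["f_hr_hz"]) if row["f_hr_hz"] else None
            hr = float(row["hr_bpm"]) if row["hr_bpm"] else None
            estimates.append(HREstimate(
                f_hr=f_hr, hr_bpm=hr,
                peak_power_fraction=float(row["quality"]),
                window_start_s=float(row["window_start_s"])))
    return estimates


def run(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline described by *config*.

    Writes ``estimates.csv``, ``run_config.json`` (and ``report.json`` /
    ``report.csv`` when ground truth is supplied) into ``out_dir`` if set.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    trace = extract_trace(config)
    timings["signal_extraction"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    estimates = estimate_from_trace(trace, config)
    timings["signal_estimation"] = time.perf_counter() - t0
    for stage, dt in timings.items():
        logger.info("stage %s: %.3f s", stage, dt)

    report = None
    if config.truth is not None and estimates:
        gt = GroundTruthSeries.from_csv(config.truth)
        report = score(estimates, gt, tol_bpm=config.tol_bpm,
                       window_s=config.window_s)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "run_config.json")
        estimates_to_csv(estimates, out / "estimates.csv")
        if report is not None:
            report.to_json(out / "report.json")
            report.to_csv(out / "report.csv")

    return PipelineResult(estimates=estimates, trace=trace, report=report,
                          timings_s=timings)
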