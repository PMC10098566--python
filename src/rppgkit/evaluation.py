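"""Scoring of heart-rate estimates against a ground-truth series.

The headline metric is the percentage of windows whose absolute error is
strictly below 3 bpm; MAE and RMSE are reported alongside.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from rppgkit.pulse import HREstimate
from rppgkit.synthetic_data import GroundTruthSeries

logger = logging.getLogger(__name__)

DEFAULT_TOL_BPM = 3.0


@dataclass(frozen=True)
class WindowScore:
    window_start_s: float
    hr_est: float
    hr_gt: float
    abs_err: float
    hit: bool


@dataclass(frozen=True)
class EvalReport:
    n_windows: int
    accuracy_pct: float
    mae_bpm: float
    rmse_bpm: float
    tol_bpm: float
    per_window: tuple[WindowScore, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_pct <= 100.0:
            raise ValueError("accuracy_pct outside [0, 100]")
        if self.n_windows != len(self.per_window):
            raise ValueError("n_windows does not match per_window length")

    def to_json(self, path) -> None:
        payload = {
            "n_windows": self.n_windows,
            "accuracy_pct": self.accuracy_pct,
            "mae_bpm": self.mae_bpm,
            "rmse_bpm": self.rmse_bpm,
            "tol_bpm": self.tol_bpm,
            "per_window": [vars(w) for w in self.per_window],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["window_start_s", "hr_est", "hr_gt", "abs_err", "hit"])
            for s in self.per_window:
                writer.writerow([f"{s.window_start_s:.3f}", f"{s.hr_est:.4f}",
                                 f"{s.hr_gt:.4f}", f"{s.abs_err:.4f}",
                                 int(s.hit)])


def align_ground_truth(gt: GroundTruthSeries, window_start_s: float,
                       window_s: float) -> Optional[float]:
    """Mean ground-truth bpm over ``[start, start + window_s)``.

    Returns None (window excluded, logged) when no ground-truth sample
    falls inside the interval.
    """
    sel = (gt.timestamps >= window_start_s) \
        & (gt.timestamps < window_start_s + window_s)
    if not sel.any():
        logger.info("no ground truth inside window [%.1f, %.1f) s; excluded",
                    window_start_s, window_start_s + window_s)
        return None
    return float(gt.hr_bpm[sel].mean())


def score(estimates: Sequence[HREstimate], gt: GroundTruthSeries,
          tol_bpm: float = DEFAULT_TOL_BPM,
          window_s: float = 30.0) -> EvalReport:
    """Score estimates with the strict |error| < tol criterion.

    A window scores a hit iff ``|est - gt| < tol_bpm`` (strict at the
    boundary).  Windows with no matching ground truth or with no-signal
    estimates are excluded.  Raises ``ValueError`` when nothing matches.
    """
    rows: list[WindowScore] = []
    for est in estimates:
        if est.hr_bpm is None:
            logger.info("no-signal window at %.1f s excluded from scoring",
                        est.window_start_s)
            continue
        ref = align_ground_truth(gt, est.window_start_s, window_s)
        if ref is None:
            continue
        err = abs(est.hr_bpm - ref)
        rows.append(WindowScore(window_start_s=est.window_start_s,
                                hr_est=est.hr_bpm, hr_gt=ref, abs_err=err,
                                hit=err < tol_bpm))
    if not rows:
        raise ValueError("no estimate could be matched to ground truth")

    errs = np.array([r.abs_err for r in rows])
    hits = sum(r.hit for r in rows)
    return EvalReport(
        n_windows=len(rows),
        accuracy_pct=100.0 * hits / len(rows),
        mae_bpm=float(errs.mean()),
        rmse_bpm=float(np.sqrt((errs ** 2).mean())),
        tol_bpm=tol_bpm,
        per_window=tuple(rows),
    )
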