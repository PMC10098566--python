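"""Per-frame spatial color averaging and sliding-window segmentation.

Each frame's ROI pixels are averaged into one (R, G, B) sample; the
resulting trace is cut into overlapping analysis windows (default 30 s
long, advancing 1 s) from which one heart-rate value is estimated each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RGBTrace:
    """Time-indexed mean-color sequence extracted from the ROI.

    ``r``, ``g``, ``b`` hold the mean 8-bit intensity of each channel per
    frame; ``valid`` flags frames where a ROI was available.  Sample *i*
    corresponds to time ``i / fps`` seconds.
    """

    fps: float
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.g, dtype=float)
        b = np.asarray(self.b, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if not (len(r) == len(g) == len(b) == len(v)):
            raise ValueError("trace channels and validity must have equal length")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "valid", v)

    def __len__(self) -> int:
        return len(self.r)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps

    def to_csv(self, path) -> None:
        """Export as ``time_s,r,g,b,valid`` CSV."""
        rows = np.column_stack(
            [self.times, self.r, self.g, self.b, self.valid.astype(int)])
        np.savetxt(path, rows, delimiter=",",
                   header="time_s,r,g,b,valid", comments="",
                   fmt=["%.6f", "%.9f", "%.9f", "%.9f", "%d"])

    @classmethod
    def from_csv(cls, path, fps: float | None = None) -> "RGBTrace":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if fps is None:
            if rows.shape[0] < 2:
                raise ValueError("cannot infer fps from fewer than 2 samples")
            fps = 1.0 / float(np.mean(np.diff(rows[:, 0])))
        return cls(fps=fps, r=rows[:, 1], g=rows[:, 2], b=rows[:, 3],
                   valid=rows[:, 4].astype(bool))


@dataclass(frozen=True)
class RGBWindow:
    """One complete analysis window cut from an :class:`RGBTrace`."""

    start_s: float
    duration_s: float
    fps: float
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.r) == len(self.g) == len(self.b)):
            raise ValueError("window channels must have equal length")

    def __len__(self) -> int:
        return len(self.r)


def extract_mean_rgb(frame: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Arithmetic mean of each color channel over the mask pixels.

    Raises ``ValueError`` on an empty mask: the caller records an invalid
    sample for that frame instead of a color.
    """
    frame = np.asarray(frame)
    mask = np.asarray(mask, dtype=bool)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected HxWx3 frame, got shape {frame.shape}")
    if mask.shape != frame.shape[:2]:
        raise ValueError("mask shape does not match frame")
    if not mask.any():
        raise ValueError("empty ROI mask")
    pixels = frame[mask].astype(float)
    means = pixels.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def window_stream(trace: RGBTrace, window_s: float = 30.0,
                  slide_s: float = 1.0) -> list[RGBWindow]:
    """Cut *trace* into complete overlapping windows.

    Window *k* covers samples ``[k*step, k*step + length)`` with
    ``step = round(fps*slide_s)`` and ``length = round(fps*window_s)``.
    Only complete windows are emitted; windows containing invalid samples
    are dropped and logged.  A trace shorter than one window yields an
    empty list.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if slide_s <= 0:
        raise ValueError("slide_s must be positive")
    length = int(round(trace.fps * window_s))
    step = int(round(trace.fps * slide_s))
    if length < 1 or step < 1:
        raise ValueError("window and slide must span at least one sample")

    windows: list[RGBWindow] = []
    n = len(trace)
    k = 0
    while k * step + length <= n:
        lo = k * step
        hi = lo + length
        if not trace.valid[lo:hi].all():
            logger.info("window at %.3f s dropped: contains invalid samples",
                        lo / trace.fps)
        else:
            windows.append(RGBWindow(
                start_s=lo / trace.fps, duration_s=window_s, fps=trace.fps,
                r=trace.r[lo:hi].copy(), g=trace.g[lo:hi].copy(),
                b=trace.b[lo:hi].copy()))
        k += 1
    return windows
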