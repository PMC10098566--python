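"""Synthetic pulsatile traces and videos with known ground-truth heart rate.

The generator stands in for webcam recordings of a human forehead: a
skin-colored patch whose per-frame mean color carries a small periodic
component at a configurable heart rate, optionally corrupted by Gaussian
noise, slow achromatic illumination drift, and achromatic flicker.
Because the ground truth is known by construction, every downstream stage
of the pipeline can be verified without human subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from rppgkit.traces import RGBTrace

logger = logging.getLogger(__name__)

#: Relative pulse strength per channel (R, G, B).  The green channel
#: carries the strongest plethysmographic component; the exact ratios are
#: test-oriented defaults, not physiological claims.
DEFAULT_CHANNEL_WEIGHTS = (0.3, 1.0, 0.6)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic pulsatile signal.

    Attributes
    ----------
    hr_bpm : float
        Ground-truth heart rate in beats per minute (pulse frequency is
        ``hr_bpm / 60`` Hz).
    fps : float
        Sampling rate in frames per second.
    duration_s : float
        Length of the recording in seconds.
    pulse_amplitude : float
        Peak amplitude of the pulse sinusoid in 8-bit intensity units,
        scaled per channel by ``channel_weights``.
    baseline_rgb : tuple of float
        Constant skin color, each component in [0, 255].
    noise_sd : float
        Standard deviation of additive white Gaussian noise (per channel,
        independent), in intensity units.
    illum_drift_amp : float
        Peak-to-peak amplitude of a slow linear illumination ramp, applied
        equally to all channels (achromatic).
    flicker_hz : float
        Frequency of an achromatic sinusoidal flicker component.
    flicker_amp : float
        Amplitude of the flicker component (0 disables it).
    harmonic_rel : float
        Relative amplitude of an optional second harmonic of the pulse
        (0 disables it); exercises spectral peak-picking robustness.
    seed : int
        Seed for the noise generator; identical configs produce identical
        output.
    """

    hr_bpm: float = 72.0
    fps: float = 30.0
    duration_s: float = 30.0
    pulse_amplitude: float = 3.0
    baseline_rgb: tuple[float, float, float] = (150.0, 120.0, 100.0)
    noise_sd: float = 0.0
    illum_drift_amp: float = 0.0
    flicker_hz: float = 0.0
    flicker_amp: float = 0.0
    harmonic_rel: float = 0.0
    channel_weights: tuple[float, float, float] = DEFAULT_CHANNEL_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0:
            raise ValueError(f"hr_bpm must be positive, got {self.hr_bpm}")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.baseline_rgb) != 3:
            raise ValueError("baseline_rgb must have three components")
        for v in self.baseline_rgb:
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"baseline component {v} outside [0, 255]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass(frozen=True)
class GroundTruthSeries:
    """Timestamped reference heart-rate values (the pulse-oximeter role)."""

    timestamps: np.ndarray
    hr_bpm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        h = np.asarray(self.hr_bpm, dtype=float)
        if t.shape != h.shape:
            raise ValueError("timestamps and hr_bpm must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "hr_bpm", h)

    def to_csv(self, path) -> None:
        """Write the sidecar as ``time_s,hr_bpm`` CSV."""
        rows = np.column_stack([self.timestamps, self.hr_bpm])
        np.savetxt(path, rows, delimiter=",", header="time_s,hr_bpm",
                   comments="", fmt="%.6f")

    @classmethod
    def from_csv(cls, path) -> "GroundTruthSeries":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(timestamps=rows[:, 0], hr_bpm=rows[:, 1])


def _raw_channels(config: SynthConfig) -> np.ndarray:
    """Unclipped float (3, n) channel signals for *config*."""
    n = config.n_samples
    t = np.arange(n, dtype=float) / config.fps
    f = config.hr_bpm / 60.0
    pulse = np.sin(2.0 * np.pi * f * t)
    if config.harmonic_rel:
        pulse = pulse + config.harmonic_rel * np.sin(4.0 * np.pi * f * t)

    # achromatic components: identical on all channels by construction so
    # the chrominance projection cancels them exactly
    achromatic = np.zeros(n)
    if config.illum_drift_amp:
        ramp = np.linspace(-0.5, 0.5, n) if n > 1 else np.zeros(1)
        achromatic = achromatic + config.illum_drift_amp * ramp
    if config.flicker_amp and config.flicker_hz:
        achromatic = achromatic + config.flicker_amp * np.sin(
            2.0 * np.pi * config.flicker_hz * t)

    rng = np.random.default_rng(config.seed)
    channels = np.empty((3, n))
    for c in range(3):
        channels[c] = (config.baseline_rgb[c]
                       + config.channel_weights[c] * config.pulse_amplitude * pulse
                       + achromatic)
    if config.noise_sd:
        channels += rng.normal(0.0, config.noise_sd, size=(3, n))
    return channels


def generate_trace(config: SynthConfig) -> RGBTrace:
    """Generate a mean-color trace with a pulsatile component at ``hr_bpm``.

    The pulse is a sinusoid at ``hr_bpm / 60`` Hz weighted per channel,
    added to the baseline together with noise, achromatic flicker and slow
    illumination drift.  Values are clipped to [0, 255]; clipping events
    are logged.  Fully reproducible from ``config.seed``.
    """
    channels = _raw_channels(config)
    n_clip = int(np.sum((channels < 0.0) | (channels > 255.0)))
    if n_clip:
        logger.warning(
            "synthetic trace: %d sample(s) clipped to the 8-bit range", n_clip)
    channels = np.clip(channels, 0.0, 255.0)
    valid = np.ones(config.n_samples, dtype=bool)
    return RGBTrace(fps=config.fps, r=channels[0], g=channels[1],
                    b=channels[2], valid=valid)


def ground_truth(config: SynthConfig, rate_hz: float = 1.0) -> GroundTruthSeries:
    """Constant ground-truth series sampled at *rate_hz* over the recording."""
    n = int(np.floor(config.duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    return GroundTruthSeries(timestamps=t,
                             hr_bpm=np.full(n, config.hr_bpm, dtype=float))


def generate_video(
    config: SynthConfig,
    width: int = 160,
    height: int = 120,
    roi_fraction: float = 0.5,
    background_rgb: tuple[int, int, int] = (40, 40, 40),
) -> tuple[np.ndarray, np.ndarray, GroundTruthSeries]:
    """Render the trace as a frame sequence with a central pulsatile patch.

    Returns ``(frames, roi_mask, ground_truth)`` where *frames* is a
    ``(n, height, width, 3)`` uint8 array whose central patch (the declared
    ROI) has per-frame mean color equal to :func:`generate_trace` output to
    within 0.5 intensity units (uint8 quantization), *roi_mask* is the
    boolean patch mask, and the ground truth is sampled at 1 Hz.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    if not 0.0 < roi_fraction <= 1.0:
        raise ValueError("roi_fraction must be in (0, 1]")

    trace = generate_trace(config)
    n = config.n_samples

    pw = max(1, int(round(width * roi_fraction)))
    ph = max(1, int(round(height * roi_fraction)))
    x0 = (width - pw) // 2
    y0 = (height - ph) // 2
    mask = np.zeros((height, width), dtype=bool)
    mask[y0:y0 + ph, x0:x0 + pw] = True

    frames = np.empty((n, height, width, 3), dtype=np.uint8)
    bg = np.array(background_rgb, dtype=np.uint8)
    frames[:] = bg
    patch_color = np.rint(
        np.column_stack([trace.r, trace.g, trace.b])).astype(np.uint8)
    frames[:, y0:y0 + ph, x0:x0 + pw, :] = patch_color[:, None, None, :]

    return frames, mask, ground_truth(config)


def roi_box(width: int, height: int, roi_fraction: float) -> tuple[int, int, int, int]:
    """(x, y, w, h) of the patch rendered by :func:`generate_video`."""
    pw = max(1, int(round(width * roi_fraction)))
    ph = max(1, int(round(height * roi_fraction)))
    return ((width - pw) // 2, (height - ph) // 2, pw, ph)
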