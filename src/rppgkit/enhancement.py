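"""Low-light ROI enhancement: double-plateau histogram equalization.

The luminance histogram of the ROI is split at an Otsu threshold into two
sub-histograms; each is clipped between a lower and an upper plateau limit
before building the cumulative mapping, which limits noise amplification
while balancing brightness.  The plateau pair is chosen by a seeded
cuckoo-search optimizer maximizing the sum of Shannon entropies of the two
clipped sub-histograms.  Enhancement acts on luminance only — chromatic
ratios carry the pulse and are preserved.

This stage is OFF by default; it is an optional pre-step for dim footage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

N_BINS = 256
#: ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PlateauParams:
    """Clipping limits of the two sub-histograms."""

    upper_plateau: int
    lower_plateau: int
    segmentation_level: int

    def __post_init__(self) -> None:
        if not 0 < self.upper_plateau <= 255:
            raise ValueError(f"upper_plateau {self.upper_plateau} outside (0, 255]")
        if not 0 <= self.lower_plateau < self.upper_plateau:
            raise ValueError("lower_plateau must be in [0, upper_plateau)")
        if not 0 <= self.segmentation_level <= 255:
            raise ValueError("segmentation_level outside [0, 255]")


@dataclass(frozen=True)
class CSConfig:
    """Cuckoo-search hyperparameters (all exposed, all seeded)."""

    n_nests: int = 15
    pa: float = 0.25
    iterations: int = 50
    seed: int = 0
    lower_bounds: tuple[int, int] = (0, 254)
    upper_bounds: tuple[int, int] = (1, 255)


@dataclass(frozen=True)
class EnhanceResult:
    """A monotone 256-entry intensity mapping and the remapped ROI."""

    mapping: np.ndarray
    enhanced: np.ndarray


def segment_histogram(histogram: np.ndarray) -> int:
    """Otsu threshold of a 256-bin histogram.

    Maximizes the between-class variance over all split levels ``t`` where
    class 0 is bins ``[0..t]`` and class 1 is bins ``[t+1..255]``; ties go
    to the lowest level.  A single-populated-bin histogram returns that
    bin.
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (N_BINS,):
        raise ValueError(f"expected a {N_BINS}-bin histogram, got {h.shape}")
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram has no mass")
    nonzero = np.nonzero(h)[0]
    if len(nonzero) == 1:
        return int(nonzero[0])

    p = h / total
    bins = np.arange(N_BINS)
    w0 = np.cumsum(p)
    m0 = np.cumsum(p * bins)
    mt = m0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (mt - m0) / w1, 0.0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(var_between))


def clip_subhistogram(sub: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Plateau clipping: cap bins at *upper*, raise nonzero bins to *lower*."""
    clipped = np.minimum(np.asarray(sub, dtype=float), upper)
    nonzero = clipped > 0
    clipped[nonzero] = np.maximum(clipped[nonzero], lower)
    return clipped


def _entropy(h: np.ndarray) -> float:
    total = h.sum()
    if total <= 0:
        return 0.0
    p = h[h > 0] / total
    return float(-(p * np.log2(p)).sum())


def plateau_objective(histogram: np.ndarray, level: int,
                      lower: int, upper: int) -> float:
    """Sum of Shannon entropies of the two clipped sub-histograms."""
    h = np.asarray(histogram, dtype=float)
    lo = clip_subhistogram(h[: level + 1], lower, upper)
    hi = clip_subhistogram(h[level + 1:], lower, upper)
    return _entropy(lo) + _entropy(hi)


def _levy_step(rng: np.random.Generator, size: int, beta: float = 1.5) -> np.ndarray:
    """Mantegna's algorithm for Levy-stable step lengths."""
    from scipy.special import gamma

    sigma = (gamma(1 + beta) * np.sin(np.pi * beta / 2)
             / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))) ** (1 / beta)
    u = rng.normal(0.0, sigma, size)
    v = rng.normal(0.0, 1.0, size)
    return u / np.abs(v) ** (1 / beta)


def _round_candidate(cand: np.ndarray, cfg: CSConfig) -> tuple[int, int]:
    lower = int(np.clip(np.rint(cand[0]), *cfg.lower_bounds))
    upper = int(np.clip(np.rint(cand[1]), *cfg.upper_bounds))
    if upper <= lower:
        upper = min(lower + 1, 255)
        lower = upper - 1 if lower >= upper else lower
    return lower, upper


def optimize_plateaus(histogram: np.ndarray, segmentation_level: int,
                      cs_config: CSConfig = CSConfig()) -> PlateauParams:
    """Choose plateau limits by seeded cuckoo search with Levy flights.

    The returned pair is never worse (under :func:`plateau_objective`)
    than the best member of the initial nest population; with
    ``iterations=0`` the best initial candidate is returned.
    """
    h = np.asarray(histogram, dtype=float)
    cfg = cs_config
    rng = np.random.default_rng(cfg.seed)

    def fitness(cand: np.ndarray) -> float:
        lower, upper = _round_candidate(cand, cfg)
        return plateau_objective(h, segmentation_level, lower, upper)

    lo = np.array([cfg.lower_bounds[0], cfg.upper_bounds[0]], dtype=float)
    hi = np.array([cfg.lower_bounds[1], cfg.upper_bounds[1]], dtype=float)
    nests = rng.uniform(lo, hi, size=(cfg.n_nests, 2))
    fit = np.array([fitness(n) for n in nests])

    for _ in range(cfg.iterations):
        best = nests[np.argmax(fit)]
        # global random walk biased toward the current best nest
        steps = _levy_step(rng, 2 * cfg.n_nests).reshape(cfg.n_nests, 2)
        trial = nests + 0.01 * steps * (nests - best) * (hi - lo)
        # the best nest itself explores isotropically, else it never moves
        trial[np.argmax(fit)] = best + 0.05 * (hi - lo) * rng.normal(size=2)
        trial = np.clip(trial, lo, hi)
        for i in range(cfg.n_nests):
            j = rng.integers(cfg.n_nests)
            f = fitness(trial[i])
            if f > fit[j]:
                nests[j] = trial[i]
                fit[j] = f
        # abandon a fraction pa of the worst nests (elitist: best survives)
        order = np.argsort(fit)
        n_abandon = int(round(cfg.pa * cfg.n_nests))
        for i in order[:n_abandon]:
            nests[i] = rng.uniform(lo, hi)
            fit[i] = fitness(nests[i])

    best = nests[np.argmax(fit)]
    lower, upper = _round_candidate(best, cfg)
    return PlateauParams(upper_plateau=upper, lower_plateau=lower,
                         segmentation_level=segmentation_level)


def build_mapping(histogram: np.ndarray, params: PlateauParams) -> np.ndarray:
    """Monotone 256-entry lookup from the clipped sub-histogram CDFs.

    Bins ``[0..level]`` map into output range ``[0..level]`` and bins
    ``[level+1..255]`` into ``[level+1..255]``, each through the cumulative
    distribution of its clipped sub-histogram.
    """
    h = np.asarray(histogram, dtype=float)
    level = params.segmentation_level
    mapping = np.zeros(N_BINS)

    def equalize(sub: np.ndarray, out_lo: int, out_hi: int) -> np.ndarray:
        clipped = clip_subhistogram(sub, params.lower_plateau,
                                    params.upper_plateau)
        total = clipped.sum()
        if total <= 0:
            return np.linspace(out_lo, out_hi, len(sub))
        cdf = np.cumsum(clipped) / total
        return out_lo + cdf * (out_hi - out_lo)

    mapping[: level + 1] = equalize(h[: level + 1], 0, level)
    if level < 255:
        mapping[level + 1:] = equalize(h[level + 1:], level + 1, 255)
    return np.rint(mapping).astype(np.uint8)


def classical_equalization_mapping(histogram: np.ndarray, level: int) -> np.ndarray:
    """Plain per-segment histogram equalization (the no-plateau limit)."""
    return build_mapping(
        np.asarray(histogram, dtype=float),
        PlateauParams(upper_plateau=255, lower_plateau=0,
                      segmentation_level=level))


def luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma of an (..., 3) RGB array, in [0, 255] floats."""
    return np.asarray(rgb, dtype=float) @ _LUMA


def apply_double_plateau_equalization(
        roi_pixels: np.ndarray, params: PlateauParams) -> EnhanceResult:
    """Remap ROI pixels through the double-plateau luminance mapping.

    For RGB input the mapping is applied to the BT.601 luminance and each
    pixel's channels are scaled by the luminance gain, preserving
    chromatic ratios (the pulse lives in chroma).  2-D input is treated as
    a plain luminance grid.
    """
    roi = np.asarray(roi_pixels)
    if roi.ndim == 3 and roi.shape[2] == 3:
        y = luminance(roi)
    elif roi.ndim == 2:
        y = roi.astype(float)
    else:
        raise ValueError(f"expected HxW or HxWx3 ROI, got shape {roi.shape}")

    y_idx = np.clip(np.rint(y), 0, 255).astype(np.uint8)
    hist = np.bincount(y_idx.ravel(), minlength=N_BINS).astype(float)
    mapping = build_mapping(hist, params)
    y_new = mapping[y_idx].astype(float)

    if roi.ndim == 2:
        enhanced = np.clip(np.rint(y_new), 0, 255).astype(np.uint8)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(y > 0, y_new / y, 1.0)
        enhanced = np.clip(np.rint(roi.astype(float) * gain[..., None]),
                           0, 255).astype(np.uint8)
    return EnhanceResult(mapping=mapping, enhanced=enhanced)


def identity_result(roi_pixels: np.ndarray) -> EnhanceResult:
    """The disabled-module path: identity mapping, untouched pixels."""
    return EnhanceResult(mapping=np.arange(N_BINS, dtype=np.uint8),
                         enhanced=np.asarray(roi_pixels).copy())
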