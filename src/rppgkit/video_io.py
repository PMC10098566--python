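"""Uniform frame-source abstraction over video files and live cameras.

Frames are always delivered as ``(height, width, 3)`` uint8 arrays in
(R, G, B) channel order — the chrominance projection is channel-asymmetric,
so a silent B/R swap would silently corrupt heart-rate estimates.  The
default on-disk container is multi-page TIFF (lossless; lossy codecs would
destroy the sub-intensity color modulations that carry the pulse); other
containers are read through :mod:`imageio` when a plugin is available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class FrameSource:
    """An open sequence of uniformly sampled RGB frames.

    ``n_frames`` is ``None`` for live sources.  Frame timestamps are
    ``frame_index / fps``.
    """

    fps: float
    width: int
    height: int
    n_frames: Optional[int]
    uri: str
    _frames: Optional[np.ndarray] = field(default=None, repr=False)
    _reader: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    def close(self) -> None:
        if self._reader is not None:
            try:
                self._reader.close()
            except Exception:  # pragma: no cover - best effort
                pass
            self._reader = None

    def __enter__(self) -> "FrameSource":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _resize_nearest(frame: np.ndarray, width: int, height: int) -> np.ndarray:
    """Nearest-neighbour resample; keeps uint8 values exact."""
    h, w = frame.shape[:2]
    if (w, h) == (width, height):
        return frame
    rows = (np.arange(height) * h // height).clip(0, h - 1)
    cols = (np.arange(width) * w // width).clip(0, w - 1)
    return frame[np.ix_(rows, cols)]


def write_video(path, frames: np.ndarray, fps: float) -> None:
    """Write uint8 RGB frames to a lossless multi-page TIFF with fps metadata."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[3] != 3:
        raise ValueError(f"expected (n, h, w, 3) frames, got {frames.shape}")
    if frames.dtype != np.uint8:
        raise ValueError("frames must be uint8")
    meta = json.dumps({"fps": fps, "color_order": "RGB"})
    tifffile.imwrite(path, frames, photometric="rgb", compression="zlib",
                     description=meta)


def _open_tiff(path: Path, fps: Optional[float]) -> FrameSource:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].description
    if frames.ndim == 3:  # single frame
        frames = frames[None]
    if frames.ndim != 4 or frames.shape[3] != 3:
        raise IOError(f"{path}: not an RGB frame stack (shape {frames.shape})")
    if fps is None:
        try:
            fps = float(json.loads(desc)["fps"])
        except (ValueError, KeyError, TypeError):
            logger.warning("%s: no fps metadata; assuming 30 fps", path)
            fps = 30.0
    return FrameSource(fps=fps, width=frames.shape[2], height=frames.shape[1],
                       n_frames=frames.shape[0], uri=str(path), _frames=frames)


def _open_imageio(path: Path, fps: Optional[float]) -> FrameSource:
    import imageio.v2 as iio

    reader = iio.get_reader(str(path))
    meta = reader.get_meta_data()
    if fps is None:
        fps = float(meta.get("fps", 30.0))
    first = np.asarray(reader.get_data(0))
    try:
        n_frames = reader.count_frames()
    except Exception:
        n_frames = None
    return FrameSource(fps=fps, width=first.shape[1], height=first.shape[0],
                       n_frames=n_frames, uri=str(path), _reader=reader)


def open_source(uri, requested_resolution: Optional[tuple[int, int]] = None,
                fps: Optional[float] = None) -> FrameSource:
    """Open a video file or camera id as a :class:`FrameSource`.

    ``requested_resolution`` is ``(width, height)``; frames are resampled
    to it on read.  ``fps`` overrides container metadata (needed for
    containers that carry none).
    """
    if isinstance(uri, int) or (isinstance(uri, str) and uri.isdigit()):
        import imageio.v2 as iio

        try:
            reader = iio.get_reader(f"<video{int(uri)}>")
        except Exception as exc:  # pragma: no cover - no camera in CI
            raise IOError(f"camera {uri} unavailable: {exc}") from exc
        meta = reader.get_meta_data()
        size = meta.get("size", (0, 0))
        src = FrameSource(fps=fps or float(meta.get("fps", 30.0)),
                          width=size[0], height=size[1], n_frames=None,
                          uri=str(uri), _reader=reader)
    else:
        path = Path(uri)
        if not path.exists():
            raise IOError(f"cannot open video source: {path} does not exist")
        if path.suffix.lower() in _TIFF_SUFFIXES:
            src = _open_tiff(path, fps)
        else:
            try:
                src = _open_imageio(path, fps)
            except Exception as exc:
                raise IOError(f"cannot open video source {path}: {exc}") from exc
    if requested_resolution is not None:
        src.width, src.height = requested_resolution
    return src


def read_frames(source: FrameSource) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(timestamp_s, frame)`` pairs; timestamps are ``i / fps``.

    Mid-stream decode failures are logged and the frame skipped, leaving a
    gap in the timestamp sequence.
    """
    if source._frames is not None:
        for i, frame in enumerate(source._frames):
            yield i / source.fps, _resize_nearest(frame, source.width,
                                                  source.height)
        return
    if source._reader is None:
        return
    i = 0
    while True:
        try:
            frame = np.asarray(source._reader.get_data(i))
        except IndexError:
            return
        except Exception as exc:
            if source.n_frames is not None and i >= source.n_frames:
                return
            logger.warning("frame %d unreadable, skipped: %s", i, exc)
            i += 1
            continue
        if frame.ndim == 2:
            frame = np.stack([frame] * 3, axis=-1)
        yield i / source.fps, _resize_nearest(frame[..., :3], source.width,
                                              source.height)
        i += 1
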