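"""Face detection, 81-point landmarks, and forehead ROI rasterization.

The landmark schema extends the classic 68-point face annotation with 13
additional points delineating the forehead: indices ``0..67`` are the base
face, ``68..80`` the forehead extension.  The forehead ROI is the filled
polygon bounded below by the eyebrow-top landmark line (indices 17..26)
and above/laterally by the 13 forehead points.

Landmark extraction is backend-pluggable: a dlib model backend and a
mediapipe backend for real faces, and a deterministic geometric fixture
backend so the downstream math is testable without model files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np

N_BASE_LANDMARKS = 68
N_FOREHEAD_LANDMARKS = 13
N_LANDMARKS = N_BASE_LANDMARKS + N_FOREHEAD_LANDMARKS

#: Index ranges of the schema.
BASE_RANGE = range(0, N_BASE_LANDMARKS)
FOREHEAD_RANGE = range(N_BASE_LANDMARKS, N_LANDMARKS)
#: Eyebrow landmarks (left brow 17-21, right brow 22-26) — the lower
#: boundary of the forehead polygon.
EYEBROW_RANGE = range(17, 27)


class ConfigurationError(RuntimeError):
    """A backend is selected but its model or library is unavailable."""


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face bounding box, 0-based, top-left origin."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"face box must have positive size, got {self}")

    @property
    def area(self) -> int:
        return self.w * self.h


@dataclass(frozen=True)
class LandmarkSet:
    """81 (x, y) landmark coordinates following the extended schema."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} (x, y) points, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)

    @property
    def base(self) -> np.ndarray:
        return self.points[list(BASE_RANGE)]

    @property
    def forehead(self) -> np.ndarray:
        return self.points[list(FOREHEAD_RANGE)]

    @property
    def eyebrows(self) -> np.ndarray:
        return self.points[list(EYEBROW_RANGE)]


@dataclass(frozen=True)
class ROIMask:
    """Binary per-frame region-of-interest mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be a 2-D boolean grid")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return self.area == 0

    def to_png(self, path) -> None:
        """Debug export of the mask as an 8-bit PNG."""
        import imageio.v2 as iio

        iio.imwrite(path, (self.mask * np.uint8(255)))


def select_largest(boxes: Sequence[FaceBox]) -> Optional[FaceBox]:
    """Largest-area box, or None when no candidates (single-subject rule)."""
    if not boxes:
        return None
    return max(boxes, key=lambda b: b.area)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of a polygon on a pixel grid.

    Pixel (row, col) is inside when its center ``(col + 0.5, row + 0.5)``
    is inside the polygon under the even-odd rule.  Vertices are (x, y) in
    0-based pixel coordinates; the result is clipped to *shape*.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    h, w = shape
    out = np.zeros((h, w), dtype=bool)

    ys = verts[:, 1]
    r_lo = max(0, int(np.floor(ys.min() - 0.5)))
    r_hi = min(h - 1, int(np.ceil(ys.max())))
    if r_hi < r_lo:
        return out

    x1 = verts[:, 0]
    y1 = verts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    col_centers = np.arange(w) + 0.5

    for r in range(r_lo, r_hi + 1):
        yc = r + 0.5
        # half-open edge rule avoids double-counting vertices on a scanline
        hit = ((y1 <= yc) & (y2 > yc)) | ((y2 <= yc) & (y1 > yc))
        if not hit.any():
            continue
        xs = x1[hit] + (yc - y1[hit]) * (x2[hit] - x1[hit]) / (y2[hit] - y1[hit])
        crossings = (xs[None, :] > col_centers[:, None]).sum(axis=1)
        out[r] = (crossings % 2) == 1
    return out


def forehead_mask(landmarks: LandmarkSet, frame_shape: tuple[int, int]) -> ROIMask:
    """Rasterize the forehead polygon bounded by brow line and forehead arc.

    The polygon walks the 13 forehead points left to right, then the 10
    eyebrow points right to left.  Degenerate geometry (zero area, or the
    forehead arc not above the brow line) yields an empty mask, which the
    pipeline treats as "skip this frame".
    """
    top = landmarks.forehead
    bottom = landmarks.eyebrows
    if np.mean(top[:, 1]) >= np.mean(bottom[:, 1]):
        return ROIMask(np.zeros(frame_shape, dtype=bool))
    polygon = np.vstack([top, bottom[::-1]])
    # shoelace area; degenerate (collinear) polygons rasterize to nothing
    x, y = polygon[:, 0], polygon[:, 1]
    area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 < 1e-9:
        return ROIMask(np.zeros(frame_shape, dtype=bool))
    return ROIMask(rasterize_polygon(polygon, frame_shape))


class LandmarkBackend(Protocol):
    """Face detection + landmark extraction behind one interface."""

    def detect(self, frame: np.ndarray) -> Optional[FaceBox]: ...

    def landmarks(self, frame: np.ndarray, box: FaceBox) -> LandmarkSet: ...


def detect_face(frame: np.ndarray, backend: LandmarkBackend) -> Optional[FaceBox]:
    """At most one face box (largest when several); absence is a value."""
    return backend.detect(frame)


def extract_landmarks(frame: np.ndarray, box: FaceBox,
                      backend: LandmarkBackend) -> LandmarkSet:
    """81 landmark points for *box*, clipped to the frame bounds."""
    lm = backend.landmarks(frame, box)
    h, w = frame.shape[:2]
    pts = lm.points.copy()
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    return LandmarkSet(pts)


class FixtureBackend:
    """Deterministic geometric backend for tests and synthetic videos.

    Construction declares the forehead box (and optional extra candidate
    boxes to exercise the largest-face rule).  Landmarks are placed on an
    analytic grid such that the rasterized forehead polygon reproduces the
    declared box exactly: forehead points span the top edge, eyebrow
    points the bottom edge.
    """

    def __init__(self, box: FaceBox, extra_boxes: Sequence[FaceBox] = ()):
        self.box = box
        self.extra_boxes = tuple(extra_boxes)

    def detect(self, frame: np.ndarray) -> Optional[FaceBox]:
        return select_largest([self.box, *self.extra_boxes])

    def landmarks(self, frame: np.ndarray, box: FaceBox) -> LandmarkSet:
        pts = np.zeros((N_LANDMARKS, 2))
        x, y, w, h = box.x, box.y, box.w, box.h
        # forehead arc: top edge, left -> right
        fx = x + w * np.arange(N_FOREHEAD_LANDMARKS) / (N_FOREHEAD_LANDMARKS - 1)
        pts[list(FOREHEAD_RANGE), 0] = fx
        pts[list(FOREHEAD_RANGE), 1] = y
        # eyebrow line: bottom edge, left -> right
        bx = x + w * np.arange(10) / 9.0
        pts[list(EYEBROW_RANGE), 0] = bx
        pts[list(EYEBROW_RANGE), 1] = y + h
        # remaining base landmarks: uniform analytic grid in a face region
        # below the brow line (positions are arbitrary but deterministic)
        rest = [i for i in BASE_RANGE if i not in EYEBROW_RANGE]
        cols = 10
        for j, idx in enumerate(rest):
            r, c = divmod(j, cols)
            pts[idx, 0] = x + (c + 0.5) * w / cols
            pts[idx, 1] = y + h + (r + 1) * h
        return LandmarkSet(pts)


class DlibBackend:
    """HoG+SVM face detector with an 81-point shape predictor model."""

    def __init__(self, model_path: str):
        try:
            import dlib
        except ImportError as exc:
            raise ConfigurationError(
                "dlib backend requested but dlib is not installed") from exc
        from pathlib import Path

        if not Path(model_path).exists():
            raise ConfigurationError(
                f"dlib landmark model file not found: {model_path}")
        self._detector = dlib.get_frontal_face_detector()
        self._predictor = dlib.shape_predictor(model_path)

    def detect(self, frame: np.ndarray) -> Optional[FaceBox]:
        rects = self._detector(frame, 0)
        boxes = [FaceBox(r.left(), r.top(), r.width(), r.height())
                 for r in rects if r.width() > 0 and r.height() > 0]
        return select_largest(boxes)

    def landmarks(self, frame: np.ndarray, box: FaceBox) -> LandmarkSet:
        import dlib

        rect = dlib.rectangle(box.x, box.y, box.x + box.w, box.y + box.h)
        shape = self._predictor(frame, rect)
        if shape.num_parts != N_LANDMARKS:
            raise ConfigurationError(
                f"model produced {shape.num_parts} points; an 81-point "
                f"predictor is required")
        pts = np.array([[shape.part(i).x, shape.part(i).y]
                        for i in range(N_LANDMARKS)], dtype=float)
        return LandmarkSet(pts)


#: Face-mesh vertex ids mapped onto the base-68 annotation, followed by 13
#: upper-forehead ring vertices for the extension.  Used by the mediapipe
#: backend only.
_MESH_TO_SCHEMA = [
    # jaw 0-16
    127, 234, 93, 58, 172, 136, 149, 148, 152, 377, 378, 365, 397, 288,
    323, 454, 356,
    # eyebrows 17-26
    70, 63, 105, 66, 107, 336, 296, 334, 293, 300,
    # nose 27-35
    168, 197, 5, 4, 75, 97, 2, 326, 305,
    # eyes 36-47
    33, 160, 158, 133, 153, 144, 362, 385, 387, 263, 373, 380,
    # mouth 48-67
    61, 39, 37, 0, 267, 269, 291, 405, 314, 17, 84, 181, 78, 82, 13, 312,
    308, 317, 14, 87,
    # forehead extension 68-80 (hairline ring, left -> right)
    21, 71, 68, 104, 69, 108, 151, 337, 299, 333, 298, 301, 251,
]


class MediapipeBackend:
    """Face-mesh backend mapped onto the 81-index schema."""

    def __init__(self) -> None:
        try:
            import mediapipe as mp
        except ImportError as exc:
            raise ConfigurationError(
                "mediapipe backend requested but mediapipe is not installed"
            ) from exc
        self._mesh = mp.solutions.face_mesh.FaceMesh(
            static_image_mode=True, max_num_faces=1)

    def _mesh_points(self, frame: np.ndarray) -> Optional[np.ndarray]:
        res = self._mesh.process(frame)
        if not res.multi_face_landmarks:
            return None
        h, w = frame.shape[:2]
        lm = res.multi_face_landmarks[0].landmark
        return np.array([[p.x * w, p.y * h] for p in lm])

    def detect(self, frame: np.ndarray) -> Optional[FaceBox]:
        pts = self._mesh_points(frame)
        if pts is None:
            return None
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        if x1 <= x0 or y1 <= y0:
            return None
        return FaceBox(int(x0), int(y0), int(x1 - x0) + 1, int(y1 - y0) + 1)

    def landmarks(self, frame: np.ndarray, box: FaceBox) -> LandmarkSet:
        pts = self._mesh_points(frame)
        if pts is None:
            raise ValueError("no face mesh found inside the given box")
        return LandmarkSet(pts[_MESH_TO_SCHEMA])


def make_backend(name: str, box: Optional[FaceBox] = None,
                 model_path: Optional[str] = None) -> LandmarkBackend:
    """Instantiate a landmark backend by name: fixture | dlib | mediapipe."""
    if name == "fixture":
        if box is None:
            raise ConfigurationError(
                "fixture backend requires a declared ROI box")
        return FixtureBackend(box)
    if name == "dlib":
        if model_path is None:
            raise ConfigurationError(
                "dlib backend requires a landmark model path")
        return DlibBackend(model_path)
    if name == "mediapipe":
        return MediapipeBackend()
    raise ConfigurationError(f"unknown landmark backend: {name!r}")
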