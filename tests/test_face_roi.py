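import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppgkit.face_roi import (BASE_RANGE, EYEBROW_RANGE, FOREHEAD_RANGE,
                              N_FOREHEAD_LANDMARKS, N_LANDMARKS,
                              ConfigurationError, FaceBox, FixtureBackend,
                              LandmarkSet, ROIMask, detect_face,
                              extract_landmarks, forehead_mask, make_backend,
                              rasterize_polygon, select_largest)


def pnpoly(px, py, poly):
    """Franklin's classic even-odd point-in-polygon test (oracle)."""
    inside = False
    n = len(poly)
    j = n - 1
    for i in range(n):
        xi, yi = poly[i]
        xj, yj = poly[j]
        if (yi > py) != (yj > py) and \
                px < (xj - xi) * (py - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


def rasterize_oracle(poly, shape):
    """Naive per-pixel even-odd rasterization at pixel centers."""
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            out[r, c] = pnpoly(c + 0.5, r + 0.5, poly)
    return out


class TestSchema:
    def test_total_landmarks(self):
        assert N_LANDMARKS == 81

    def test_forehead_extension_size(self):
        assert N_FOREHEAD_LANDMARKS == 13
        assert len(FOREHEAD_RANGE) == 13

    def test_indices_partition(self):
        indices = list(BASE_RANGE) + list(FOREHEAD_RANGE)
        assert sorted(indices) == list(range(81))
        assert len(set(indices)) == 81

    def test_eyebrows_within_base(self):
        assert set(EYEBROW_RANGE) <= set(BASE_RANGE)

    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(np.zeros((68, 2)))


class TestFaceBox:
    def test_positive_size_required(self):
        with pytest.raises(ValueError):
            FaceBox(0, 0, 0, 5)

    def test_largest_face_rule(self):
        small = FaceBox(0, 0, 10, 10)    # 100 px^2
        large = FaceBox(5, 5, 20, 20)    # 400 px^2
        assert select_largest([small, large]) == large

    def test_no_candidates(self):
        assert select_largest([]) is None


class TestFixtureBackend:
    def test_detect_returns_declared_box(self):
        box = FaceBox(10, 5, 40, 20)
        backend = FixtureBackend(box)
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        assert detect_face(frame, backend) == box

    def test_detect_multiple_returns_largest(self):
        box = FaceBox(10, 5, 40, 20)
        backend = FixtureBackend(box, extra_boxes=[FaceBox(0, 0, 5, 5)])
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        assert detect_face(frame, backend) == box

    def test_landmark_count(self):
        backend = FixtureBackend(FaceBox(10, 5, 40, 20))
        frame = np.zeros((200, 100, 3), dtype=np.uint8)
        lm = extract_landmarks(frame, backend.detect(frame), backend)
        assert lm.points.shape == (81, 2)
        assert lm.forehead.shape == (13, 2)

    def test_analytic_grid_positions(self):
        box = FaceBox(12, 6, 24, 12)
        backend = FixtureBackend(box)
        frame = np.zeros((200, 100, 3), dtype=np.uint8)
        lm = backend.landmarks(frame, box)
        # forehead points span the top edge left to right
        np.testing.assert_allclose(lm.forehead[:, 1], 6.0)
        np.testing.assert_allclose(lm.forehead[:, 0],
                                   12 + 24 * np.arange(13) / 12)
        # eyebrow points span the bottom edge
        np.testing.assert_allclose(lm.eyebrows[:, 1], 18.0)

    def test_static_mask_zero_jitter(self):
        box = FaceBox(10, 5, 40, 20)
        backend = FixtureBackend(box)
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        masks = []
        for _ in range(3):
            lm = extract_landmarks(frame, detect_face(frame, backend), backend)
            masks.append(forehead_mask(lm, frame.shape[:2]).mask)
        assert np.array_equal(masks[0], masks[1])
        assert np.array_equal(masks[1], masks[2])


class TestForeheadMask:
    def test_rectangle_area(self):
        # fixture landmarks forming an axis-aligned 40x20 rectangle
        backend = FixtureBackend(FaceBox(10, 5, 40, 20))
        frame = np.zeros((200, 100, 3), dtype=np.uint8)
        lm = backend.landmarks(frame, backend.box)
        mask = forehead_mask(lm, frame.shape[:2])
        assert mask.area == 800
        np.testing.assert_array_equal(
            mask.mask, rasterize_oracle(np.vstack(
                [lm.forehead, lm.eyebrows[::-1]]), frame.shape[:2]))

    def test_clipped_to_frame(self):
        backend = FixtureBackend(FaceBox(40, 5, 40, 20))
        frame = np.zeros((30, 60, 3), dtype=np.uint8)
        lm = extract_landmarks(frame, backend.box, backend)
        mask = forehead_mask(lm, frame.shape[:2])
        assert 0 < mask.area <= 30 * 60

    def test_vertically_flipped_is_empty(self):
        backend = FixtureBackend(FaceBox(10, 5, 40, 20))
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        lm = backend.landmarks(frame, backend.box)
        flipped = lm.points.copy()
        flipped[:, 1] = 99 - flipped[:, 1]
        mask = forehead_mask(LandmarkSet(flipped), frame.shape[:2])
        assert mask.empty

    def test_collinear_is_empty(self):
        pts = np.zeros((81, 2))
        pts[:, 0] = np.arange(81)
        pts[:, 1] = 50.0
        pts[list(FOREHEAD_RANGE), 1] = 50.0
        mask = forehead_mask(LandmarkSet(pts), (100, 100))
        assert mask.empty


class TestRasterize:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_even_odd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 8)
        poly = rng.integers(0, 20, size=(n, 2)).astype(float)
        got = rasterize_polygon(poly, (20, 20))
        np.testing.assert_array_equal(got, rasterize_oracle(poly, (20, 20)))

    def test_mask_within_polygon_bbox(self):
        poly = np.array([[3.0, 2.0], [15.0, 4.0], [9.0, 12.0]])
        mask = rasterize_polygon(poly, (20, 20))
        rows, cols = np.nonzero(mask)
        assert rows.min() >= 1 and rows.max() <= 12
        assert cols.min() >= 2 and cols.max() <= 15

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            rasterize_polygon(np.array([[0.0, 0.0], [1.0, 1.0]]), (5, 5))


@settings(max_examples=20, deadline=None)
@given(x=st.integers(0, 10), y=st.integers(0, 10),
       w=st.integers(1, 30), h=st.integers(1, 30))
def test_rectangle_mask_area_property(x, y, w, h):
    backend = FixtureBackend(FaceBox(x, y, w, h))
    frame = np.zeros((200, 200, 3), dtype=np.uint8)
    lm = backend.landmarks(frame, backend.box)
    assert forehead_mask(lm, frame.shape[:2]).area == w * h


class TestBackendFactory:
    def test_fixture_requires_box(self):
        with pytest.raises(ConfigurationError):
            make_backend("fixture")

    def test_unknown_backend(self):
        with pytest.raises(ConfigurationError):
            make_backend("nope")

    def test_dlib_requires_model_path(self):
        with pytest.raises(ConfigurationError):
            make_backend("dlib")

    def test_dlib_missing_model_named_in_error(self):
        # either dlib is absent (install error) or the model file is
        # missing (config error naming the file); both are ConfigurationError
        with pytest.raises(ConfigurationError):
            make_backend("dlib", model_path="/no/such/model.dat")


def test_roimask_png_export(tmp_path):
    mask = ROIMask(np.eye(4, dtype=bool))
    path = tmp_path / "mask.png"
    mask.to_png(path)
    import imageio.v2 as iio

    back = iio.imread(path)
    np.testing.assert_array_equal(back > 0, np.eye(4, dtype=bool))
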