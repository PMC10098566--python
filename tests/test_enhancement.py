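import itertools

import numpy as np
import pytest

from rppgkit.enhancement import (CSConfig, PlateauParams, build_mapping,
                                 classical_equalization_mapping,
                                 clip_subhistogram,
                                 apply_double_plateau_equalization,
                                 identity_result, luminance,
                                 optimize_plateaus, plateau_objective,
                                 segment_histogram)


def otsu_oracle(hist):
    """Brute force over all 256 split levels; ties to the lowest level."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_level, best_var = 0, -1.0
    bins = np.arange(256)
    for t in range(256):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = (hist[: t + 1] * bins[: t + 1]).sum() / hist[: t + 1].sum()
            mu1 = (hist[t + 1:] * bins[t + 1:]).sum() / hist[t + 1:].sum()
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_level, best_var = t, var
    return best_level


class TestSegmentHistogram:
    def test_bimodal_between_modes(self):
        hist = np.zeros(256)
        hist[50] = 100
        hist[200] = 100
        level = segment_histogram(hist)
        assert 50 <= level < 200
        assert level == otsu_oracle(hist)

    def test_uniform_matches_bruteforce(self):
        hist = np.ones(256)
        assert segment_histogram(hist) == otsu_oracle(hist) == 127

    def test_single_bin(self):
        hist = np.zeros(256)
        hist[10] = 42
        assert segment_histogram(hist) == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_random_histograms_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 50, size=256).astype(float)
        assert segment_histogram(hist) == otsu_oracle(hist)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            segment_histogram(np.zeros(256))


class TestObjective:
    def test_matches_independent_recomputation(self, rng):
        hist = rng.integers(0, 100, size=256).astype(float)
        level = 128
        lower, upper = 5, 40
        # independent recomputation of the entropy-sum objective
        def entropy(h):
            h = np.minimum(h, upper)
            nz = h > 0
            h[nz] = np.maximum(h[nz], lower)
            p = h[h > 0] / h[h > 0].sum()
            return -(p * np.log2(p)).sum()

        expected = entropy(hist[: level + 1].copy()) \
            + entropy(hist[level + 1:].copy())
        assert plateau_objective(hist, level, lower, upper) == \
            pytest.approx(expected, abs=1e-12)


class TestOptimizePlateaus:
    def test_seed_determinism(self, rng):
        hist = rng.integers(0, 100, size=256).astype(float)
        cfg = CSConfig(seed=7, iterations=10)
        p1 = optimize_plateaus(hist, 128, cfg)
        p2 = optimize_plateaus(hist, 128, cfg)
        assert p1 == p2

    def test_matches_exhaustive_grid(self, rng):
        # 3-candidate search space: lower fixed at 0, upper in {1, 2, 3}
        hist = rng.integers(0, 10, size=256).astype(float)
        level = segment_histogram(hist)
        cfg = CSConfig(seed=1, iterations=20, n_nests=10,
                       lower_bounds=(0, 0), upper_bounds=(1, 3))
        result = optimize_plateaus(hist, level, cfg)
        grid_best = max(
            ((0, u) for u in (1, 2, 3)),
            key=lambda c: plateau_objective(hist, level, c[0], c[1]))
        assert (result.lower_plateau, result.upper_plateau) == grid_best

    def test_zero_iterations_returns_best_initial(self, rng):
        hist = rng.integers(0, 100, size=256).astype(float)
        cfg = CSConfig(seed=3, iterations=0)
        params = optimize_plateaus(hist, 128, cfg)
        assert 0 <= params.lower_plateau < params.upper_plateau <= 255

    def test_never_worse_than_initial_population(self, rng):
        hist = rng.integers(0, 100, size=256).astype(float)
        level = 128
        f0 = plateau_objective(
            hist, level, *(lambda p: (p.lower_plateau, p.upper_plateau))(
                optimize_plateaus(hist, level, CSConfig(seed=5, iterations=0))))
        f50 = plateau_objective(
            hist, level, *(lambda p: (p.lower_plateau, p.upper_plateau))(
                optimize_plateaus(hist, level, CSConfig(seed=5, iterations=50))))
        assert f50 >= f0


class TestPlateauParams:
    def test_order_enforced(self):
        with pytest.raises(ValueError):
            PlateauParams(upper_plateau=10, lower_plateau=10,
                          segmentation_level=100)

    def test_upper_range(self):
        with pytest.raises(ValueError):
            PlateauParams(upper_plateau=0, lower_plateau=0,
                          segmentation_level=0)


class TestApplyEqualization:
    def test_constant_roi_stays_constant(self):
        roi = np.full((10, 10), 77, dtype=np.uint8)
        params = PlateauParams(upper_plateau=200, lower_plateau=0,
                               segmentation_level=77)
        out = apply_double_plateau_equalization(roi, params)
        assert len(np.unique(out.enhanced)) == 1

    def test_mapping_monotone(self, rng):
        roi = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        params = PlateauParams(upper_plateau=30, lower_plateau=2,
                               segmentation_level=100)
        out = apply_double_plateau_equalization(roi, params)
        assert np.all(np.diff(out.mapping.astype(int)) >= 0)

    def test_output_range(self, rng):
        roi = rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8)
        params = PlateauParams(upper_plateau=10, lower_plateau=1,
                               segmentation_level=60)
        out = apply_double_plateau_equalization(roi, params)
        assert out.enhanced.min() >= 0 and out.enhanced.max() <= 255

    def test_no_plateau_equals_classical_he(self, rng):
        # counts kept <= 255 so upper=255 disables upper clipping entirely
        values = rng.integers(0, 256, size=200).astype(np.uint8)
        hist = np.bincount(values, minlength=256).astype(float)
        level = 128
        mapping = build_mapping(
            hist, PlateauParams(upper_plateau=255, lower_plateau=0,
                                segmentation_level=level))
        # classical per-segment HE oracle, written independently
        expected = np.zeros(256)
        for lo, hi in ((0, level), (level + 1, 255)):
            seg = hist[lo:hi + 1]
            if seg.sum() > 0:
                cdf = np.cumsum(seg) / seg.sum()
                expected[lo:hi + 1] = lo + cdf * (hi - lo)
            else:
                expected[lo:hi + 1] = np.linspace(lo, hi, hi - lo + 1)
        np.testing.assert_array_equal(
            mapping, np.rint(expected).astype(np.uint8))
        np.testing.assert_array_equal(
            mapping, classical_equalization_mapping(hist, level))

    def test_chroma_ratio_preserved(self):
        # RGB pixels rescaled by the per-pixel luminance gain: channel
        # ratios survive up to uint8 rounding
        roi = np.zeros((4, 4, 3), dtype=np.uint8)
        roi[..., 0] = 120
        roi[..., 1] = 80
        roi[..., 2] = 40
        params = PlateauParams(upper_plateau=255, lower_plateau=0,
                               segmentation_level=128)
        out = apply_double_plateau_equalization(roi, params)
        px = out.enhanced[0, 0].astype(float)
        assert px[1] / px[0] == pytest.approx(80 / 120, abs=0.03)
        assert px[2] / px[0] == pytest.approx(40 / 120, abs=0.03)

    def test_clip_subhistogram(self):
        sub = np.array([0.0, 1.0, 5.0, 100.0])
        clipped = clip_subhistogram(sub, lower=2, upper=50)
        np.testing.assert_array_equal(clipped, [0.0, 2.0, 5.0, 50.0])

    def test_luminance_weights(self):
        px = np.array([[[100, 100, 100]]])
        assert luminance(px)[0, 0] == pytest.approx(100.0)

    def test_identity_result(self):
        roi = np.arange(16, dtype=np.uint8).reshape(4, 4)
        out = identity_result(roi)
        np.testing.assert_array_equal(out.mapping, np.arange(256))
        np.testing.assert_array_equal(out.enhanced, roi)
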