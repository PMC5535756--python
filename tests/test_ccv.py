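import numpy as np
import pytest

from conftest import brute_force_alternations

from ccvpatch.base_classifiers import ProbPrediction
from ccvpatch.ccv import (
    AdjustedPrediction,
    CCVModel,
    DegenerateShapeError,
    adjust_predictions,
    alternation_count,
    ccv_of_contour,
    count_sign_alternations,
    fit_ccv_model,
    sample_curve,
    slope_vector,
    split_curves,
    tangent_points,
    weight_abnormal,
    weight_normal,
)
from ccvpatch.preprocess import Contour, trace_contour
from ccvpatch.synth_patches import ShapeParams, generate_mask


class TestTangentPoints:
    def test_disc_left_tangent_column(self, disc_contour):
        q = tangent_points(disc_contour)
        assert q.left[0] == 22  # centre col 31.5, radius ~10

    def test_extremes_lie_on_bounding_box(self, square_mask):
        c = trace_contour(square_mask)
        q = tangent_points(c)
        cols = c.points[:, 0]
        rows = c.points[:, 1]
        assert q.left[0] == cols.min() and q.right[0] == cols.max()
        assert q.top[1] == rows.min() and q.bottom[1] == rows.max()
        # ties broken by smallest traversal index
        assert q.left == tuple(c.points[np.flatnonzero(cols == cols.min())[0]])

    def test_single_pixel_contour_rejected(self):
        with pytest.raises(DegenerateShapeError):
            tangent_points(Contour(points=np.array([(5, 5)])))


class TestSplitCurves:
    def test_disc_arcs_roughly_equal(self, disc_contour):
        arcs = split_curves(disc_contour, tangent_points(disc_contour))
        lengths = sorted(len(a) for a in arcs)
        assert len(arcs) == 4
        assert lengths[-1] - lengths[0] <= len(disc_contour) // 4

    def test_arcs_partition_contour(self, disc_contour):
        arcs = split_curves(disc_contour, tangent_points(disc_contour))
        rebuilt = np.vstack([a[:-1] for a in arcs])
        # partition starts at the first tangent point, a rotation of the contour
        pts = disc_contour.points
        start = np.flatnonzero((pts == rebuilt[0]).all(axis=1))[0]
        rotated = np.vstack([pts[start:], pts[:start]])
        assert np.array_equal(rebuilt, rotated)

    def test_square_arcs_are_sides(self, square_mask):
        c = trace_contour(square_mask)
        arcs = split_curves(c, tangent_points(c))
        for arc in arcs:
            d = np.diff(arc, axis=0)
            assert len(arc) >= 1


class TestSampleCurve:
    def test_interval_two_keeps_endpoints(self):
        curve = np.array([(i, 0) for i in range(10)])
        out = sample_curve(curve, 2)
        assert [p[0] for p in out] == [0, 2, 4, 6, 8, 9]

    def test_interval_one_is_identity(self):
        curve = np.array([(i, i) for i in range(5)])
        assert np.array_equal(sample_curve(curve, 1), curve)

    def test_interval_beyond_length_keeps_endpoints_only(self):
        curve = np.array([(i, 0) for i in range(4)])
        assert np.array_equal(sample_curve(curve, 10), curve[[0, -1]])


class TestSlopeVector:
    def test_slopes_from_anchor(self):
        K = slope_vector(np.array([(0, 0), (2, 2), (4, 8)]))
        assert np.allclose(K, [1.0, 2.0])

    def test_collinear_samples_constant(self):
        K = slope_vector(np.array([(0, 0), (1, 2), (2, 4), (3, 6)]))
        assert np.allclose(K, 2.0)

    def test_vertical_pairs_skipped(self):
        K = slope_vector(np.array([(0, 0), (0, 5), (2, 2)]))
        assert np.allclose(K, [1.0])

    def test_all_vertical_gives_empty(self):
        K = slope_vector(np.array([(0, 0), (0, 1), (0, 2)]))
        assert len(K) == 0 and alternation_count(K) == 0


class TestAlternationCount:
    def test_worked_sign_sequence(self):
        assert count_sign_alternations([+1, +1, -1, -1, +1, -1]) == 3

    def test_monotone_slopes_give_zero(self):
        assert alternation_count([1.0, 2.0, 3.5, 7.0]) == 0

    def test_zeros_inherit_previous_sign(self):
        assert count_sign_alternations([+1, 0, -1]) == 1
        assert count_sign_alternations([0, 0, +1, 0, 0, +1]) == 0

    def test_matches_pair_scan_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            seq = rng.integers(-1, 2, size=rng.integers(0, 15))
            assert count_sign_alternations(seq) == brute_force_alternations(seq)


class TestCCVOfContour:
    def test_star_exceeds_ellipse(self):
        """An 8-lobed star of comparable size has at least the CCV of a
        smooth ellipse in nearly every seed pair."""
        wins = 0
        for seed in range(50):
            ell = generate_mask(ShapeParams(base_radius=12, eccentricity=1.5), seed)
            star = generate_mask(
                ShapeParams(base_radius=12, eccentricity=1.0,
                            boundary_noise_amp=3, n_lobes=8), seed)
            if (ccv_of_contour(trace_contour(star))
                    >= ccv_of_contour(trace_contour(ell))):
                wins += 1
        assert wins >= 45

    def test_mirror_invariance_of_symmetric_shape(self, disc_mask):
        base = ccv_of_contour(trace_contour(disc_mask))
        assert ccv_of_contour(trace_contour(disc_mask[:, ::-1])) == base
        assert ccv_of_contour(trace_contour(disc_mask[::-1, :])) == base

    def test_mirror_invariance_in_distribution(self):
        """Mirroring reverses arc traversal and shifts the 2-pixel sampling
        grid, so individual irregular contours may change by a count or
        two; the statistic is mirror-invariant in distribution."""
        p = ShapeParams(base_radius=10, boundary_noise_amp=2.5, n_lobes=5)
        orig, mirrored = [], []
        for seed in range(60):
            m = generate_mask(p, seed)
            orig.append(ccv_of_contour(trace_contour(m)))
            mirrored.append(ccv_of_contour(trace_contour(m[:, ::-1])))
        assert abs(np.mean(mirrored) - np.mean(orig)) < 0.75

    def test_translation_invariance(self):
        m = generate_mask(ShapeParams(base_radius=9, boundary_noise_amp=2,
                                      n_lobes=6), 3)
        shifted = np.roll(m, (3, -2), axis=(0, 1))
        assert (ccv_of_contour(trace_contour(shifted))
                == ccv_of_contour(trace_contour(m)))

    def test_four_point_diamond_is_zero(self):
        diamond = Contour(points=np.array([(1, 0), (2, 1), (1, 2), (0, 1)]))
        assert ccv_of_contour(diamond) == 0


class TestCCVModel:
    def test_class_means(self):
        model = fit_ccv_model([2, 4, 10, 14],
                              ["normal", "normal", "abnormal", "abnormal"])
        assert model.m1 == 3 and model.m2 == 12 and model.valid

    def test_identical_distributions_flagged(self):
        with pytest.warns(UserWarning):
            model = fit_ccv_model([5, 5, 5, 5],
                                  ["normal", "abnormal", "normal", "abnormal"])
        assert not model.valid

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            fit_ccv_model([1, 2], ["normal", "normal"])

    def test_contour_inputs_accepted(self, disc_contour):
        model = fit_ccv_model([disc_contour, 9], ["normal", "abnormal"])
        assert model.m1 == ccv_of_contour(disc_contour)


class TestWeights:
    model = CCVModel(m1=10, m2=20)

    def test_normal_weight_branches(self):
        assert weight_normal(5, self.model) == 1.2
        assert weight_normal(15, self.model) == pytest.approx(1.0)
        assert weight_normal(25, self.model) == 0.8

    def test_abnormal_weight_branches(self):
        assert weight_abnormal(25, self.model) == 1.2
        assert weight_abnormal(15, self.model) == pytest.approx(1.0)
        assert weight_abnormal(5, self.model) == 0.8

    def test_weights_sum_to_two_everywhere(self):
        grid = np.linspace(-10, 40, 1000)
        total = [weight_normal(c, self.model) + weight_abnormal(c, self.model)
                 for c in grid]
        assert np.allclose(total, 2.0)

    def test_continuity_and_monotonicity(self):
        grid = np.linspace(0, 30, 3001)
        wn = np.array([weight_normal(c, self.model) for c in grid])
        wa = np.array([weight_abnormal(c, self.model) for c in grid])
        assert (np.diff(wn) <= 1e-9).all()  # nonincreasing
        assert (np.diff(wa) >= -1e-9).all()  # nondecreasing
        assert np.abs(np.diff(wn)).max() < 0.01  # no jumps on a fine grid
        assert wn.min() >= 0.8 and wn.max() <= 1.2

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            weight_normal(5, CCVModel(m1=10, m2=10))


class TestAdjustPredictions:
    model = CCVModel(m1=2, m2=10)

    def pred(self, label, p):
        return ProbPrediction(sample_id="s", initial_label=label, p_initial=p)

    def test_low_confidence_normal_with_irregular_contour_flips(self):
        adj = adjust_predictions([self.pred("normal", 0.6)], [12], self.model)[0]
        assert adj.omega == 0.8
        assert adj.p_final == pytest.approx(0.48)
        assert adj.final_label == "abnormal"
        assert adj.p_final_of_final_label == pytest.approx(0.52)

    def test_neutral_weight_keeps_label(self):
        adj = adjust_predictions([self.pred("normal", 0.51)], [6], self.model)[0]
        assert adj.omega == pytest.approx(1.0)
        assert adj.final_label == "normal"

    def test_probability_clipped_at_one(self):
        adj = adjust_predictions([self.pred("abnormal", 0.9)], [15], self.model)[0]
        assert adj.omega == 1.2
        assert adj.p_final == 1.0
        assert adj.final_label == "abnormal"

    def test_missing_ccv_rejected(self):
        with pytest.raises(ValueError):
            adjust_predictions([self.pred("normal", 0.6)], [], self.model)
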