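"""Centerline metrics, dilation tolerance, and the paired statistics."""

import numpy as np
import pytest
import scipy.stats

from hepavess import (
    Mask,
    cl_f1,
    cl_precision,
    cl_recall,
    dilate_physical,
    evaluate_case,
    pearson_r,
    wilcoxon_signed_rank,
)
from hepavess.errors import (
    EmptyInputError,
    ParameterError,
    SampleSizeError,
    UndefinedMetricError,
)
from oracles import ball_lattice_count, exact_signed_rank_pvalue


def tube(shape=(20, 12, 12), x=5, spacing=(1, 1, 1)):
    data = np.zeros(shape, np.uint8)
    data[x, 6, :] = 1
    return Mask(np.swapaxes(data, 0, 0), spacing)


class TestDilatePhysical:
    def test_zero_radius_is_identity(self):
        m = Mask.from_bool(np.random.default_rng(0).random((6, 6, 6)) > 0.5)
        assert np.array_equal(dilate_physical(m, 0.0).data, m.data)

    def test_unit_spacing_2mm_ball_has_33_voxels(self):
        m = Mask(np.zeros((9, 9, 9), np.uint8))
        m.data[4, 4, 4] = 1
        assert dilate_physical(m, 2.0).data.sum() == ball_lattice_count(2.0, (1, 1, 1)) == 33

    def test_anisotropic_spacing_is_physical(self):
        # 2 mm on a (1,1,2) grid reaches one voxel across-plane, two in-plane
        m = Mask(np.zeros((9, 9, 9), np.uint8), spacing=(1, 1, 2))
        m.data[4, 4, 4] = 1
        d = dilate_physical(m, 2.0)
        assert d.data.sum() == ball_lattice_count(2.0, (1, 1, 2))
        assert d.data[4, 4, 6] == 0 and d.data[4, 4, 5] == 1

    def test_extensive_and_monotone_in_radius(self):
        rng = np.random.default_rng(1)
        m = Mask.from_bool(rng.random((8, 8, 8)) > 0.8, spacing=(1, 1, 2))
        d1 = dilate_physical(m, 1.0)
        d2 = dilate_physical(m, 2.5)
        assert np.all(d1.data >= m.data)
        assert np.all(d2.data >= d1.data)


class TestCenterlineMetrics:
    def test_perfect_prediction_scores_one(self):
        m = tube()
        assert cl_recall(m, m, 2.0) == 1.0
        assert cl_precision(m, m, 2.0) == 1.0

    def test_offset_tubes_within_and_beyond_tolerance(self):
        ref, near, far = tube(x=5), tube(x=6), tube(x=9)
        assert cl_recall(ref, near, 2.0) == 1.0
        assert cl_recall(ref, far, 2.0) == 0.0

    def test_empty_prediction_recall_zero_precision_undefined(self):
        ref = tube()
        empty = Mask(np.zeros_like(ref.data), ref.spacing)
        assert cl_recall(ref, empty, 2.0) == 0.0
        with pytest.raises(UndefinedMetricError):
            cl_precision(ref, empty, 2.0)

    def test_far_spurious_tube_halves_precision(self):
        ref = tube(shape=(20, 12, 12), x=5)
        pred = Mask(ref.data.copy(), ref.spacing)
        pred.data[15, 6, :] = 1  # equally long far false tube
        assert cl_precision(ref, pred, 2.0) == pytest.approx(0.5)

    def test_symmetry_recall_precision_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = Mask.from_bool(rng.random((10, 10, 6)) > 0.8, spacing=(1, 1, 2))
            b = Mask.from_bool(rng.random((10, 10, 6)) > 0.8, spacing=(1, 1, 2))
            if not (a.data.any() and b.data.any()):
                continue
            assert cl_recall(a, b, 2.0) == pytest.approx(cl_precision(b, a, 2.0))

    def test_monotone_in_tolerance(self):
        ref, pred = tube(x=5), tube(x=8)
        scores = [cl_recall(ref, pred, t) for t in (0.5, 2.0, 3.5, 5.0)]
        assert scores == sorted(scores)

    def test_liver_restriction_ignores_outside_changes(self, clean_case):
        ref = clean_case.vessel_mask
        pred = Mask(ref.data.copy(), ref.spacing)
        liver = clean_case.liver_mask
        base = evaluate_case(ref, pred, liver)
        noisy = Mask(pred.data.copy(), pred.spacing)
        outside = liver.data == 0
        noisy.data[outside] ^= (
            np.random.default_rng(3).random(outside.sum()) > 0.7
        ).astype(np.uint8)
        changed = evaluate_case(ref, noisy, liver)
        assert changed.cl_recall == pytest.approx(base.cl_recall)
        assert changed.cl_precision == pytest.approx(base.cl_precision)

    def test_evaluate_empty_reference_in_liver_raises(self):
        ref = tube(x=5)
        liver = Mask(np.zeros_like(ref.data), ref.spacing)
        liver.data[15:, :, :] = 1  # liver away from the reference
        with pytest.raises(EmptyInputError):
            evaluate_case(ref, ref, liver)


class TestClF1:
    @pytest.mark.parametrize(
        "r,p,expected",
        [(1.0, 1.0, 1.0), (0.0, 0.7, 0.0), (0.5, 1.0, 2 * 0.5 / 1.5), (0.0, 0.0, 0.0)],
    )
    def test_closed_forms(self, r, p, expected):
        assert cl_f1(r, p) == pytest.approx(expected)

    def test_bounds_identities(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            r, p = rng.random(2)
            f = cl_f1(r, p)
            assert f <= (r + p) / 2 + 1e-12
        assert cl_f1(0.37, 0.37) == pytest.approx(0.37)


class TestWilcoxon:
    def test_five_pair_exact_p(self):
        pairs = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6)]
        stat, p = wilcoxon_signed_rank(pairs)
        assert stat == 0.0
        assert p == pytest.approx(0.0625)
        assert p == pytest.approx(exact_signed_rank_pvalue([a - b for a, b in pairs]))

    def test_matches_scipy_exact_on_random_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=10)
            b = a + rng.normal(0.4, 1.0, size=10)
            if np.any(a == b):
                continue
            _, p = wilcoxon_signed_rank(np.column_stack([a, b]))
            ref = scipy.stats.wilcoxon(a, b, mode="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=8), rng.normal(size=8)
        _, p1 = wilcoxon_signed_rank(np.column_stack([a, b]))
        _, p2 = wilcoxon_signed_rank(np.column_stack([b, a]))
        assert p1 == pytest.approx(p2)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(SampleSizeError):
            wilcoxon_signed_rank([(1.0, 1.0)] * 8)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        b = a + rng.normal(0.3, 1.0, size=30)
        _, p = wilcoxon_signed_rank(np.column_stack([a, b]))
        ref = scipy.stats.wilcoxon(a, b, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            pearson_r([1, 2], [3, 4])
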