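"""Vesselness filtering, Bayesian classification, and the classical chain."""

import numpy as np
import pytest
from scipy import ndimage

from hepavess import (
    BayesClassifierParams,
    Mask,
    VesselnessParams,
    Volume,
    auto_seed,
    classify_vessels,
    directional_dilate,
    fit_bayes_classifier,
    multiscale_vesselness,
    reconnect_fragments,
    run_wang_pipeline,
)
from hepavess.errors import (
    DegenerateStatisticsError,
    ParameterError,
    SeedError,
    SeedFailureError,
    SizeError,
)
from conftest import n_components_26


def bright_tube(shape=(40, 40, 40), radius=3.0, axis=2, contrast=200.0):
    g = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2
    axes = [a for a in range(3) if a != axis]
    r2 = sum((g[a] - c[a]) ** 2 for a in axes)
    data = np.where(r2 <= radius**2, contrast, 0.0).astype(np.float32)
    return Volume(ndimage.gaussian_filter(data, 0.5), (1, 1, 1))


def bright_sphere(shape=(40, 40, 40), radius=3.0, contrast=200.0):
    g = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2
    r2 = sum((g[a] - c[a]) ** 2 for a in range(3))
    data = np.where(r2 <= radius**2, contrast, 0.0).astype(np.float32)
    return Volume(ndimage.gaussian_filter(data, 0.5), (1, 1, 1))


class TestMultiscaleVesselness:
    def test_constant_volume_zero_response(self):
        v = Volume(np.full((10, 10, 10), 60.0, np.float32))
        resp, _ = multiscale_vesselness(v)
        assert np.all(resp.data == 0)

    def test_nonnegative_response(self, clean_case):
        resp, _ = multiscale_vesselness(
            Volume(clean_case.image.data[:32, :32, :24], clean_case.image.spacing)
        )
        assert resp.data.min() >= 0

    def test_tube_beats_equal_sphere_on_axis(self):
        params = VesselnessParams(scales=(1.0, 2.0, 3.0))
        tube_resp, _ = multiscale_vesselness(bright_tube(), params)
        sphere_resp, _ = multiscale_vesselness(bright_sphere(), params)
        centre = (19, 19, 19)
        assert tube_resp.data[centre] > sphere_resp.data[centre]

    def test_rotation_about_z_preserves_axis_response(self):
        params = VesselnessParams(scales=(1.0, 2.0, 3.0), c=1000.0)
        rx, _ = multiscale_vesselness(bright_tube(axis=0), params)
        ry, _ = multiscale_vesselness(bright_tube(axis=1), params)
        a, b = rx.data[19, 19, 19], ry.data[19, 19, 19]
        assert abs(a - b) / max(a, b) < 0.05

    def test_direction_field_follows_tube_axis(self):
        resp, dirs = multiscale_vesselness(bright_tube(axis=2),
                                           VesselnessParams(scales=(2.0, 3.0)))
        d = dirs[19, 19, 19]
        assert abs(d[2]) > 0.95  # aligned with z

    def test_too_small_volume_rejected(self):
        with pytest.raises(SizeError):
            multiscale_vesselness(Volume(np.zeros((4, 10, 10), np.float32)))

    def test_scales_must_be_sorted_positive(self):
        with pytest.raises(ParameterError):
            VesselnessParams(scales=(2.0, 1.0))
        with pytest.raises(ParameterError):
            VesselnessParams(scales=(-1.0, 2.0))


class TestBayesClassifier:
    def fit_two_gaussians(self, seed=0, mu_v=0.8, mu_b=0.1, sd=0.1, n=100):
        rng = np.random.default_rng(seed)
        resp = np.zeros((10, 10, 2), np.float32)
        resp[:5].flat = rng.normal(mu_v, sd, 100)
        resp[5:].flat = rng.normal(mu_b, sd, 100)
        vol = Volume(resp)
        vessel = Mask.from_bool(np.arange(10)[:, None, None] < np.full((10, 10, 2), 5))
        return vol, vessel, Mask.from_bool(vessel.data == 0)

    def test_separated_regions_classified_to_own_class(self):
        vol, vessel, backgr = self.fit_two_gaussians()
        c = fit_bayes_classifier(vol, vessel, backgr)
        labels = classify_vessels(vol, c)
        err = np.mean(labels.data != vessel.data)
        assert err < 0.01

    def test_decision_boundary_near_midpoint_for_equal_priors(self):
        # N(0.8, 0.1^2) vs N(0.1, 0.1^2), equal sizes: boundary at 0.45
        vol, vessel, backgr = self.fit_two_gaussians(sd=0.1)
        c = fit_bayes_classifier(vol, vessel, backgr)
        below = Volume(np.full((3, 3, 3), 0.40, np.float32))
        above = Volume(np.full((3, 3, 3), 0.50, np.float32))
        assert classify_vessels(below, c).data.sum() == 0
        assert classify_vessels(above, c).data.sum() == 27

    def test_identical_regions_fall_back_to_prior(self):
        rng = np.random.default_rng(1)
        resp = Volume(rng.normal(0.5, 0.1, (8, 8, 4)).astype(np.float32))
        half = np.zeros((8, 8, 4), bool)
        half[::2] = True
        c = fit_bayes_classifier(resp, Mask.from_bool(half), Mask.from_bool(~half))
        # likelihoods match, equal region sizes: posterior = prior = 0.5,
        # classification cannot be confidently vessel anywhere
        assert abs(c.vessel_mean - c.background_mean) < 0.05

    def test_all_at_class_mean_labelled_to_that_class(self):
        c = BayesClassifierParams(0.8, 0.01, 0.1, 0.01, 0.5)
        at_vessel = Volume(np.full((4, 4, 4), 0.8, np.float32))
        at_bg = Volume(np.full((4, 4, 4), 0.1, np.float32))
        assert classify_vessels(at_vessel, c).data.all()
        assert not classify_vessels(at_bg, c).data.any()

    def test_zero_variance_region_rejected(self):
        resp = Volume(np.zeros((6, 6, 6), np.float32))
        m = Mask.from_bool(np.ones((6, 6, 6), bool))
        with pytest.raises(DegenerateStatisticsError):
            fit_bayes_classifier(resp, m, m)

    def test_raising_vessel_prior_is_monotone(self):
        rng = np.random.default_rng(2)
        resp = Volume(rng.random((8, 8, 8)).astype(np.float32))
        lo = BayesClassifierParams(0.8, 0.02, 0.2, 0.02, 0.3)
        hi = BayesClassifierParams(0.8, 0.02, 0.2, 0.02, 0.7)
        m_lo = classify_vessels(resp, lo).data
        m_hi = classify_vessels(resp, hi).data
        assert np.all(m_hi >= m_lo)


class TestDirectionalDilate:
    def gap_tube(self, gap=2):
        data = np.zeros((30, 9, 9), np.uint8)
        data[2:13, 4, 4] = 1
        data[13 + gap : 28, 4, 4] = 1
        dirs = np.zeros((30, 9, 9, 3), np.float32)
        dirs[..., 0] = 1.0
        return Mask(data, (1, 1, 1)), dirs

    def test_zero_length_identity(self):
        m, dirs = self.gap_tube()
        out = directional_dilate(m, dirs, 0.0)
        assert np.array_equal(out.data, m.data)

    def test_bridges_gap_into_single_component(self):
        m, dirs = self.gap_tube(gap=2)
        assert n_components_26(m) == 2
        out = directional_dilate(m, dirs, 3.0)
        assert n_components_26(out) == 1

    def test_never_shrinks(self):
        m, dirs = self.gap_tube()
        out = directional_dilate(m, dirs, 3.0)
        assert np.all(out.data >= m.data)


class TestReconnectFragments:
    def test_already_connected_unchanged(self):
        data = np.zeros((10, 5, 5), np.uint8)
        data[2:8, 2, 2] = 1
        m = Mask(data, (1, 1, 1))
        out = reconnect_fragments(m, (2, 2, 2), 2.0)
        assert np.array_equal(out.data, m.data)

    def test_near_fragments_bridged_far_blob_removed(self):
        data = np.zeros((30, 7, 7), np.uint8)
        data[2:10, 3, 3] = 1
        data[11:18, 3, 3] = 1  # 1 mm gap
        data[27, 3, 3] = 1  # ~9 mm away, beyond max_gap
        m = Mask(data, (1, 1, 1))
        out = reconnect_fragments(m, (2, 3, 3), max_gap=2.0)
        assert n_components_26(out) == 1
        assert out.data[27, 3, 3] == 0
        assert out.data[10, 3, 3] == 1  # bridge voxel

    def test_seed_outside_mask_rejected(self):
        m = Mask(np.zeros((5, 5, 5), np.uint8))
        m.data[1, 1, 1] = 1
        with pytest.raises(SeedError):
            reconnect_fragments(m, (4, 4, 4), 2.0)


class TestAutoSeed:
    def test_seed_lands_in_aorta(self, clean_case):
        seed = auto_seed(clean_case.image)
        # the aorta is the thickest structure; its axis sits at the tree root
        root_pos = clean_case.tree.positions[clean_case.tree.root]
        world = clean_case.image.index_to_world(np.asarray(seed))
        assert np.linalg.norm(world[:2] - root_pos[:2]) <= clean_case.params.aorta_radius

    def test_single_tube_seed_on_axis(self):
        v = bright_tube(radius=4.0)
        seed = auto_seed(v, bright_threshold=100.0)
        assert seed[0] in (19, 20) and seed[1] in (19, 20)

    def test_all_dark_volume_fails_with_seed_error(self):
        v = Volume(np.zeros((10, 10, 10), np.float32))
        with pytest.raises(SeedFailureError):
            auto_seed(v)


class TestWangPipeline:
    def test_all_dark_volume_raises_seed_failure(self):
        v = Volume(np.zeros((16, 16, 16), np.float32), (1, 1, 1))
        with pytest.raises(SeedFailureError):
            run_wang_pipeline(v)

    def test_output_single_component(self, wang_mask_clean):
        assert n_components_26(wang_mask_clean) == 1

    def test_confounder_voxels_leak_into_output(self, vein_case, wang_mask_vein):
        # the intensity-driven chain cannot tell a parallel vein from an
        # artery: some confounder voxels survive into the tree
        overlap = (wang_mask_vein.data > 0) & (vein_case.confounder_mask.data > 0)
        assert overlap.sum() > 0
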