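"""Model-output combination, skeletons, and cost-based tree connection."""

import numpy as np
import pytest

from hepavess import (
    Mask,
    Volume,
    combine_model_outputs,
    connect_to_root,
    postprocess,
    select_root,
    skeletonize_with_radii,
)
from hepavess.errors import EmptyInputError, GeometryError, ParameterError, SeedError
from conftest import n_components_26, soft_maps
from oracles import relaxation_shortest_paths


class TestCombineModelOutputs:
    def test_zero_coarse_returns_fine(self):
        fine = Volume(np.random.default_rng(0).random((8, 8, 8)).astype(np.float32),
                      (1, 1, 1))
        coarse = Volume(np.zeros((4, 4, 4), np.float32), (2, 2, 2))
        out = combine_model_outputs(fine, coarse)
        assert np.allclose(out.data, fine.data)

    def test_same_grid_idempotent(self):
        fine = Volume(np.random.default_rng(1).random((6, 6, 6)).astype(np.float32))
        out = combine_model_outputs(fine, fine)
        assert np.array_equal(out.data, fine.data)

    def test_voxelwise_maximum(self):
        fine = Volume(np.full((4, 4, 4), 0.3, np.float32))
        coarse = Volume(np.full((4, 4, 4), 0.9, np.float32))
        assert np.allclose(combine_model_outputs(fine, coarse).data, 0.9)

    def test_disjoint_extents_rejected(self):
        fine = Volume(np.zeros((4, 4, 4), np.float32), origin=(0, 0, 0))
        coarse = Volume(np.zeros((4, 4, 4), np.float32), origin=(100, 100, 100))
        with pytest.raises(GeometryError):
            combine_model_outputs(fine, coarse)


class TestSkeletonizeWithRadii:
    def test_tube_skeleton_is_axial_line_with_correct_radius(self):
        data = np.zeros((30, 13, 13), np.uint8)
        g = np.indices((30, 13, 13)).astype(float)
        data[((g[1] - 6) ** 2 + (g[2] - 6) ** 2) <= 9.0] = 1
        s = skeletonize_with_radii(Mask(data, (1, 1, 1)))
        # 1-voxel-wide line along x at the tube centre
        assert len(s) <= 32
        assert np.all(np.abs(s.voxels[:, 1] - 6) <= 1)
        diag = np.linalg.norm([1, 1, 1])
        assert abs(np.median(s.radii) - 3.0) <= diag

    def test_single_voxel_mask(self):
        m = Mask(np.zeros((5, 5, 5), np.uint8))
        m.data[2, 3, 1] = 1
        s = skeletonize_with_radii(m)
        assert len(s) == 1 and tuple(s.voxels[0]) == (2, 3, 1)

    def test_skeleton_subset_of_mask(self, clean_case):
        s = skeletonize_with_radii(clean_case.vessel_mask)
        assert np.all(clean_case.vessel_mask.data[tuple(s.voxels.T)] == 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyInputError):
            skeletonize_with_radii(Mask(np.zeros((4, 4, 4), np.uint8)))


class TestSelectRoot:
    def test_root_lands_in_aorta(self, clean_case):
        s = skeletonize_with_radii(clean_case.vessel_mask)
        root = select_root(s)
        root_pos = clean_case.tree.positions[clean_case.tree.root]
        world = clean_case.vessel_mask.index_to_world(np.asarray(root))
        assert np.linalg.norm(world[:2] - root_pos[:2]) <= clean_case.params.aorta_radius

    def test_uniform_radius_tie_breaks_by_linear_index(self):
        data = np.zeros((10, 3, 3), np.uint8)
        data[1:9, 1, 1] = 1
        s = skeletonize_with_radii(Mask(data, (1, 1, 1)))
        uniform = s.radii == s.radii[0]
        if uniform.all():
            linear = np.ravel_multi_index(tuple(s.voxels.T), s.shape)
            assert select_root(s) == tuple(s.voxels[np.argmin(linear)])


class TestConnectToRoot:
    def test_connected_input_unchanged_zero_cost(self):
        data = np.zeros((8, 4, 4), np.uint8)
        data[1:7, 2, 2] = 1
        raw = Volume(np.ones((8, 4, 4), np.float32), (1, 1, 1))
        out, report = connect_to_root(raw, Mask(data, (1, 1, 1)), (1, 2, 2), 1.0)
        assert np.array_equal(out.data, data)
        assert all(c.cost == 0.0 for c in report.components)

    def test_free_corridor_connects_blocked_corridor_prunes(self):
        binary = np.zeros((10, 5, 5), np.uint8)
        binary[1, 2, 2] = 1
        binary[8, 2, 2] = 1
        good = np.zeros((10, 5, 5), np.float32)
        good[:, 2, 2] = 1.0  # p=1 corridor: ~zero cost
        out, rep = connect_to_root(Volume(good, (1, 1, 1)),
                                   Mask(binary, (1, 1, 1)), (1, 2, 2), 0.5)
        assert n_components_26(out) == 1
        assert out.data[8, 2, 2] == 1
        bad = np.zeros((10, 5, 5), np.float32)  # p=0 everywhere: cost = mm
        out2, rep2 = connect_to_root(Volume(bad, (1, 1, 1)),
                                     Mask(binary, (1, 1, 1)), (1, 2, 2), 0.5)
        assert out2.data[8, 2, 2] == 0
        assert out2.data.sum() == 1

    def test_costs_match_exhaustive_relaxation_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            prob = rng.random((6, 6, 6)).astype(np.float32)
            binary = np.zeros((6, 6, 6), np.uint8)
            binary[0, 0, 0] = 1
            spots = rng.integers(0, 6, size=(3, 3))
            binary[tuple(spots.T)] = 1
            spacing = (1.0, 1.0, 2.0)
            out, rep = connect_to_root(
                Volume(prob, spacing), Mask(binary, spacing), (0, 0, 0), 1e9
            )
            dist = relaxation_shortest_paths(prob, spacing, np.argwhere(
                _root_component(binary)))
            from scipy import ndimage

            labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3)))
            for c in rep.components:
                if c.is_root:
                    continue
                expected = dist[labels == c.component_id].min()
                assert c.cost == pytest.approx(expected, abs=1e-4)

    def test_max_cost_zero_keeps_only_root_component(self):
        binary = np.zeros((8, 4, 4), np.uint8)
        binary[1, 2, 2] = 1
        binary[6, 2, 2] = 1
        raw = Volume(np.full((8, 4, 4), 0.5, np.float32), (1, 1, 1))
        out, rep = connect_to_root(raw, Mask(binary, (1, 1, 1)), (1, 2, 2), 0.0)
        assert out.data.sum() == 1 and out.data[1, 2, 2] == 1

    def test_kept_set_monotone_in_max_cost(self):
        rng = np.random.default_rng(3)
        prob = rng.random((7, 7, 7)).astype(np.float32)
        binary = (rng.random((7, 7, 7)) > 0.85).astype(np.uint8)
        binary[3, 3, 3] = 1
        raw = Volume(prob, (1, 1, 1))
        kept_sets = []
        for mc in (0.0, 0.5, 1.0, 2.0, 5.0):
            _, rep = connect_to_root(raw, Mask(binary, (1, 1, 1)), (3, 3, 3), mc)
            kept_sets.append(set(rep.kept_ids()))
        for a, b in zip(kept_sets, kept_sets[1:]):
            assert a <= b

    def test_output_always_single_component_with_root(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            prob = rng.random((8, 8, 8)).astype(np.float32)
            binary = (rng.random((8, 8, 8)) > 0.8).astype(np.uint8)
            binary[4, 4, 4] = 1
            out, _ = connect_to_root(
                Volume(prob, (1, 1, 2)), Mask(binary, (1, 1, 2)), (4, 4, 4),
                float(rng.random() * 5)
            )
            assert n_components_26(out) == 1
            assert out.data[4, 4, 4] == 1

    def test_root_outside_mask_rejected(self):
        raw = Volume(np.zeros((4, 4, 4), np.float32))
        with pytest.raises(SeedError):
            connect_to_root(raw, Mask(np.zeros((4, 4, 4), np.uint8)), (0, 0, 0), 1.0)

    def test_negative_max_cost_rejected(self):
        m = Mask(np.ones((4, 4, 4), np.uint8))
        with pytest.raises(ParameterError):
            connect_to_root(Volume(np.ones((4, 4, 4), np.float32)), m, (0, 0, 0), -1.0)


def _root_component(binary):
    from scipy import ndimage

    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3)))
    return labels == labels[0, 0, 0]


class TestPostprocess:
    def test_ground_truth_maps_reconstruct_tree(self, clean_case):
        fine, coarse = soft_maps(clean_case)
        mask, report = postprocess(fine, coarse, threshold=0.5, max_cost=10.0)
        from hepavess import evaluate_case

        r = evaluate_case(clean_case.vessel_mask, mask, clean_case.liver_mask)
        assert r.cl_f1 >= 0.95
        assert n_components_26(mask) == 1

    def test_all_zero_probabilities_rejected(self):
        zero = Volume(np.zeros((8, 8, 8), np.float32))
        with pytest.raises(EmptyInputError):
            postprocess(zero, None)

    def test_trunk_gap_small_cost_loses_branches_large_cost_restores(self, clean_case):
        # a probability gap between trunk and intrahepatic split: with a
        # small connection budget every branch beyond the gap is pruned,
        # raising the budget restores them
        from hepavess import cl_recall

        fine, coarse = soft_maps(clean_case)
        tree = clean_case.tree
        trunk_tip = tree.positions[3]
        x_gap = int(round(trunk_tip[0] / clean_case.image.spacing[0])) + 1
        gap_fine = Volume(fine.data.copy(), fine.spacing)
        gap_fine.data[x_gap : x_gap + 4] = 0.0
        gap_coarse = Volume(coarse.data.copy(), coarse.spacing)
        xg2 = int(round(trunk_tip[0] / 2.0))
        gap_coarse.data[xg2 : xg2 + 2] = 0.0

        small, _ = postprocess(gap_fine, gap_coarse, 0.5, max_cost=0.5)
        large, _ = postprocess(gap_fine, gap_coarse, 0.5, max_cost=20.0)
        r_small = cl_recall(clean_case.vessel_mask, small, 2.0, clean_case.liver_mask)
        r_large = cl_recall(clean_case.vessel_mask, large, 2.0, clean_case.liver_mask)
        assert r_small < 0.2
        assert r_large > 0.9
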