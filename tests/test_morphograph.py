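import numpy as np
import pytest

from micmac.artifact_filter import measure_cell
from micmac.morphograph import (
    FEATURE_NAMES,
    build_graph,
    compute_features,
    skeletonize,
)
from micmac.segmentation import LabelVolume

from .conftest import make_label_volume


def y_line_mask(shape=(3, 48, 48)):
    """One-voxel-wide Y: a trunk and two diagonal arms."""
    vol = np.zeros(shape, dtype=bool)
    vol[1, 24, 2:22] = True
    for i in range(14):
        vol[1, 24 + i + 1, 21 + i] = True
        vol[1, 24 - i - 1, 21 + i] = True
    return vol


class TestSkeletonize:
    def test_thin_line_unchanged(self):
        vol = np.zeros((3, 5, 30), dtype=bool)
        vol[1, 2, 2:28] = True
        skel = skeletonize(vol)
        np.testing.assert_array_equal(skel.voxels, vol)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            skeletonize(np.zeros((3, 3, 3), dtype=bool))

    def test_ball_skeleton_collapses_to_center(self):
        r = 8
        n = 2 * r + 3
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        c = n // 2
        ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
        skel = skeletonize(ball)
        coords = skel.coords
        assert len(coords) >= 1
        assert np.linalg.norm(coords - c, axis=1).max() <= 3.0

    def test_y_tube_skeleton_topology(self):
        """A rasterized Y tube must thin to 3 endpoints and one junction."""
        from scipy import ndimage as ndi

        seed = y_line_mask(shape=(9, 48, 48))
        seed = np.roll(seed, 3, axis=0)
        dist = ndi.distance_transform_edt(~seed)
        tube = dist <= 2.0
        skel = skeletonize(tube)
        g = build_graph(skel, voxel_size=(1, 1, 1), spur_min_length=3.0)
        assert g.n_endpoints == 3
        assert g.n_nodes == 4
        assert g.n_edges == 3


class TestBuildGraph:
    def test_straight_path(self):
        vol = np.zeros((3, 3, 30), dtype=bool)
        vol[1, 1, 2:28] = True  # 26 voxels, length 25 steps
        g = build_graph(skeletonize(vol), voxel_size=(1, 1, 1))
        assert (g.n_nodes, g.n_edges) == (2, 1)
        assert g.edge_lengths[0] == pytest.approx(25.0, abs=1.0)

    def test_y_skeleton_counts(self):
        g = build_graph(skeletonize(y_line_mask()), voxel_size=(1, 1, 1))
        assert (g.n_nodes, g.n_edges, g.n_endpoints) == (4, 3, 3)

    def test_single_voxel_degenerate(self):
        vol = np.zeros((3, 3, 3), dtype=bool)
        vol[1, 1, 1] = True
        g = build_graph(skeletonize(vol), voxel_size=(1, 1, 1))
        assert (g.n_nodes, g.n_edges) == (1, 0)

    def test_anisotropic_step_lengths(self):
        """A diagonal x-y step must contribute sqrt(dx^2+dy^2) µm."""
        vol = np.zeros((3, 12, 12), dtype=bool)
        for i in range(10):
            vol[1, i, i] = True
        g = build_graph(skeletonize(vol), voxel_size=(1.0, 0.3, 0.4))
        assert g.edge_lengths[0] == pytest.approx(9 * np.sqrt(0.3**2 + 0.4**2), rel=1e-6)

    def test_geodesic_at_least_euclidean(self):
        g = build_graph(skeletonize(y_line_mask()), voxel_size=(1, 1, 1))
        assert (g.edge_tortuosities() >= 1.0).all()


class TestFeatures:
    def test_y_graph_hand_computed(self):
        lv = make_label_volume(y_line_mask())
        cell = measure_cell(lv, 1)
        g = build_graph(skeletonize(lv.labels == 1), voxel_size=(1, 1, 1))
        f = compute_features(cell, g)
        assert f["avg_node_degree"] == pytest.approx(1.5)
        assert f["link_density"] == pytest.approx(0.5)
        assert f["s_metric"] == pytest.approx(9.0)
        assert f["ending_node_density"] * cell.volume == pytest.approx(3.0)

    def test_path_graph_hand_computed(self):
        vol = np.zeros((3, 3, 30), dtype=bool)
        vol[1, 1, 2:28] = True
        lv = make_label_volume(vol)
        cell = measure_cell(lv, 1)
        g = build_graph(skeletonize(vol), voxel_size=(1, 1, 1))
        f = compute_features(cell, g)
        assert f["avg_node_degree"] == pytest.approx(1.0)
        assert f["link_density"] == pytest.approx(1.0)
        assert f["s_metric"] == pytest.approx(1.0)
        assert f["mean_tortuosity"] == pytest.approx(1.0, abs=0.01)

    def test_ball_compactness_and_polarity(self, ball_mask):
        lv = make_label_volume(ball_mask)
        cell = measure_cell(lv, 1)
        g = build_graph(skeletonize(ball_mask), voxel_size=(1, 1, 1))
        f = compute_features(cell, g)
        assert 0.90 <= f["compactness"] <= 1.05
        assert f["polarity"] == pytest.approx(1 / 3, abs=0.02)
        assert f["bound1"] == pytest.approx(20.0, abs=2.0)

    def test_feature_vector_complete_and_finite(self, ball_mask):
        lv = make_label_volume(ball_mask)
        cell = measure_cell(lv, 1)
        g = build_graph(skeletonize(ball_mask), voxel_size=(1, 1, 1))
        f = compute_features(cell, g)
        assert list(f.keys()) == FEATURE_NAMES
        assert np.isfinite(list(f.values())).all()

    def test_scale_behavior(self):
        """Isotropic voxel rescaling: volume ~ s^3, lengths ~ s, unitless
        graph features unchanged."""
        vol = y_line_mask()
        s = 2.0
        f1 = self._features(vol, (1.0, 1.0, 1.0))
        f2 = self._features(vol, (s, s, s))
        assert f2["volume"] == pytest.approx(s**3 * f1["volume"])
        assert f2["total_skeleton_length"] == pytest.approx(s * f1["total_skeleton_length"])
        assert f2["bound1"] == pytest.approx(s * f1["bound1"])
        for name in ("compactness", "polarity", "link_density", "avg_node_degree", "s_metric"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-6)

    def test_rotation_robustness(self):
        """Axis-aligned 90° rotations must leave features within 5%."""
        from scipy import ndimage as ndi

        seed = y_line_mask(shape=(15, 48, 48))
        seed = np.roll(seed, 6, axis=0)
        dist = ndi.distance_transform_edt(~seed)
        mask = dist <= 2.0  # tubular Y with an unambiguous line skeleton
        base = self._features(mask, (1, 1, 1))
        for axes in ((1, 2), (0, 1), (0, 2)):
            rot = np.rot90(mask, k=1, axes=axes)
            f = self._features(rot, (1, 1, 1))
            for name in FEATURE_NAMES:
                if base[name] == 0:
                    assert abs(f[name]) < 1e-9
                else:
                    assert f[name] == pytest.approx(base[name], rel=0.05), name

    @staticmethod
    def _features(mask, voxel_size):
        lv = make_label_volume(mask, voxel_size)
        cell = measure_cell(lv, 1)
        g = build_graph(skeletonize(mask, voxel_size), voxel_size=voxel_size)
        return compute_features(cell, g)


class TestPlantedTreeOracle:
    def test_recovered_counts_match_planted_trees(self):
        """Rasterized random trees: N, E, endpoint counts recovered exactly,
        total length within 10% of planted."""
        from micmac.synthetic_data import CellSpec, SceneSpec, render_scene

        for seed in (0, 1, 2):
            spec = CellSpec(seed=seed)
            scene = SceneSpec(
                shape=(64, 160, 160), n_cells=1, noise_sd=0.0,
                background_gradient=0.0, psf_sigma=0.0, seed=seed,
            )
            stack, truth = render_scene(scene, [spec])
            skel = skeletonize(truth.labels == 1, scene.voxel_size)
            g = build_graph(skel, spur_min_length=2.0)
            tree = truth.trees[0]
            assert (g.n_nodes, g.n_edges, g.n_endpoints) == (
                tree.n_nodes, tree.n_edges, tree.n_endpoints,
            )
            assert g.total_length() == pytest.approx(sum(tree.edge_lengths), rel=0.10)
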