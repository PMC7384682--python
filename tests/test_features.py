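import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from reference import brute_complete_linkage_cut, labels_to_partition
from twocalm.features import (
    DimensionGrid,
    cluster_curvature,
    cluster_density,
    cluster_volume,
    feature_sweep,
    hierarchical_cut,
    make_grid,
)
from twocalm.localizations import LocalizationCloud


class TestGrid:
    def test_standard_sweep(self):
        g = make_grid([(2500, 2500, 2500)], size_min=10, step=10, size_max=1000)
        assert g.L == 99
        assert g.dims[0] == 20 and g.dims[-1] == 1000

    def test_small_explicit(self):
        g = make_grid([(100, 100, 100)], size_min=5, step=5, size_max=20)
        assert list(g.dims) == [10, 15, 20]

    def test_auto_cap_at_1000(self):
        g = make_grid([(4000, 4000, 4000), (4500, 4000, 4000)], size_min=10, step=10, size_max="auto")
        assert g.size_max == 1000  # 0.45 * 4000 = 1800 exceeds the cap

    def test_auto_uses_min_edge(self):
        g = make_grid([(2000, 900, 2000)], size_min=10, step=10, size_max="auto")
        assert g.size_max == pytest.approx(0.45 * 900, abs=10)

    def test_too_few_dims_rejected(self):
        with pytest.raises(ValueError):
            make_grid([(100, 100, 100)], size_min=10, step=50, size_max=30)


class TestHierarchicalCut:
    def test_collinear_example(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0]], float)
        cs = hierarchical_cut(pts, d=2.0)
        assert labels_to_partition(cs.labels) == {frozenset({0, 1}), frozenset({2})}

    def test_d_above_diameter_single_cluster(self, rng):
        pts = rng.uniform(0, 10, size=(40, 3))
        cs = hierarchical_cut(pts, d=100.0)
        assert cs.n_clusters == 1

    def test_d_below_min_distance_all_singletons(self, rng):
        pts = rng.uniform(0, 100, size=(30, 3))
        dmin = pdist(pts).min()
        cs = hierarchical_cut(pts, d=dmin * 0.9)
        assert cs.n_clusters == 30

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_agglomeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 13))
        pts = r.uniform(0, 10, size=(n, 3))
        d = float(r.uniform(1, 8))
        fast = labels_to_partition(hierarchical_cut(pts, d).labels)
        slow = brute_complete_linkage_cut(pts, d)
        assert fast == slow

    @pytest.mark.parametrize("seed", range(5))
    def test_diameter_guarantee(self, seed):
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 500, size=(300, 3))
        d = float(r.uniform(30, 200))
        cs = hierarchical_cut(pts, d)
        dm = squareform(pdist(pts))
        for k in range(cs.n_clusters):
            idx = np.flatnonzero(cs.labels == k)
            if len(idx) > 1:
                assert dm[np.ix_(idx, idx)].max() <= d + 1e-9

    def test_coarsening_in_d(self, rng):
        pts = rng.uniform(0, 200, size=(150, 3))
        prev = hierarchical_cut(pts, 20.0)
        for d in (40.0, 80.0, 160.0):
            cur = hierarchical_cut(pts, d)
            assert cur.n_clusters <= prev.n_clusters
            # every cluster of the finer partition lies inside one coarser cluster
            for k in range(prev.n_clusters):
                idx = np.flatnonzero(prev.labels == k)
                assert len(set(cur.labels[idx])) == 1
            prev = cur

    def test_order_invariance(self, rng):
        pts = rng.uniform(0, 50, size=(60, 3))
        perm = rng.permutation(60)
        p1 = labels_to_partition(hierarchical_cut(pts, 15.0).labels)
        l2 = hierarchical_cut(pts[perm], 15.0).labels
        back = np.empty(60, dtype=int)
        back[perm] = np.arange(60)
        assert p1 == labels_to_partition(l2[back])


class TestVolumes:
    def test_bullet_two_points(self):
        r = 3.0
        pts = np.array([[0, 0, 0], [2 * r, 0, 0]], float)
        assert cluster_volume(pts, "bullet") == pytest.approx(2 * (4 / 3) * np.pi * r**3)

    def test_hull_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert cluster_volume(pts, "hull") == pytest.approx(1 / 6)

    def test_box_unit_cube(self):
        pts = np.array([[x, y, z] for x in (0, 10) for y in (0, 10) for z in (0, 10)], float)
        assert cluster_volume(pts, "box") == pytest.approx(1000.0)

    def test_undefined_cases(self):
        single = np.array([[1.0, 2.0, 3.0]])
        assert cluster_volume(single, "bullet") is None
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        assert cluster_volume(tri, "hull") is None
        coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert cluster_volume(coplanar, "hull") is None

    def test_box_clamp_on_flat_cluster(self):
        flat = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        assert cluster_volume(flat, "box", box_clamp=5.0) == pytest.approx(10 * 10 * 5)

    def test_translation_and_rotation_invariance(self, rng):
        pts = rng.uniform(0, 20, size=(30, 3))
        R = Rotation.random(random_state=1).as_matrix()
        moved = pts @ R.T + [100.0, -50.0, 30.0]
        for mode in ("bullet", "hull"):
            assert cluster_volume(moved, mode) == pytest.approx(cluster_volume(pts, mode), rel=1e-9)
        shifted = pts + [5.0, 5.0, 5.0]
        assert cluster_volume(shifted, "box") == pytest.approx(cluster_volume(pts, "box"), rel=1e-12)


class TestDensityCurvature:
    def test_relative_density_arithmetic(self):
        assert cluster_density(10, 1000.0, 1e-3) == pytest.approx(10.0)
        assert cluster_density(5, 5000.0, 1e-3) == pytest.approx(1.0)

    def test_coplanar_and_collinear_are_flat(self, rng):
        xy = rng.uniform(0, 10, size=(50, 2))
        coplanar = np.column_stack([xy, np.zeros(50)])
        assert cluster_curvature(coplanar) == 0.0
        line = np.column_stack([np.linspace(0, 10, 20), np.zeros(20), np.zeros(20)])
        assert cluster_curvature(line) == 0.0

    def test_isotropic_gaussian_approaches_one_third(self):
        r = np.random.default_rng(2)
        pts = r.normal(0, 5.0, size=(10_000, 3))
        assert cluster_curvature(pts) == pytest.approx(1 / 3, abs=0.01)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(0, 3.0, size=(200, 3)) * [1.0, 0.5, 0.2]
        tau = cluster_curvature(pts)
        R = Rotation.random(random_state=5).as_matrix()
        moved = pts @ R.T + [1000.0, 2000.0, -500.0]
        assert cluster_curvature(moved) == pytest.approx(tau, abs=1e-9)
        assert 0.0 <= tau <= 1 / 3

    def test_too_small_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_curvature(np.zeros((3, 3)))


class TestFeatureSweep:
    def test_cluster_count_non_increasing(self, csr_cloud):
        g = DimensionGrid(size_min=10, step=60, L=8)
        sets = feature_sweep(csr_cloud, g)
        counts = [s.n_clusters for s in sets]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_two_blob_geometry(self, two_blob_cloud):
        # d between blob diameter (~70) and separation (600): exactly 2 clusters
        g = DimensionGrid(size_min=100, step=100, L=2)  # dims 200, 300
        sets = feature_sweep(two_blob_cloud, g)
        assert sets[0].n_clusters == 2 and sets[1].n_clusters == 2

    def test_bullet_volumes_match_per_cluster_reference(self, thomas_cloud):
        """The vectorised sweep agrees with the per-cluster volume function."""
        g = DimensionGrid(size_min=20, step=40, L=3)
        sets = feature_sweep(thomas_cloud, g)
        from twocalm.localizations import sample_global_density

        rho = sample_global_density(thomas_cloud)
        for s, d in zip(sets, g.dims):
            cs = hierarchical_cut(thomas_cloud.points, d)
            dens = []
            for k in range(cs.n_clusters):
                mem = thomas_cloud.points[cs.labels == k]
                v = cluster_volume(mem, "bullet")
                if v is not None and v > 0:
                    dens.append((len(mem) / v) / rho)
            assert np.allclose(np.sort(s.densities), np.sort(dens), rtol=1e-9)

    def test_exclusion_counting(self):
        # 5 far-apart points: all singletons, everything excluded
        pts = np.column_stack([np.arange(5) * 1000.0, np.zeros(5), np.zeros(5)])
        cloud = LocalizationCloud(pts)
        g = DimensionGrid(size_min=1, step=2, L=2)
        sets = feature_sweep(cloud, g, global_density=1e-9)
        assert sets[0].n_excluded_density == sets[0].n_clusters
        assert np.isnan(sets[0].av_density)
        assert len(sets[0].densities) == 0
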