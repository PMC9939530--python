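"""Great-circle centre tests, the dispersion statistic, and instance growing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crown_gf3d as cg
from crown_gf3d.segmentation import (
    CentreDetectionParams,
    Plane,
    SegmentationParams,
    _plane_basis,
)


def _leaf_pair(separation=0.05, seed=0):
    """Two flat-ish leaves side by side with per-point ground truth ids."""
    spec0 = cg.SyntheticLeafSpec(length=0.04, width=0.028, curl_amplitude=0.002,
                                 droop_angle=0.1, zenith=math.radians(70))
    spec1 = cg.SyntheticLeafSpec(length=0.04, width=0.028, curl_amplitude=0.003,
                                 droop_angle=0.15, zenith=math.radians(70),
                                 attachment_point=(separation, 0.0, 0.0))
    a, _ = cg.generate_leaf(spec0, 6e5, 0.0004, seed=seed)
    b, _ = cg.generate_leaf(spec1, 6e5, 0.0004, seed=seed + 1)
    coords = np.vstack([a.coords, b.coords])
    truth = np.r_[np.zeros(len(a), dtype=int), np.ones(len(b), dtype=int)]
    return cg.PointCloud(coords=coords), truth


class TestGreatCirclePlane:
    def test_exact_plane_through_point(self, rng):
        n = np.array([0.0, 0.0, 1.0])
        pts = np.column_stack([rng.normal(size=(20, 2)), np.zeros(20)])
        cloud = cg.PointCloud(coords=np.vstack([[0.0, 0.0, 0.0], pts]))
        plane, mean_d = cg.fit_great_circle_plane(cloud, 0, np.arange(1, 21))
        assert mean_d == pytest.approx(0.0, abs=1e-12)
        assert abs(plane.normal @ n) == pytest.approx(1.0)
        assert plane.D == pytest.approx(0.0, abs=1e-12)

    def test_mean_distance_matches_direct_formula(self, rng):
        coords = rng.normal(size=(40, 3)) * [1.0, 1.0, 0.02]
        cloud = cg.PointCloud(coords=coords)
        plane, mean_d = cg.fit_great_circle_plane(cloud, 0, np.arange(1, 40))
        A, B, C, D = plane.A, plane.B, plane.C, plane.D
        oracle = np.mean([abs(A * x + B * y + C * z - D) for x, y, z in coords[1:]])
        assert mean_d == pytest.approx(oracle, abs=1e-12)

    def test_collinear_neighbours_rejected(self):
        cloud = cg.PointCloud(coords=np.outer(np.arange(8), [1.0, 0, 0]))
        with pytest.raises(ValueError, match="collinear"):
            cg.fit_great_circle_plane(cloud, 0, np.arange(1, 8))


class TestCentreNormal:
    def test_exact_plane_recovers_normal(self, rng):
        nb = np.column_stack([rng.normal(size=(30, 2)), np.zeros(30)])
        n = cg.estimate_centre_normal(np.zeros(3), nb)
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-12)

    def test_unit_norm_and_sign_convention(self, rng):
        nb = rng.normal(size=(25, 3)) * [1, 1, 0.05]
        n = cg.estimate_centre_normal(np.zeros(3), nb)
        assert np.linalg.norm(n) == pytest.approx(1.0)
        assert n[2] >= 0

    def test_outlier_downweighted_vs_plain_fit(self, rng):
        nb = np.column_stack([rng.normal(size=(60, 2)), rng.normal(0, 1e-4, 60)])
        nb = np.vstack([nb, [[0.4, 0.0, 2.0]]])  # gross off-plane outlier
        robust = cg.estimate_centre_normal(np.zeros(3), nb)
        M = nb.T @ nb
        plain = np.linalg.eigh(M)[1][:, 0]
        plain = plain * np.sign(plain[2])
        ang = lambda v: math.acos(min(1.0, abs(float(v @ [0, 0, 1.0]))))
        assert ang(robust) < ang(plain)


class TestNormalConsistency:
    def test_identical_normals_give_zero(self):
        n = np.array([0, 0, 1.0])
        assert cg.normal_consistency(n, np.tile(n, (5, 1))) == 0.0

    def test_orthogonal_normals_give_half_pi(self):
        n = np.array([0, 0, 1.0])
        nb = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        assert cg.normal_consistency(n, nb) == pytest.approx(math.pi / 2)

    def test_matches_direct_summation(self, rng):
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        nb = rng.normal(size=(30, 3))
        nb /= np.linalg.norm(nb, axis=1)[:, None]
        oracle = np.mean([math.acos(min(1.0, abs(float(v @ n)))) for v in nb])
        assert cg.normal_consistency(n, nb) == pytest.approx(oracle, abs=1e-12)

    def test_empty_neighbours_rejected(self):
        with pytest.raises(ValueError):
            cg.normal_consistency(np.array([0, 0, 1.0]), np.empty((0, 3)))


class TestProjection:
    def test_point_on_plane_maps_to_itself(self):
        plane = Plane(0.0, 0.0, 1.0, 2.0)
        np.testing.assert_allclose(
            cg.project_points_to_plane([[1.0, 5.0, 2.0]], plane)[0], [1, 5, 2]
        )

    def test_z_plane_drops_height(self):
        plane = Plane(0.0, 0.0, 1.0, 0.0)
        np.testing.assert_allclose(
            cg.project_points_to_plane([[1.0, 2.0, 5.0]], plane)[0], [1, 2, 0]
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_on_plane(self, seed):
        r = np.random.default_rng(seed)
        n = r.normal(size=3)
        n /= np.linalg.norm(n)
        plane = Plane(*n, float(r.normal()))
        pts = r.normal(scale=3.0, size=(15, 3))
        proj = cg.project_points_to_plane(pts, plane)
        assert np.abs(proj @ n - plane.D).max() <= 1e-9
        np.testing.assert_allclose(
            cg.project_points_to_plane(proj, plane), proj, atol=1e-9
        )
        # distance-reducing: |p' - p| equals the point-to-plane distance
        np.testing.assert_allclose(
            np.linalg.norm(proj - pts, axis=1), np.abs(pts @ n - plane.D), atol=1e-9
        )


class TestAngularUniformity:
    plane = Plane(0.0, 0.0, 1.0, 0.0)

    @staticmethod
    def _cell_points(R=1.0):
        """One point exactly inside each of the 40 cells (z = 0 plane)."""
        e1, e2 = _plane_basis(np.array([0, 0, 1.0]))
        pts = []
        for d in range(5):
            r = R * math.sqrt((d + 0.5) / 5.0)
            for s in range(8):
                phi = (s + 0.5) * math.pi / 4.0
                pts.append(r * math.cos(phi) * e1 + r * math.sin(phi) * e2)
        return np.array(pts)

    def test_equal_cell_counts_give_zero(self):
        pts = self._cell_points()
        assert cg.angular_uniformity(pts, np.zeros(3), self.plane, 1.0) == 0.0

    def test_forty_points_in_one_cell_give_39(self):
        pts = np.tile(self._cell_points()[0], (40, 1))
        sigma = cg.angular_uniformity(pts, np.zeros(3), self.plane, 1.0)
        assert sigma == pytest.approx(39.0, abs=1e-12)

    def test_uniform_disk_dispersion_near_one(self, rng):
        r = np.sqrt(rng.uniform(0, 1, 4000))
        phi = rng.uniform(0, 2 * math.pi, 4000)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(4000)])
        sigma = cg.angular_uniformity(pts, np.zeros(3), self.plane, 1.0)
        assert sigma == pytest.approx(1.0, abs=0.35)

    def test_invariant_under_45_degree_rotations(self, rng):
        r = np.sqrt(rng.uniform(0, 1, 500))
        phi = rng.uniform(0, 2 * math.pi, 500)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(500)])
        base = cg.angular_uniformity(pts, np.zeros(3), self.plane, 1.0)
        for mult in (1, 3, 6):
            a = mult * math.pi / 4.0
            R = np.array([[math.cos(a), -math.sin(a), 0],
                          [math.sin(a), math.cos(a), 0], [0, 0, 1.0]])
            rot = cg.angular_uniformity(pts @ R.T, np.zeros(3), self.plane, 1.0)
            assert rot == pytest.approx(base, abs=1e-12)

    def test_empty_disk_is_infinite(self):
        assert math.isinf(
            cg.angular_uniformity(np.empty((0, 3)), np.zeros(3), self.plane, 1.0)
        )

    def test_half_disk_rim_neighbourhood_fails_threshold(self, rng):
        # a point on the leaf rim sees only half the great circle
        r = np.sqrt(rng.uniform(0, 1, 2000))
        phi = rng.uniform(0, math.pi, 2000)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(2000)])
        sigma = cg.angular_uniformity(pts, np.zeros(3), self.plane, 1.0)
        assert sigma > 2.0


class TestDetectCentres:
    def test_empty_cloud(self):
        out = cg.detect_leaf_centres(
            cg.PointCloud(coords=np.empty((0, 3))), CentreDetectionParams()
        )
        assert len(out) == 0

    def test_single_flat_leaf_centre_near_centroid(self, flat_leaf_cloud):
        cloud, _, centroid, spec = flat_leaf_cloud
        params = CentreDetectionParams(radius=0.75 * spec.width / 2.0)
        centres = cg.detect_leaf_centres(cloud, params)
        assert len(centres) >= 1
        d = np.linalg.norm(cloud.coords[centres] - centroid, axis=1)
        assert (d <= params.radius / 2.0).all()


class TestSegmentLeaves:
    params = SegmentationParams(geodesic_cap=0.08, min_leaf_points=40)

    def test_two_separated_leaves_yield_two_instances(self):
        cloud, truth = _leaf_pair()
        centres = cg.detect_leaf_centres(
            cloud, CentreDetectionParams(radius=0.0105)
        )
        seg = cg.segment_leaves(cloud, centres, self.params)
        ids = seg.leaf_id
        assert len(np.unique(ids[ids >= 0])) == 2
        # label agreement up to permutation
        agree = 0
        for inst in np.unique(ids[ids >= 0]):
            m = ids == inst
            agree += max((truth[m] == 0).sum(), (truth[m] == 1).sum())
        assert agree / (ids >= 0).sum() >= 0.95

    def test_single_leaf_single_instance(self, flat_leaf_cloud):
        cloud, _, _, spec = flat_leaf_cloud
        centres = cg.detect_leaf_centres(
            cloud, CentreDetectionParams(radius=0.75 * spec.width / 2)
        )
        seg = cg.segment_leaves(cloud, centres, self.params)
        ids = seg.leaf_id[seg.leaf_id >= 0]
        assert len(np.unique(ids)) == 1

    def test_dbscan_fallback_without_centres(self):
        cloud, _ = _leaf_pair()
        seg = cg.segment_leaves(cloud, np.empty(0, dtype=int), self.params)
        ids = seg.leaf_id
        assert len(np.unique(ids[ids >= 0])) == 2

    def test_every_point_gets_exactly_one_id(self):
        cloud, _ = _leaf_pair()
        centres = cg.detect_leaf_centres(cloud, CentreDetectionParams(radius=0.0105))
        seg = cg.segment_leaves(cloud, centres, self.params)
        assert seg.leaf_id.shape == (len(cloud),)
        assert (seg.leaf_id >= -1).all()

    def test_empty_cloud(self):
        seg = cg.segment_leaves(cg.PointCloud(coords=np.empty((0, 3))),
                                np.empty(0, dtype=int), self.params)
        assert len(seg) == 0

    def test_instance_count_tracks_true_leaf_count(self, pipeline_runs):
        counts = np.array([rep.n_leaves for rep in pipeline_runs.values()])
        assert abs(counts.mean() - 50) / 50 <= 0.10
        assert (np.abs(counts - 50) / 50 <= 0.20).all()
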