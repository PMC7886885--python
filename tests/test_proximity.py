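import numpy as np
import pytest

from fibmorph.mesh_core import TriangleMesh
from fibmorph.morphometrics import surface_area
from fibmorph.proximity import (
    DistanceField,
    condition_change,
    contact_report,
    proximity_surface,
    vertex_areas,
    vertex_to_mesh_distances,
    vertex_to_mesh_distances_bruteforce,
)

from conftest import icosphere


def random_mesh(n_vertices, n_faces, seed, scale=1000.0):
    rng = np.random.default_rng(seed)
    v = rng.uniform(-scale, scale, (n_vertices, 3))
    f = rng.integers(0, n_vertices, (n_faces, 3))
    ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    return TriangleMesh(v, f[ok])


def cap_fraction_pct(r, d, t):
    """Analytic spherical-cap fraction of the source sphere surface whose
    points lie within t of a second sphere (same radius r, centres d apart)."""
    ct = (d * d + r * r - (r + t) ** 2) / (2 * d * r)
    if ct > 1:
        return 0.0
    return 100.0 * (1.0 - ct) / 2.0


class TestDistances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_accelerated_equals_bruteforce(self, seed):
        src = random_mesh(60, 50, seed)
        tgt = random_mesh(60, 50, seed + 100)
        fast = vertex_to_mesh_distances(src, tgt).distances
        slow = vertex_to_mesh_distances_bruteforce(src, tgt).distances
        assert np.allclose(fast, slow, rtol=0, atol=1e-9)

    def test_vertex_on_surface_distance_zero(self):
        tgt, _, _ = icosphere(1000.0, 2)
        src = TriangleMesh(tgt.vertices[:5], np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4]]))
        d = vertex_to_mesh_distances(src, tgt).distances
        assert d.min() == pytest.approx(0.0, abs=1e-9)

    def test_concentric_spheres_constant_shell(self):
        outer, _, _ = icosphere(1000.0, 4)
        inner, _, _ = icosphere(900.0, 4)
        d = vertex_to_mesh_distances(outer, inner).distances
        # chord sagitta of the inner icosphere bounds the discretisation
        assert d.min() > 99.0
        assert d.max() < 101.0
        assert np.all(np.abs(d - 100.0) < 1.5)

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            DistanceField(np.array([-1.0]), "a", "b")


class TestProximitySurface:
    def test_vertex_area_partition_sums_to_total(self):
        mesh, _, _ = icosphere(1234.0, 3)
        assert vertex_areas(mesh).sum() == pytest.approx(surface_area(mesh), rel=1e-9)

    def test_threshold_extremes(self):
        src, _, _ = icosphere(1000.0, 3)
        tgt, _, _ = icosphere(1000.0, 3, center=(2500, 0, 0))
        field = vertex_to_mesh_distances(src, tgt)
        below = proximity_surface(src, field, field.distances.min() * 0.5)
        assert below.proximity_area_um2 == 0.0
        assert below.fraction_pct == 0.0
        above = proximity_surface(src, field, field.distances.max() + 1.0)
        assert above.fraction_pct == pytest.approx(100.0, rel=1e-9)
        assert above.proximity_area_um2 == pytest.approx(above.source_total_area_um2, rel=1e-9)

    def test_monotone_in_threshold(self):
        src, _, _ = icosphere(1000.0, 3)
        tgt, _, _ = icosphere(1000.0, 3, center=(2100, 0, 0))
        field = vertex_to_mesh_distances(src, tgt)
        areas = [
            proximity_surface(src, field, t).proximity_area_um2
            for t in np.linspace(0, 600, 13)
        ]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))

    def test_two_sphere_cap_oracle(self):
        r, gap = 1000.0, 50.0
        d = 2 * r + gap
        src, _, _ = icosphere(r, 4)
        tgt, _, _ = icosphere(r, 4, center=(d, 0, 0))
        field = vertex_to_mesh_distances(src, tgt)
        res = proximity_surface(src, field, 90.0)
        assert res.fraction_pct == pytest.approx(cap_fraction_pct(r, d, 90.0), abs=0.2)
        # below the 50 nm gap nothing can be within 30 nm
        assert proximity_surface(src, field, 30.0).fraction_pct == 0.0

    def test_face_mode_stricter_than_vertex_mode(self):
        src, _, _ = icosphere(1000.0, 3)
        tgt, _, _ = icosphere(1000.0, 3, center=(2100, 0, 0))
        field = vertex_to_mesh_distances(src, tgt)
        v = proximity_surface(src, field, 200.0, area_mode="vertex")
        f = proximity_surface(src, field, 200.0, area_mode="face")
        assert f.proximity_area_um2 <= v.proximity_area_um2

    def test_negative_threshold_rejected(self):
        src, _, _ = icosphere(1000.0, 2)
        field = DistanceField(np.ones(src.n_vertices), "a", "b")
        with pytest.raises(ValueError):
            proximity_surface(src, field, -1.0)

    def test_joint_rigid_motion_invariance(self):
        from test_morphometrics import rotation

        src, _, _ = icosphere(1000.0, 3)
        tgt, _, _ = icosphere(1000.0, 3, center=(2080, 0, 0))
        field = vertex_to_mesh_distances(src, tgt)
        base = proximity_surface(src, field, 120.0)
        R = rotation([3, 1, 2], 0.7)
        t = np.array([5e4, -2e4, 1e4])
        src2 = src.with_geometry(src.vertices @ R.T + t, src.faces)
        tgt2 = tgt.with_geometry(tgt.vertices @ R.T + t, tgt.faces)
        moved = proximity_surface(src2, vertex_to_mesh_distances(src2, tgt2), 120.0)
        assert moved.fraction_pct == pytest.approx(base.fraction_pct, rel=1e-6)
        assert moved.proximity_area_um2 == pytest.approx(base.proximity_area_um2, rel=1e-6)


class TestContactReport:
    def test_far_mitochondrion_zero_at_both_thresholds(self):
        plastid, _, _ = icosphere(1000.0, 3)
        mito, _, _ = icosphere(300.0, 3, center=(5000, 0, 0))
        results = contact_report(plastid, [mito])
        assert [r.threshold_nm for r in results] == [30.0, 90.0]
        assert all(r.fraction_pct == 0.0 for r in results)

    def test_two_mitochondria_distinct_patches(self):
        plastid, _, _ = icosphere(1000.0, 4)
        near, _, _ = icosphere(200.0, 3, center=(1220, 0, 0))   # 20 nm gap
        far, _, _ = icosphere(200.0, 3, center=(0, 1270, 0))    # 70 nm gap
        r30, r90 = contact_report(plastid, [near, far])
        assert 0 < r30.fraction_pct < r90.fraction_pct
        # the 90 nm surface must cover both patches
        assert r90.n_vertices_within > r30.n_vertices_within

    def test_requires_a_mitochondrion(self):
        plastid, _, _ = icosphere(1000.0, 2)
        with pytest.raises(ValueError):
            contact_report(plastid, [])


class TestConditionChange:
    @staticmethod
    def result(frac, threshold=30.0):
        from fibmorph.proximity import ProximityResult

        return ProximityResult(threshold, frac, 100.0, frac, 1, 10)

    def test_plus_25_percent(self):
        out = condition_change(self.result(4.0), self.result(5.0))
        assert out["percent_change"] == pytest.approx(25.0)
        assert not out["zero_baseline"]

    def test_identical_zero_change(self):
        out = condition_change(self.result(3.3), self.result(3.3))
        assert out["percent_change"] == pytest.approx(0.0)

    def test_zero_baseline_flagged_absent(self):
        out = condition_change(self.result(0.0), self.result(2.0))
        assert out["percent_change"] is None
        assert out["zero_baseline"]

    def test_mismatched_thresholds_rejected(self):
        with pytest.raises(ValueError):
            condition_change(self.result(1.0, 30.0), self.result(1.0, 90.0))
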