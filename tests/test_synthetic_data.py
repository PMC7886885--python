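import numpy as np
import pytest
import trimesh as _trimesh

from fibmorph.mesh_core import validate
from fibmorph.morphometrics import enclosed_volume, surface_area
from fibmorph.proximity import vertex_to_mesh_distances
from fibmorph.reconstruct import labels_to_mesh
from fibmorph.stack_preprocess import segment_threshold
from fibmorph.synthetic_data import (
    Capsule,
    Ellipsoid,
    OrganelleSpec,
    Sphere,
    SyntheticCellSpec,
    default_class_ranges,
    default_study_specs,
    high_occupancy_cell,
    make_cell_labels,
    make_parametric_mesh,
    render_intensity_stack,
    standard_cell,
    surface_gap,
)


class TestShapes:
    def test_sphere_analytics(self):
        s = Sphere((0, 0, 0), 1000.0)
        assert s.volume() == pytest.approx(4 / 3 * np.pi * 1e9)
        assert s.surface() == pytest.approx(4 * np.pi * 1e6)

    def test_degenerate_ellipsoid_equals_sphere(self):
        e = Ellipsoid((0, 0, 0), (700.0, 700.0, 700.0))
        s = Sphere((0, 0, 0), 700.0)
        assert e.volume() == pytest.approx(s.volume(), rel=1e-9)
        assert e.surface() == pytest.approx(s.surface(), rel=1e-6)

    @pytest.mark.parametrize("radii", [(900.0, 600.0, 300.0),   # triaxial
                                       (900.0, 900.0, 300.0),   # oblate
                                       (900.0, 300.0, 300.0)])  # prolate
    def test_ellipsoid_surface_against_fine_mesh(self, radii):
        e = Ellipsoid((0, 0, 0), radii)
        tm = _trimesh.creation.icosphere(subdivisions=6, radius=1.0)
        tm.apply_scale(radii)
        assert e.surface() == pytest.approx(tm.area, rel=0.002)

    def test_capsule_analytics_against_trimesh(self):
        c = Capsule((0, 0, 0), (0, 0, 1), 200.0, 500.0)
        tm = _trimesh.creation.capsule(height=1000.0, radius=200.0, count=(64, 64))
        assert c.volume() == pytest.approx(tm.volume, rel=0.01)
        assert c.surface() == pytest.approx(tm.area, rel=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Sphere((0, 0, 0), -1.0)
        with pytest.raises(ValueError):
            Ellipsoid((0, 0, 0), (1.0, -2.0, 3.0))
        with pytest.raises(ValueError):
            Capsule((0, 0, 0), (0, 0, 0), 1.0, 1.0)

    def test_surface_gap_sphere_pair(self):
        a = Sphere((0, 0, 0), 100.0)
        b = Sphere((260.0, 0, 0), 100.0)
        assert surface_gap(a, b) == pytest.approx(60.0)

    def test_surface_gap_sphere_capsule(self):
        s = Sphere((0, 500.0, 0), 100.0)
        c = Capsule((0, 0, 0), (1, 0, 0), 150.0, 400.0)
        assert surface_gap(s, c) == pytest.approx(250.0)

    def test_surface_gap_ellipsoid_unsupported(self):
        with pytest.raises(NotImplementedError):
            surface_gap(Sphere((0, 0, 0), 1.0), Ellipsoid((5, 0, 0), (1, 1, 1)))


class TestParametricMesh:
    def test_sphere_oracle(self):
        mesh, surf, vol = make_parametric_mesh(
            OrganelleSpec("plastid", Sphere((0, 0, 0), 1000.0)), subdivision=4
        )
        rep = validate(mesh)
        assert rep.is_watertight and rep.is_consistently_oriented
        assert enclosed_volume(mesh) == pytest.approx(vol, rel=0.01)
        assert surface_area(mesh) == pytest.approx(surf, rel=0.005)

    def test_subdivision0_icosahedron_inscribed(self):
        mesh, _, vol = make_parametric_mesh(
            OrganelleSpec("other", Sphere((0, 0, 0), 500.0)), subdivision=0
        )
        assert enclosed_volume(mesh) < vol  # convex inscribed polyhedron

    def test_capsule_mesh_watertight_with_volume(self):
        spec = OrganelleSpec("mitochondrion", Capsule((10, 20, 30), (1, 1, 0), 150.0, 400.0))
        mesh, surf, vol = make_parametric_mesh(spec, subdivision=4)
        assert validate(mesh).is_watertight
        assert enclosed_volume(mesh) == pytest.approx(vol, rel=0.01)
        assert surface_area(mesh) == pytest.approx(surf, rel=0.01)

    def test_negative_subdivision_rejected(self):
        with pytest.raises(ValueError):
            make_parametric_mesh(OrganelleSpec("other", Sphere((0, 0, 0), 1.0)), -1)


class TestVoxelization:
    def test_plastid_cell_volume_ratio(self):
        cell = OrganelleSpec("cell", Sphere((0, 0, 0), 2000.0), 80.0)
        plastid = OrganelleSpec("plastid", Sphere((0, 0, 0), 1240.0), 200.0)
        spec = SyntheticCellSpec(cell=cell, organelles=[plastid], voxel_size_nm=40.0)
        labels, manifest = make_cell_labels(spec)
        comp = {c["compartment"]: c for c in manifest["compartments"]}
        ratio = comp["plastid"]["voxel_volume_nm3"] / (
            comp["cell"]["voxel_volume_nm3"]
        )
        assert ratio == pytest.approx((1240 / 2000) ** 3, rel=0.02)

    def test_empty_organelle_list(self):
        cell = OrganelleSpec("cell", Sphere((0, 0, 0), 500.0), 80.0)
        spec = SyntheticCellSpec(cell=cell, organelles=[], voxel_size_nm=20.0)
        labels, manifest = make_cell_labels(spec)
        assert set(np.unique(labels.labels)) == {0, 1}

    def test_escaping_organelle_rejected(self):
        cell = OrganelleSpec("cell", Sphere((0, 0, 0), 500.0), 80.0)
        out = OrganelleSpec("nucleus", Sphere((450.0, 0, 0), 200.0), 120.0)
        spec = SyntheticCellSpec(cell=cell, organelles=[out], voxel_size_nm=20.0)
        with pytest.raises(ValueError, match="escapes"):
            make_cell_labels(spec)

    def test_unnested_overlap_rejected(self):
        cell = OrganelleSpec("cell", Sphere((0, 0, 0), 500.0), 80.0)
        a = OrganelleSpec("nucleus", Sphere((-100.0, 0, 0), 150.0), 120.0)
        b = OrganelleSpec("mitochondrion", Sphere((100.0, 0, 0), 150.0), 160.0)
        spec = SyntheticCellSpec(cell=cell, organelles=[a, b], voxel_size_nm=20.0)
        with pytest.raises(ValueError, match="overlap"):
            make_cell_labels(spec)

    def test_unrealised_gap_pair_rejected(self):
        cell = OrganelleSpec("cell", Sphere((0, 0, 0), 500.0), 80.0)
        a = OrganelleSpec("plastid", Sphere((-200.0, 0, 0), 100.0), 200.0)
        b = OrganelleSpec("mitochondrion", Sphere((200.0, 0, 0), 100.0), 160.0)
        with pytest.raises(ValueError, match="gap"):
            SyntheticCellSpec(
                cell=cell, organelles=[a, b], voxel_size_nm=20.0,
                gap_pairs=[("plastid", "mitochondrion", 50.0)],
            )

    def test_prescribed_gap_recovered_within_voxel(self):
        spec = standard_cell(
            cell_radius_nm=800.0, voxel_size_nm=16.0, gap_nm=50.0, seed=0
        )
        labels, manifest = make_cell_labels(spec)
        value_of = {c["compartment"]: c["label"] for c in manifest["compartments"]}
        plastid = labels_to_mesh(labels, value_of["plastid"],
                                 include_labels=(value_of["pyrenoid"],))
        mito = labels_to_mesh(labels, value_of["mitochondrion"])
        measured = vertex_to_mesh_distances(mito, plastid).distances.min()
        assert abs(measured - 50.0) <= 16.0

    def test_voxel_volume_converges_to_analytic(self):
        errors = []
        for voxel in (64.0, 32.0, 16.0):
            cell = OrganelleSpec("cell", Sphere((0, 0, 0), 1000.0), 80.0)
            spec = SyntheticCellSpec(cell=cell, organelles=[], voxel_size_nm=voxel)
            _, manifest = make_cell_labels(spec)
            c = manifest["compartments"][0]
            errors.append(abs(c["voxel_volume_nm3"] / c["analytic_volume_nm3"] - 1))
        assert errors[2] < errors[0]
        assert errors[2] < 0.01


class TestRender:
    def test_lossless_roundtrip_without_noise_or_drift(self):
        spec = standard_cell(400.0, 10.0, 40.0, seed=4)
        spec.noise_sigma = 0.0
        spec.max_drift_step_px = 0
        labels, _ = make_cell_labels(spec)
        stack, trace = render_intensity_stack(labels, spec)
        assert not trace.shifts.any()
        seg = segment_threshold(stack, default_class_ranges(spec))
        for value, name in seg.label_map.items():
            orig_value = [v for v, n in labels.label_map.items() if n == name][0]
            assert np.array_equal(seg.labels == value, labels.labels == orig_value)

    def test_gaussian_tail_misclassification_bound(self):
        # two levels 50/200, sigma 20, threshold at 125: the 3.75-sigma
        # tail bounds the error rate below 0.1%
        cell = OrganelleSpec("cell", Sphere((0, 0, 0), 600.0), 200.0)
        spec = SyntheticCellSpec(
            cell=cell, organelles=[], voxel_size_nm=15.0,
            noise_sigma=20.0, max_drift_step_px=0, background_intensity=50.0,
            texture_amplitude=0.0, seed=9,
        )
        labels, _ = make_cell_labels(spec)
        stack, _ = render_intensity_stack(labels, spec)
        seg = (stack.data >= 125.0).astype(np.int32)
        miscls = (seg != (labels.labels > 0)).mean()
        assert miscls < 0.001

    def test_determinism_given_seed(self):
        spec = standard_cell(300.0, 10.0, 40.0, seed=123)
        labels, _ = make_cell_labels(spec)
        a, ta = render_intensity_stack(labels, spec)
        b, tb = render_intensity_stack(labels, spec)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ta.shifts, tb.shifts)


class TestStudySpecs:
    def test_default_study_shape(self):
        specs = default_study_specs(seed=0)
        assert len(specs) == 18  # 3 cells x 6 presets
        tags = {s.tag for s in specs}
        assert len(tags) == 6
        for s in specs:
            assert s.gap_pairs  # every cell prescribes a plastid-mito gap

    def test_study_determinism(self):
        a = default_study_specs(seed=5)
        b = default_study_specs(seed=5)
        assert all(
            x.cell.shape.radius == y.cell.shape.radius
            and x.organelles[3].shape.radius == y.organelles[3].shape.radius
            for x, y in zip(a, b)
        )

    def test_high_occupancy_fractions(self):
        spec = high_occupancy_cell()
        cell_vol = spec.cell.shape.volume()
        fractions = {
            o.compartment: o.shape.volume() / cell_vol for o in spec.organelles
        }
        assert fractions["plastid"] == pytest.approx(0.30, abs=0.002)
        assert fractions["nucleus"] == pytest.approx(0.10, abs=0.002)
        assert fractions["mitochondrion"] == pytest.approx(0.04, abs=0.001)
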