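import numpy as np
import pytest

from fibmorph.stack_preprocess import (
    ImageStack,
    LabelVolume,
    ShiftTrace,
    align_stack,
    crop_roi,
    denoise,
    read_labels,
    read_stack,
    segment_threshold,
    write_labels,
    write_stack,
)
from fibmorph.synthetic_data import (
    make_cell_labels,
    render_intensity_stack,
    standard_cell,
)

VS = (8.0, 8.0, 8.0)


def flat_stack(shape=(4, 32, 32), value=100.0):
    return ImageStack(np.full(shape, value), VS)


class TestCrop:
    def test_cube_crop(self):
        stack = ImageStack(np.arange(100**3, dtype=np.float32).reshape(100, 100, 100), VS)
        out = crop_roi(stack, ((10, 20), (10, 20), (10, 20)))
        assert out.shape == (10, 10, 10)
        assert out.voxel_size == VS
        assert out.data[0, 0, 0] == stack.data[10, 10, 10]

    def test_full_range_identity(self):
        stack = flat_stack()
        out = crop_roi(stack, ((0, 4), (0, 32), (0, 32)))
        assert np.array_equal(out.data, stack.data)

    @pytest.mark.parametrize("bounds", [((2, 2), (0, 32), (0, 32)),
                                        ((3, 1), (0, 32), (0, 32)),
                                        ((0, 5), (0, 32), (0, 32))])
    def test_bad_bounds_rejected(self, bounds):
        with pytest.raises(ValueError):
            crop_roi(flat_stack(), bounds)


class TestAlign:
    @staticmethod
    def textured(nz=8, n=48, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 255, (n, n))
        return np.broadcast_to(base, (nz, n, n)).copy()

    def test_known_drift_recovered_exactly(self):
        data = self.textured()
        shifts = np.array([[0, 0], [1, -2], [3, 0], [2, 2], [-1, 1], [0, -3], [2, -1], [1, 1]])
        drifted = data.copy()
        for k, (dy, dx) in enumerate(shifts):
            drifted[k] = np.roll(np.roll(data[k], dy, axis=0), dx, axis=1)
        stack = ImageStack(drifted, VS)
        _, trace = align_stack(stack, search_radius=4)
        assert np.array_equal(trace.shifts, -shifts)

    def test_already_aligned_all_zero(self):
        stack = ImageStack(self.textured(), VS)
        _, trace = align_stack(stack, search_radius=3)
        assert not trace.shifts.any()

    def test_two_identical_slices_zero_shift(self):
        stack = ImageStack(self.textured(nz=2), VS)
        aligned, trace = align_stack(stack, search_radius=3)
        assert tuple(trace.shifts[1]) == (0, 0)
        assert np.array_equal(aligned.data[0], aligned.data[1])

    def test_constant_slice_warns_zero_shift(self):
        data = self.textured(nz=3)
        data[1] = 42.0
        with pytest.warns(UserWarning, match="zero variance"):
            _, trace = align_stack(ImageStack(data, VS), search_radius=3)
        assert tuple(trace.shifts[1]) == (0, 0)

    def test_excessive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            align_stack(ImageStack(self.textured(n=16), VS), search_radius=16)

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            align_stack(flat_stack(shape=(1, 16, 16)), search_radius=2)

    def test_rendered_drift_negated_at_zero_noise(self):
        spec = standard_cell(400.0, 8.0, 32.0, seed=11)
        spec.noise_sigma = 0.0
        labels, _ = make_cell_labels(spec, margin_voxels=12)
        stack, true_trace = render_intensity_stack(labels, spec)
        _, rec = align_stack(stack, search_radius=9)
        assert np.array_equal(rec.shifts, -true_trace.shifts)

    def test_voxel_size_metadata_preserved(self):
        stack = ImageStack(self.textured(), (4.0, 8.0, 8.0))
        aligned, _ = align_stack(stack, search_radius=2)
        assert aligned.voxel_size == (4.0, 8.0, 8.0)


class TestDenoise:
    def test_median_removes_impulse(self):
        data = np.full((3, 16, 16), 50.0)
        data[1, 8, 8] = 255.0
        out = denoise(ImageStack(data, VS), "median", window=3)
        assert out.data[1, 8, 8] == 50.0

    @pytest.mark.parametrize("method,params", [("median", {"window": 3}),
                                               ("gaussian_sharpen", {"sigma": 1.0, "amount": 0.5})])
    def test_constant_stack_unchanged(self, method, params):
        stack = flat_stack(value=77.0)
        out = denoise(stack, method, **params)
        assert np.allclose(out.data, 77.0)
        assert out.voxel_size == stack.voxel_size

    def test_even_median_window_rejected(self):
        with pytest.raises(ValueError):
            denoise(flat_stack(), "median", window=4)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            denoise(flat_stack(), "gaussian_sharpen", sigma=0.0)

    def test_sharpening_steepens_edges_vs_plain_blur(self):
        rng = np.random.default_rng(0)
        n = 64
        edge = np.zeros((1, n, n))
        edge[:, :, n // 2:] = 100.0
        noisy = edge + rng.normal(0, 10.0, edge.shape)
        stack = ImageStack(noisy, VS)
        sharpened = denoise(stack, "gaussian_sharpen", sigma=1.0, amount=0.5)
        from scipy import ndimage

        blurred = ndimage.gaussian_filter(noisy[0], 1.0)
        g_sharp = np.abs(np.diff(sharpened.data[0], axis=1))[:, n // 2 - 1].mean()
        g_blur = np.abs(np.diff(blurred, axis=1))[:, n // 2 - 1].mean()
        assert g_sharp > g_blur


class TestSegment:
    def test_two_intensity_volume_counts(self):
        rng = np.random.default_rng(1)
        mask = rng.random((10, 20, 20)) < 0.3
        data = np.where(mask, 200.0, 50.0)
        seg = segment_threshold(ImageStack(data, VS), [("plastid", (150, 255))])
        assert (seg.labels == 1).sum() == mask.sum()
        assert seg.label_map == {1: "plastid"}

    def test_min_component_clears_all(self):
        data = np.full((6, 6, 6), 50.0)
        data[2:4, 2:4, 2:4] = 200.0  # 8-voxel blob
        seg = segment_threshold(
            ImageStack(data, VS), [("other", (150, 255))], min_component_voxels=100
        )
        assert not seg.labels.any()

    def test_priority_first_match_wins(self):
        data = np.full((2, 4, 4), 100.0)
        seg = segment_threshold(
            ImageStack(data, VS),
            [("nucleus", (50, 150)), ("plastid", (90, 110))],
        )
        assert set(seg.label_map.values()) == {"nucleus"}

    def test_disjoint_intervals_order_invariant(self):
        rng = np.random.default_rng(2)
        data = rng.choice([40.0, 120.0, 220.0], size=(6, 12, 12))
        ranges = [("nucleus", (100, 150)), ("plastid", (200, 255))]
        a = segment_threshold(ImageStack(data, VS), ranges)
        b = segment_threshold(ImageStack(data, VS), ranges[::-1])
        for name in ("nucleus", "plastid"):
            va = [k for k, v in a.label_map.items() if v == name][0]
            vb = [k for k, v in b.label_map.items() if v == name][0]
            assert np.array_equal(a.labels == va, b.labels == vb)

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            segment_threshold(flat_stack(), [])


class TestIO:
    def test_stack_roundtrip_with_sidecar(self, tmp_path):
        stack = ImageStack(np.random.default_rng(0).random((4, 8, 8)), (4.0, 8.0, 8.0), "demo")
        p = tmp_path / "s.tif"
        write_stack(stack, p)
        back = read_stack(p)
        assert np.allclose(back.data, stack.data)
        assert back.voxel_size == (4.0, 8.0, 8.0)

    def test_missing_sidecar_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "bare.tif"
        tifffile.imwrite(p, np.zeros((2, 4, 4), dtype=np.uint8))
        with pytest.raises(FileNotFoundError):
            read_stack(p)

    def test_labels_roundtrip(self, tmp_path):
        labels = np.zeros((3, 6, 6), dtype=np.int32)
        labels[1, 2:4, 2:4] = 2
        vol = LabelVolume(labels, VS, {2: "plastid"})
        p = tmp_path / "l.tif"
        write_labels(vol, p)
        back = read_labels(p)
        assert np.array_equal(back.labels, labels)
        assert back.label_map == {2: "plastid"}

    def test_shift_trace_csv_roundtrip(self, tmp_path):
        trace = ShiftTrace(np.array([[0, 0], [2, -1], [-3, 4]]))
        p = tmp_path / "shifts.csv"
        trace.to_csv(p)
        back = ShiftTrace.from_csv(p)
        assert np.array_equal(back.shifts, trace.shifts)

    def test_first_shift_must_be_zero(self):
        with pytest.raises(ValueError):
            ShiftTrace(np.array([[1, 0], [0, 0]]))


def test_label_volume_requires_mapped_labels():
    labels = np.ones((2, 2, 2), dtype=np.int32)
    with pytest.raises(ValueError, match="label_map"):
        LabelVolume(labels, VS, {})
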