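"""NIfTI I/O, preprocessing and postprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brainext as bx
from brainext.errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionError,
)
from brainext.phantoms import DomainSpec, make_phantom
from brainext.volio import (
    MaskVolume,
    VolumeGrid,
    correct_bias,
    from_slices,
    largest_component,
    normalize_intensity,
    read_mask,
    read_volume,
    select_timepoint,
    to_slices,
    write_mask,
    write_volume,
)

from oracles import flood_fill_components, percentile_oracle


class TestNiftiIO:
    def test_volume_round_trip_preserves_data_and_spacing(self, tmp_path):
        sample = make_phantom(DomainSpec(), 0)
        path = tmp_path / "vol.nii.gz"
        write_volume(sample.volume, path)
        back = read_volume(path)
        assert np.array_equal(back.data, sample.volume.data)
        assert np.allclose(back.spacing_mm, sample.volume.spacing_mm, atol=1e-6)

    def test_4d_series_time_axis_preserved(self, tmp_path, rng):
        data = rng.random((8, 8, 4, 10))
        v = VolumeGrid(data, (0.2, 0.2, 0.8))
        path = tmp_path / "func.nii.gz"
        write_volume(v, path)
        back = read_volume(path)
        assert back.is_4d and back.n_timepoints == 10
        assert np.allclose(back.data, data)

    def test_mask_round_trip_stays_binary(self, tmp_path):
        sample = make_phantom(DomainSpec(), 0)
        path = tmp_path / "mask.nii.gz"
        write_mask(sample.mask, path)
        back = read_mask(path)
        assert back.data.dtype == bool
        assert np.array_equal(back.data, sample.mask.data)

    def test_2d_image_rejected(self, tmp_path):
        import nibabel as nib

        path = tmp_path / "flat.nii"
        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), str(path))
        with pytest.raises(DimensionError):
            read_volume(path)


class TestTimepoint:
    def make_series(self, n=10):
        data = np.stack([np.full((4, 4, 2), float(k)) for k in range(n)], axis=-1)
        return VolumeGrid(data, (1, 1, 1))

    def test_explicit_index(self):
        v = self.make_series()
        assert np.all(select_timepoint(v, 4).data == 4.0)

    def test_default_is_fifth_frame(self):
        v = self.make_series()
        assert np.all(select_timepoint(v).data == 4.0)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            select_timepoint(self.make_series(), 99)

    def test_3d_with_nondefault_timepoint_rejected(self):
        v = VolumeGrid(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(DimensionError):
            select_timepoint(v, 2)


class TestNormalize:
    def test_linear_ramp_maps_percentiles_to_unit_interval(self):
        data = np.linspace(0.0, 100.0, 40 * 40 * 40).reshape(40, 40, 40)
        v = VolumeGrid(data, (1, 1, 1))
        norm, rec = normalize_intensity(v)
        assert rec.p1 == pytest.approx(percentile_oracle(data, 1.0), rel=1e-12)
        assert rec.p99 == pytest.approx(percentile_oracle(data, 99.0), rel=1e-12)
        interior = (data > rec.p1) & (data < rec.p99)
        expected = (data[interior] - rec.p1) / (rec.p99 - rec.p1)
        assert np.allclose(norm.data[interior], expected)
        assert norm.data.min() == 0.0 and norm.data.max() == 1.0

    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(0)
        data = rng.random((12, 12, 6)) * 10
        a = normalize_intensity(VolumeGrid(data, (1, 1, 1)))[0].data
        b = normalize_intensity(VolumeGrid(gain * data + offset, (1, 1, 1)))[0].data
        assert np.allclose(a, b, atol=1e-9)

    def test_constant_volume_rejected(self):
        v = VolumeGrid(np.full((8, 8, 8), 3.0), (1, 1, 1))
        with pytest.raises(DegenerateInputError):
            normalize_intensity(v)


class TestBiasCorrection:
    def test_off_mode_is_identity(self):
        s = make_phantom(DomainSpec(), 0)
        out = correct_bias(s.volume, mode="off")
        assert out is s.volume

    def test_bias_free_phantom_nearly_unchanged(self):
        s = make_phantom(DomainSpec(bias_amplitude=0.0), 0)
        out = correct_bias(s.volume, mode="homomorphic")
        rel_rms = np.linalg.norm(out.data - s.volume.data) / \
            np.linalg.norm(s.volume.data)
        assert rel_rms < 0.02

    def test_biased_phantom_flat_region_cv_decreases(self):
        spec = DomainSpec(bias_amplitude=0.3, noise_sd=0.01)
        s = make_phantom(spec, 0)
        region = s.mask.data  # known flat (single mean) region
        out = correct_bias(s.volume, mode="homomorphic")

        def cv(vol):
            vals = vol[region]
            return vals.std() / vals.mean()

        assert cv(out.data) < cv(s.volume.data)

    def test_all_zero_volume_flagged(self):
        v = VolumeGrid(np.zeros((8, 8, 8)), (1, 1, 1))
        out = correct_bias(v, mode="homomorphic")
        assert out.warning is not None


class TestSlicing:
    def test_resize_shape_contract(self):
        s = make_phantom(DomainSpec(), 0)
        norm, rec = normalize_intensity(s.volume)
        stack = to_slices(norm, size=256, record=rec)
        assert stack.slices.shape == (32, 256, 256)

    def test_crop_mode_keeps_center(self):
        data = np.zeros((300, 300, 3))
        data[150, 150, :] = 1.0
        v = VolumeGrid(data, (1, 1, 1))
        stack = to_slices(v, size=256, resize_mode="crop")
        assert stack.slices.shape == (3, 256, 256)
        assert stack.slices[0, 128, 128] == 1.0

    def test_crop_pad_round_trip_restores_geometry_exactly(self):
        s = make_phantom(DomainSpec(), 0)
        mask_grid = VolumeGrid(s.mask.data.astype(float), s.mask.spacing_mm)
        stack = to_slices(mask_grid, size=128, resize_mode="pad")
        back = from_slices(stack.slices, stack.record, s.mask.spacing_mm)
        assert np.array_equal(back.data, s.mask.data)

    def test_resize_round_trip_dice_on_smooth_mask(self):
        s = make_phantom(DomainSpec(surface_wobble=0.0), 0)
        mask_grid = VolumeGrid(s.mask.data.astype(float), s.mask.spacing_mm)
        stack = to_slices(mask_grid, size=256, resize_mode="resize")
        back = from_slices(stack.slices, stack.record, s.mask.spacing_mm)
        assert bx.dice_score(back, s.mask) >= 0.98

    def test_all_empty_slices_give_empty_volume(self):
        s = make_phantom(DomainSpec(), 0)
        norm, rec = normalize_intensity(s.volume)
        stack = to_slices(norm, size=64, resize_mode="pad", record=rec)
        empty = np.zeros_like(stack.slices)
        back = from_slices(empty, stack.record, s.volume.spacing_mm)
        assert back.voxel_count == 0

    def test_single_full_slice_lands_at_right_index(self):
        v = VolumeGrid(np.zeros((32, 32, 8)), (1, 1, 1))
        stack = to_slices(v, size=32, resize_mode="pad")
        slices = np.zeros_like(stack.slices)
        slices[5] = 1.0
        back = from_slices(slices, stack.record, (1, 1, 1))
        assert back.data[:, :, 5].all()
        assert back.data.sum() == 32 * 32

    def test_slice_count_mismatch_rejected(self):
        v = VolumeGrid(np.zeros((16, 16, 8)), (1, 1, 1))
        stack = to_slices(v, size=16, resize_mode="pad")
        with pytest.raises(DimensionError):
            from_slices(stack.slices[:5], stack.record, (1, 1, 1))


class TestLargestComponent:
    def build(self, blobs, shape=(12, 12, 12)):
        m = np.zeros(shape, bool)
        for sl in blobs:
            m[sl] = True
        return MaskVolume(m, (1, 1, 1))

    def test_keeps_largest_of_two_blobs(self):
        m = self.build([
            (slice(0, 2), slice(0, 5), slice(0, 1)),   # 10 voxels
            (slice(8, 9), slice(8, 11), slice(8, 9)),  # 3 voxels
        ])
        out = largest_component(m)
        assert out.voxel_count == 10
        assert out.data[0, 0, 0] and not out.data[8, 8, 8]

    def test_single_blob_unchanged(self):
        m = self.build([(slice(2, 5), slice(2, 5), slice(2, 5))])
        assert np.array_equal(largest_component(m).data, m.data)

    def test_empty_mask_returned_with_warning(self):
        m = MaskVolume(np.zeros((4, 4, 4), bool), (1, 1, 1))
        out = largest_component(m)
        assert out.voxel_count == 0 and out.warning is not None

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(10):
            m = MaskVolume(rng.random((10, 10, 10)) < 0.25, (1, 1, 1))
            if not m.data.any():
                continue
            comps = flood_fill_components(m.data, connectivity)
            biggest = max(len(c) for c in comps)
            out = largest_component(m, connectivity=connectivity)
            assert out.voxel_count == biggest

    def test_bad_connectivity_rejected(self):
        m = MaskVolume(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ConfigurationError):
            largest_component(m, connectivity=18)
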