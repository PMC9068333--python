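import numpy as np
import pytest

from laaoplan.geometry import Point3D
from laaoplan.volume_io import (
    LabelMask,
    VolumeGrid,
    crop_around_point,
    read_volume,
    resample_isotropic,
    resize_to_shape,
    write_volume,
)


def _random_grid(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(rng.normal(size=shape).astype(np.float32), spacing, (2.0, -3.0, 5.0))


class TestNiftiRoundTrip:
    def test_data_spacing_origin_preserved(self, rng, tmp_path):
        v = _random_grid(rng, spacing=(0.7, 1.1, 2.0))
        write_volume(v, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz")
        assert np.abs(back.data - v.data).max() == 0
        assert np.allclose(back.spacing, v.spacing)
        assert np.allclose(back.origin, v.origin)

    def test_label_mask_lossless(self, rng, tmp_path):
        m = LabelMask(rng.integers(0, 3, size=(12, 10, 8)).astype(np.int16), (1, 1, 1), (0, 0, 0))
        write_volume(m, tmp_path / "m.nii.gz")
        back = read_volume(tmp_path / "m.nii.gz")
        assert np.array_equal(np.asarray(back.data), m.data)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")


def _write_dicom_slice(path, z, rows=8, cols=8, value=0, spacing=(0.8, 0.6)):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    arr = np.full((rows, cols), value, dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    def test_reads_geometry_and_values(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        for k, z in enumerate([0.0, 2.0, 4.0, 6.0]):
            _write_dicom_slice(d / f"s{k}.dcm", z, value=k)
        v = read_volume(d, format="dicom_series")
        assert v.shape == (8, 8, 4)
        assert np.allclose(v.spacing, [0.6, 0.8, 2.0])
        assert np.allclose(v.data[0, 0, :], [0, 1, 2, 3])

    def test_missing_slice_reports_gap(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        for k, z in enumerate([0.0, 2.0, 6.0, 8.0]):  # slice at z=4 missing
            _write_dicom_slice(d / f"s{k}.dcm", z, value=k)
        with pytest.raises(ValueError, match="z=2.00"):
            read_volume(d, format="dicom_series")


class TestResampleIsotropic:
    def test_constant_volume_stays_constant(self):
        v = VolumeGrid(np.full((10, 12, 14), 7.0), (2.0, 1.5, 1.0), (0, 0, 0))
        out = resample_isotropic(v, 1.0)
        assert np.allclose(out.data, 7.0)
        assert np.allclose(out.spacing, 1.0)

    def test_identity_on_matching_grid(self, rng):
        v = _random_grid(rng)
        out = resample_isotropic(v, 1.0)
        assert out.shape == v.shape
        assert np.allclose(out.data, v.data, atol=1e-6)

    def test_linear_ramp_closed_form(self):
        # f(world x) = x sampled at 2 mm, resampled to 1 mm: linear interp is exact
        n = 20
        x = np.arange(n) * 2.0
        data = np.broadcast_to(x[:, None, None], (n, 4, 4)).copy()
        v = VolumeGrid(data, (2.0, 2.0, 2.0), (0, 0, 0))
        out = resample_isotropic(v, 1.0)
        expected = out.axis_coords(0)
        assert np.abs(out.data[:, 1, 1] - expected).max() < 1e-6

    def test_idempotent_on_same_grid(self, rng):
        v = _random_grid(rng, spacing=(1.3, 0.9, 1.1))
        once = resample_isotropic(v, 1.0)
        twice = resample_isotropic(once, 1.0)
        assert np.allclose(once.data, twice.data, atol=1e-6)

    def test_labels_keep_label_set(self, rng):
        m = LabelMask(rng.integers(0, 4, size=(9, 9, 9)).astype(np.int16), (1.5, 1.5, 1.5), (0, 0, 0))
        out = resample_isotropic(m, 1.0, "nearest")
        assert set(np.unique(out.data)) <= set(np.unique(m.data))
        with pytest.raises(ValueError):
            resample_isotropic(m, 1.0, "linear")

    def test_extent_preserved_within_one_voxel(self, rng):
        v = _random_grid(rng, shape=(20, 30, 40), spacing=(0.8, 1.2, 0.5))
        out = resample_isotropic(v, 1.0)
        old_extent = (np.array(v.shape) - 1) * v.spacing
        new_extent = (np.array(out.shape) - 1) * out.spacing
        assert np.all(np.abs(old_extent - new_extent) <= 1.0)


class TestResize:
    def test_own_shape_is_identity(self, rng):
        v = _random_grid(rng)
        out, t = resize_to_shape(v, v.shape)
        assert np.allclose(out.data, v.data, atol=1e-6)
        assert t.is_identity

    def test_downsampling_doubles_spacing(self, rng):
        v = _random_grid(rng, shape=(64, 64, 64))
        out, _ = resize_to_shape(v, (32, 32, 32))
        assert np.allclose(out.spacing, 2.0 * v.spacing)
        # physical extent (cell-based) conserved
        assert np.allclose(np.array(out.shape) * out.spacing, np.array(v.shape) * v.spacing)

    def test_transform_round_trip(self, rng):
        v = _random_grid(rng)
        _, t = resize_to_shape(v, (8, 8, 8))
        p = np.array([[3.3, -1.2, 7.9]])
        assert np.abs(t.inverse(t.forward(p)) - p).max() < 1e-9


class TestCrop:
    def test_full_crop_at_center_is_identity(self, rng):
        v = _random_grid(rng)
        center = v.index_to_world((np.array(v.shape) - 1) / 2.0 + 0.25)
        out, _ = crop_around_point(v, Point3D.from_array(center), v.shape)
        assert np.allclose(out.data, v.data)

    def test_outside_region_padded(self, rng):
        v = _random_grid(rng)
        corner = v.index_to_world((0, 0, 0))
        out, _ = crop_around_point(v, Point3D.from_array(corner), (16, 16, 16), pad_value=-42.0)
        assert (out.data == -42.0).sum() > 0
        assert np.all(out.data[:8, :8, :8][out.data[:8, :8, :8] == -42.0] == -42.0)

    def test_world_coordinates_unchanged(self, rng):
        v = _random_grid(rng)
        v.data[5, 6, 7] = 123.456
        world_before = v.index_to_world((5, 6, 7))
        center = v.index_to_world((8, 8, 8))
        out, _ = crop_around_point(v, Point3D.from_array(center), (10, 10, 10))
        idx = np.argwhere(out.data == np.float32(123.456))[0]
        assert np.abs(out.index_to_world(idx) - world_before).max() < 1e-9

    def test_center_outside_warns(self, rng):
        v = _random_grid(rng)
        with pytest.warns(UserWarning, match="outside"):
            out, _ = crop_around_point(v, Point3D(1000.0, 1000.0, 1000.0), (4, 4, 4), pad_value=9.0)
        assert np.all(out.data == 9.0)


def test_crop_resize_transforms_compose(rng):
    v = _random_grid(rng, shape=(24, 24, 24))
    cropped, t1 = crop_around_point(v, Point3D(8.0, 4.0, 12.0), (12, 12, 12))
    _, t2 = resize_to_shape(cropped, (6, 6, 6))
    p = np.array([[5.0, 2.0, 9.0]])
    forward = t2.forward(t1.forward(p))
    back = t1.inverse(t2.inverse(forward))
    assert np.abs(back - p).max() < 1e-9
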