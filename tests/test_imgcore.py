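"""Image/mask data model, NIfTI round-trips, resampling and VOI statistics."""

import itertools

import nibabel as nib
import numpy as np
import pytest

from y90quant.imgcore import (
    StudySet,
    UnitsError,
    VoiMask,
    VoxelGrid,
    mask_difference,
    read_dicom_series,
    read_grid,
    read_mask,
    resample_to,
    voi_stats,
    write_grid,
    write_mask,
)


class TestVoxelGrid:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.ones((4, 4)), (1, 1, 1))  # not 3-D
        with pytest.raises(ValueError):
            VoxelGrid(np.ones((4, 4, 4)), (1, 0, 1))  # non-positive spacing
        with pytest.raises(ValueError):
            VoxelGrid(np.full((2, 2, 2), np.nan), (1, 1, 1))  # non-finite
        with pytest.raises(UnitsError):
            VoxelGrid(np.ones((2, 2, 2)), (1, 1, 1), units="becquerel")

    def test_voxel_volume_ml(self):
        g = VoxelGrid(np.ones((2, 2, 2)), (4.664,) * 3)
        assert g.voxel_volume_ml == pytest.approx(0.4664**3, rel=1e-12)


class TestNiftiIO:
    def test_round_trip_identity(self, tmp_path):
        g = VoxelGrid(np.ones((4, 4, 4)), (1.0, 1.0, 1.0), (0, 0, 0), "cps")
        write_grid(g, tmp_path / "g.nii.gz")
        back = read_grid(tmp_path / "g.nii.gz", "cps")
        np.testing.assert_array_equal(back.data, g.data)
        assert back.spacing == g.spacing
        assert back.origin == g.origin

    def test_clinical_spacing_survives(self, tmp_path, rng):
        g = VoxelGrid(rng.uniform(0, 5, (5, 6, 7)), (4.664,) * 3, (-10.0, 3.5, 0.0))
        write_grid(g, tmp_path / "g.nii.gz")
        back = read_grid(tmp_path / "g.nii.gz")
        assert back.spacing == pytest.approx((4.664, 4.664, 4.664), abs=1e-3)
        assert back.origin == pytest.approx(g.origin, abs=1e-4)
        np.testing.assert_allclose(back.data, g.data, rtol=1e-6)

    def test_2d_file_rejected(self, tmp_path):
        nib.save(nib.Nifti1Image(np.ones((4, 4)), np.eye(4)), str(tmp_path / "flat.nii"))
        with pytest.raises(ValueError, match="3-D"):
            read_grid(tmp_path / "flat.nii")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_grid(tmp_path / "nope.nii.gz")

    def test_mask_round_trip_uint8(self, tmp_path, small_grid, rng):
        m = VoiMask(rng.uniform(0, 1, small_grid.shape) > 0.5, "tumor")
        write_mask(m, small_grid, tmp_path / "m.nii.gz")
        img = nib.load(str(tmp_path / "m.nii.gz"))
        assert img.get_data_dtype() == np.uint8
        back = read_mask(tmp_path / "m.nii.gz", "tumor")
        np.testing.assert_array_equal(back.data, m.data)


def test_dicom_series_import(tmp_path, rng):
    """A synthetic 3-slice DICOM series stacks into the right geometry."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    vals = rng.integers(0, 500, size=(3, 8, 8)).astype(np.uint16)
    for z in range(3):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Rows, ds.Columns = 8, 8
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelSpacing = [4.664, 4.664]
        ds.ImagePositionPatient = [0.0, 0.0, 4.664 * z]
        ds.InstanceNumber = z + 1
        ds.PixelData = vals[z].tobytes()
        ds.save_as(str(tmp_path / f"slice_{z}.dcm"), enforce_file_format=True)
    grid = read_dicom_series(tmp_path)
    assert grid.shape == (8, 8, 3)
    assert grid.spacing == pytest.approx((4.664, 4.664, 4.664))
    np.testing.assert_array_equal(grid.data[:, :, 1], vals[1].astype(float))


class TestResample:
    @pytest.mark.parametrize("mode", ["nearest", "trilinear"])
    def test_identity_on_same_geometry(self, small_grid, mode):
        out = resample_to(small_grid, small_grid, mode)
        np.testing.assert_allclose(out.data, small_grid.data, atol=1e-12)

    def test_constant_preserved_on_finer_grid(self):
        src = VoxelGrid(np.full((6, 6, 6), 7.0), (4.0,) * 3)
        ref = VoxelGrid(np.zeros((10, 10, 10)), (2.0,) * 3, (1.0, 1.0, 1.0))
        out = resample_to(src, ref, "trilinear")
        np.testing.assert_allclose(out.data, 7.0)

    def test_nearest_preserves_value_set(self):
        board = np.indices((8, 8, 8)).sum(axis=0) % 2
        src = VoxelGrid(board.astype(float), (1.0,) * 3)
        ref = VoxelGrid(np.zeros((4, 4, 4)), (2.0,) * 3)
        out = resample_to(src, ref, "nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_bad_mode(self, small_grid):
        with pytest.raises(ValueError):
            resample_to(small_grid, small_grid, "cubic")


class TestVoiStats:
    def test_constant_field(self):
        img = VoxelGrid(np.full((5, 5, 5), 2.0), (1.0,) * 3)
        mask = np.zeros((5, 5, 5), bool)
        mask.flat[:10] = True
        st = voi_stats(img, VoiMask(mask))
        assert st["mean"] == pytest.approx(2.0)
        assert st["total"] == pytest.approx(20.0)
        assert st["voxel_count"] == 10

    def test_clinical_voxel_volume(self):
        img = VoxelGrid(np.ones((10, 10, 10)), (4.664,) * 3)
        st = voi_stats(img, VoiMask(np.ones((10, 10, 10))))
        assert st["volume_ml"] == pytest.approx(1000 * 0.4664**3, rel=1e-12)
        assert st["volume_ml"] == pytest.approx(101.5, abs=0.05)

    def test_empty_mask_rejected(self, small_grid):
        with pytest.raises(ValueError, match="empty"):
            voi_stats(small_grid, VoiMask(np.zeros(small_grid.shape)))

    def test_total_matches_brute_force(self, rng):
        img = VoxelGrid(rng.normal(size=(6, 6, 6)), (1.0,) * 3)
        mask = rng.uniform(size=(6, 6, 6)) > 0.4
        expected = 0.0
        for i, j, k in itertools.product(range(6), repeat=3):
            if mask[i, j, k]:
                expected += img.data[i, j, k]
        assert voi_stats(img, VoiMask(mask))["total"] == pytest.approx(expected, abs=1e-12)

    def test_volume_invariant_under_axis_permutation(self, rng):
        data = rng.uniform(0, 1, (4, 5, 6))
        mask = data > 0.5
        vols = set()
        for perm in itertools.permutations(range(3)):
            g = VoxelGrid(data.transpose(perm), tuple(np.array([1.0, 2.0, 3.0])[list(perm)]))
            vols.add(round(voi_stats(g, VoiMask(mask.transpose(perm)))["volume_ml"], 12))
        assert len(vols) == 1


class TestMaskDifference:
    def test_whole_equals_part_gives_empty(self, rng):
        m = VoiMask(rng.uniform(size=(4, 4, 4)) > 0.5)
        assert mask_difference(m, m).voxel_count == 0

    def test_empty_part_is_identity(self, rng):
        whole = VoiMask(rng.uniform(size=(4, 4, 4)) > 0.5)
        out = mask_difference(whole, VoiMask(np.zeros((4, 4, 4))))
        np.testing.assert_array_equal(out.data, whole.data)

    def test_counts_by_enumeration(self):
        whole = np.zeros((10, 10, 10), bool)
        whole.flat[:100] = True
        part = np.zeros((10, 10, 10), bool)
        part.flat[:30] = True
        assert mask_difference(VoiMask(whole), VoiMask(part)).voxel_count == 70

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_difference(VoiMask(np.ones((3, 3, 3))), VoiMask(np.ones((4, 4, 4))))


def test_studyset_validation(small_grid):
    with pytest.raises(ValueError):
        StudySet(spect=small_grid, administered_activity=-1.0)
    with pytest.raises(ValueError, match="aligned"):
        StudySet(spect=small_grid, ct_masks={"liver": VoiMask(np.ones((2, 2, 2)))})
    s = StudySet(spect=small_grid, administered_activity=555.0, agent="Y90")
    assert s.administered_activity == 555.0
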