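"""I/O round-trips and the preprocessing chain."""

import numpy as np
import pytest

from sanityscan import (
    CTVolume,
    NormalizationStats,
    SegmentationMask,
    clip_hu,
    compute_normalization_stats,
    normalize,
    preprocess,
    read_volume,
    resample_isotropic,
    resample_mask,
    resize_slices,
    write_volume,
)
from sanityscan.errors import (
    DegenerateDataError,
    IntegrityError,
    ParameterError,
)


def make_volume(rng, shape=(6, 10, 12), spacing=(2.0, 0.8, 0.8)):
    return CTVolume(voxels=rng.normal(0, 100, size=shape), spacing=spacing)


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def test_nifti_round_trip_preserves_voxels_and_spacing(tmp_path, rng):
    vol = make_volume(rng)
    path = tmp_path / "vol.nii.gz"
    write_volume(vol, path)
    back = read_volume(path)
    assert back.spacing == pytest.approx((2.0, 0.8, 0.8))
    np.testing.assert_array_equal(back.voxels, vol.voxels)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _write_dicom_series(dirpath, z_positions, rng, spacing=(0.7, 0.7)):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    for i, z in enumerate(z_positions):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.PatientID = "p0"
        ds.Rows = 8
        ds.Columns = 8
        ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = rng.integers(0, 3000, size=(8, 8), dtype=np.uint16).tobytes()
        ds.save_as(dirpath / f"slice{i:03d}.dcm", enforce_file_format=True)


def test_dicom_series_reads_hu_and_spacing(tmp_path, rng):
    _write_dicom_series(tmp_path, [0.0, 2.5, 5.0, 7.5], rng)
    vol = read_volume(tmp_path)
    assert vol.voxels.shape == (4, 8, 8)
    assert vol.spacing == pytest.approx((2.5, 0.7, 0.7))
    # rescale intercept applied: raw uint16 minus 1024
    assert vol.voxels.min() >= -1024.0


def test_dicom_series_with_gap_raises_integrity_error(tmp_path, rng):
    # one slice missing from the spatial sequence: positions 0, 2.5, 7.5
    _write_dicom_series(tmp_path, [0.0, 2.5, 7.5], rng)
    with pytest.raises(IntegrityError):
        read_volume(tmp_path)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def test_resample_constant_volume_is_constant(rng):
    vol = CTVolume(np.full((5, 9, 11), 42.0), spacing=(2.0, 0.7, 1.3))
    out = resample_isotropic(vol)
    assert out.spacing == (1.0, 1.0, 1.0)
    assert np.allclose(out.voxels, 42.0, atol=1e-6)


def test_resample_identity_when_already_isotropic(rng):
    vol = make_volume(rng, spacing=(1.0, 1.0, 1.0))
    out = resample_isotropic(vol)
    np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-10)


def test_resample_ramp_matches_1d_oracle():
    """v(z) = z at 2 mm slice spacing: compare against the 1-D brute force."""
    from test_interp import brute_force_resample_1d

    nz = 8
    ramp = np.arange(nz, dtype=float)
    vol = CTVolume(
        np.repeat(ramp[:, None, None], 4, axis=1).repeat(5, axis=2),
        spacing=(2.0, 1.0, 1.0),
    )
    out = resample_isotropic(vol)
    assert out.voxels.shape[0] == 16  # extent 16 mm at 1 mm spacing
    expected = brute_force_resample_1d(ramp, 16, "lanczos")
    np.testing.assert_allclose(out.voxels[:, 2, 2], expected, atol=1e-10)


def test_resample_preserves_physical_extent(rng):
    vol = make_volume(rng, shape=(7, 20, 30), spacing=(3.0, 0.5, 0.75))
    out = resample_isotropic(vol)
    for ax, (n_in, sp) in enumerate(zip(vol.voxels.shape, vol.spacing)):
        extent_in = n_in * sp
        extent_out = out.voxels.shape[ax] * 1.0
        assert abs(extent_in - extent_out) <= 1.0  # within one voxel


def test_resample_rejects_bad_spacing(rng):
    with pytest.raises(ParameterError):
        resample_isotropic(make_volume(rng), target_spacing=0.0)


def test_mask_resampled_nearest_neighbour_stays_binary():
    mask_vox = np.zeros((4, 8, 8), dtype=np.uint8)
    mask_vox[1:3, 2:6, 2:6] = 1
    mask = SegmentationMask(mask_vox, spacing=(2.0, 1.0, 1.0))
    out = resample_mask(mask)
    assert set(np.unique(out.voxels)) <= {0, 1}
    assert out.voxels.shape[0] == 8


# ---------------------------------------------------------------------------
# Slice resizing
# ---------------------------------------------------------------------------

def test_resize_constant_slice_constant():
    vol = CTVolume(np.full((3, 10, 10), 5.0), spacing=(1.0, 1.0, 1.0))
    out = resize_slices(vol, 299)
    assert out.voxels.shape == (3, 299, 299)
    assert np.allclose(out.voxels, 5.0)


def test_resize_identity_at_target_size(rng):
    vol = CTVolume(rng.normal(size=(2, 299, 299)), spacing=(1.0, 1.0, 1.0))
    out = resize_slices(vol, 299)
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_resize_rejects_tiny_size(rng):
    with pytest.raises(ParameterError):
        resize_slices(make_volume(rng), size=1)


# ---------------------------------------------------------------------------
# Clipping and normalization
# ---------------------------------------------------------------------------

def test_clip_hu_forced_values():
    vol = CTVolume(
        np.array([-1000.0, -300.0, 0.0, 300.0, 1000.0]).reshape(5, 1, 1)
        * np.ones((5, 2, 2)),
        spacing=(1.0, 1.0, 1.0),
    )
    out = clip_hu(vol)
    np.testing.assert_array_equal(
        out.voxels[:, 0, 0], [-300.0, -300.0, 0.0, 300.0, 300.0]
    )


def test_clip_is_idempotent(rng):
    vol = make_volume(rng)
    once = clip_hu(vol)
    twice = clip_hu(once)
    np.testing.assert_array_equal(once.voxels, twice.voxels)


def test_clip_rejects_inverted_bounds(rng):
    with pytest.raises(ParameterError):
        clip_hu(make_volume(rng), lo=10, hi=-10)


def test_normalization_stats_mean_of_two_constant_volumes():
    v0 = CTVolume(np.zeros((3, 4, 4)), spacing=(1, 1, 1))
    v100 = CTVolume(np.full((3, 4, 4), 100.0), spacing=(1, 1, 1))
    stats = compute_normalization_stats([v0, v100])
    assert stats.mean == pytest.approx(50.0)
    assert stats.std == pytest.approx(50.0)


def test_normalization_stats_match_two_pass_oracle(rng):
    vols = [make_volume(rng, shape=(3, 5, 7)) for _ in range(4)]
    stats = compute_normalization_stats(vols)
    pooled = np.concatenate([v.voxels.ravel() for v in vols])
    assert stats.mean == pytest.approx(pooled.mean())
    assert stats.std == pytest.approx(pooled.std())


def test_normalization_stats_degenerate_on_constant():
    vol = CTVolume(np.full((3, 4, 4), 7.0), spacing=(1, 1, 1))
    with pytest.raises(DegenerateDataError):
        compute_normalization_stats([vol])


def test_normalize_round_trip(rng):
    vol = make_volume(rng)
    stats = NormalizationStats(mean=12.0, std=34.0)
    normed = normalize(vol, stats)
    back = normed.voxels * stats.std + stats.mean
    np.testing.assert_allclose(back, vol.voxels, atol=1e-9)


def test_normalize_identity_stats(rng):
    vol = make_volume(rng)
    out = normalize(vol, NormalizationStats(mean=0.0, std=1.0))
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_training_cohort_self_normalization_is_standard(rng):
    vols = [clip_hu(make_volume(rng, shape=(3, 6, 6))) for _ in range(3)]
    stats = compute_normalization_stats(vols)
    pooled = np.concatenate([normalize(v, stats).voxels.ravel() for v in vols])
    assert pooled.mean() == pytest.approx(0.0, abs=1e-9)
    assert pooled.std() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def test_preprocess_constant_zero_volume_gives_zeros():
    vol = CTVolume(np.zeros((4, 10, 10)), spacing=(2.0, 1.0, 1.0))
    out = preprocess(vol, NormalizationStats(mean=0.0, std=1.0), size=64)
    assert out.slices.shape[1:] == (64, 64)
    assert np.allclose(out.slices, 0.0, atol=1e-9)


def test_preprocess_deterministic_and_matches_step_composition(rng):
    vol = make_volume(rng)
    stats = NormalizationStats(mean=5.0, std=20.0)
    a = preprocess(vol, stats, size=64)
    b = preprocess(vol, stats, size=64)
    np.testing.assert_array_equal(a.slices, b.slices)
    # independent composition of the four steps in the stated order
    manual = normalize(clip_hu(resize_slices(resample_isotropic(vol), 64)), stats)
    np.testing.assert_array_equal(a.slices, manual.voxels)


def test_preprocess_preserves_slice_count_and_order(rng):
    ramp = np.arange(6, dtype=float)[:, None, None] * np.ones((6, 8, 8))
    vol = CTVolume(ramp, spacing=(1.0, 1.0, 1.0))
    out = preprocess(vol, NormalizationStats(mean=0.0, std=1.0), size=32)
    assert out.n_slices == 6
    means = out.slices.mean(axis=(1, 2))
    assert np.all(np.diff(means) > 0)  # ramp order preserved


def test_volume_invariants_rejected():
    with pytest.raises(ParameterError):
        CTVolume(np.zeros((1, 4, 4)), spacing=(1, 1, 1))  # too few slices
    with pytest.raises(ParameterError):
        CTVolume(np.zeros((3, 4, 4)), spacing=(0, 1, 1))  # bad spacing
    bad = np.zeros((3, 4, 4))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ParameterError):
        CTVolume(bad, spacing=(1, 1, 1))
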