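"""Volumetric CT containers, file I/O, and the scan preprocessing chain.

The preprocessing chain mirrors common practice for feeding CT volumes to
2-D slice encoders: resample to 1.0 mm isotropic resolution with windowed
sinc interpolation, resize every axial slice to 299 x 299 pixels with
bilinear interpolation, clip Hounsfield units to +/-300 HU, and z-score
with mean/std pooled over the *training* volumes only.

Array convention: ``voxels[t, i, j]`` is slice ``t`` (axial), row ``i``,
column ``j``; ``spacing`` is (slice, row, col) in millimetres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._interp import apply_along_axis_matrix, interp_matrix
from .errors import (
    AlignmentError,
    DegenerateDataError,
    FormatError,
    IntegrityError,
    ParameterError,
)

__all__ = [
    "CTVolume",
    "SegmentationMask",
    "PreprocessedVolume",
    "NormalizationStats",
    "read_volume",
    "read_mask",
    "write_volume",
    "resample_isotropic",
    "resample_mask",
    "resize_slices",
    "clip_hu",
    "compute_normalization_stats",
    "normalize",
    "preprocess",
]

DEFAULT_TARGET_SPACING_MM = 1.0
DEFAULT_SLICE_SIZE_PX = 299
DEFAULT_HU_CLIP = (-300.0, 300.0)
SINC_WINDOW = "lanczos"
SINC_RADIUS = 3


@dataclass(frozen=True)
class CTVolume:
    """A 3-D scalar grid in Hounsfield units with physical spacing."""

    voxels: np.ndarray                 # (slices, rows, cols), HU
    spacing: tuple[float, float, float]  # (slice, row, col) mm
    patient_id: str = ""

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if vox.ndim != 3:
            raise ParameterError("voxels must be a 3-D array")
        if vox.shape[0] < 2:
            raise ParameterError("a CT volume needs at least 2 slices")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be strictly positive on all axes")
        if not np.all(np.isfinite(vox)):
            raise ParameterError("voxel values must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class SegmentationMask:
    """Binary grid aligned to a :class:`CTVolume` marking the target region."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ParameterError("mask voxels must be a 3-D array")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ParameterError("mask values must be 0 or 1")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    def check_aligned(self, vol: CTVolume) -> None:
        if self.voxels.shape != vol.voxels.shape or not np.allclose(
            self.spacing, vol.spacing
        ):
            raise AlignmentError(
                f"mask grid {self.voxels.shape}/{self.spacing} does not match "
                f"volume {vol.voxels.shape}/{vol.spacing}"
            )


@dataclass(frozen=True)
class PreprocessedVolume:
    """Ordered stack of normalized square slices ready for an encoder."""

    slices: np.ndarray  # (s, size, size)
    patient_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.slices, dtype=float)
        object.__setattr__(self, "slices", arr)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ParameterError("slices must be a stack of square images")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("slice values must be finite")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled mean/std of post-clipping HU over the training volumes."""

    mean: float
    std: float

    def __post_init__(self):
        if not self.std > 0:
            raise DegenerateDataError("normalization std must be positive")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI file or a directory holding a single DICOM series.

    Voxels are returned in HU (DICOM rescale slope/intercept applied) with
    the axial axis first.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def read_mask(path: str | os.PathLike) -> SegmentationMask:
    vol = read_volume(path)
    vox = vol.voxels
    binary = (vox > 0.5).astype(np.uint8)
    return SegmentationMask(voxels=binary, spacing=vol.spacing)


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # nibabel axes are (x, y, z); put the axial axis first.
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels=voxels, spacing=spacing, patient_id=path.stem.split(".")[0])


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI with a diagonal affine from its spacing."""
    import nibabel as nib

    data = np.transpose(vol.voxels, (2, 1, 0))
    sp = vol.spacing
    affine = np.diag([sp[2], sp[1], sp[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"{path}: no readable DICOM files")
    series = {getattr(d, "SeriesInstanceUID", None) for d in datasets}
    if len(series) != 1:
        raise IntegrityError(f"{path}: directory holds {len(series)} DICOM series")
    rows = {(int(d.Rows), int(d.Columns)) for d in datasets}
    px = {tuple(float(v) for v in d.PixelSpacing) for d in datasets}
    orient = {tuple(round(float(v), 6) for v in d.ImageOrientationPatient) for d in datasets}
    if len(rows) != 1 or len(px) != 1 or len(orient) != 1:
        raise IntegrityError(f"{path}: inconsistent DICOM series (mixed geometry)")
    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    order = np.argsort(zs)
    zs = zs[order]
    datasets = [datasets[i] for i in order]
    dz = np.diff(zs)
    if len(dz) == 0:
        raise IntegrityError(f"{path}: series has a single slice")
    if np.any(dz <= 0) or not np.allclose(dz, dz[0], rtol=1e-3, atol=1e-3):
        raise IntegrityError(
            f"{path}: non-uniform slice positions (gap or duplicate in series)"
        )
    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(float)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        inter = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + inter)
    r, c = next(iter(rows))
    pr, pc = next(iter(px))
    pid = str(getattr(datasets[0], "PatientID", path.name))
    return CTVolume(
        voxels=np.stack(slices),
        spacing=(float(dz[0]), pr, pc),
        patient_id=pid,
    )


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

def _iso_lengths(vol_shape, spacing, target: float) -> list[int]:
    # physical extent preserved to within one voxel per axis
    return [max(2, int(round(n * s / target))) for n, s in zip(vol_shape, spacing)]


def resample_isotropic(
    vol: CTVolume, target_spacing: float = DEFAULT_TARGET_SPACING_MM
) -> CTVolume:
    """Resample to isotropic resolution with windowed-sinc interpolation.

    Uses a separable Lanczos-windowed sinc kernel (radius
    :data:`SINC_RADIUS`) per axis; the physical extent is preserved to
    within one voxel on each axis.
    """
    if target_spacing <= 0:
        raise ParameterError("target spacing must be positive")
    out = np.asarray(vol.voxels, dtype=float)
    new_shape = _iso_lengths(out.shape, vol.spacing, target_spacing)
    for axis in range(3):
        if new_shape[axis] != out.shape[axis] or not np.isclose(
            vol.spacing[axis], target_spacing
        ):
            mat = interp_matrix(
                out.shape[axis], new_shape[axis], kernel=SINC_WINDOW, a=SINC_RADIUS
            )
            out = apply_along_axis_matrix(out, mat, axis)
    return CTVolume(
        voxels=out,
        spacing=(target_spacing,) * 3,
        patient_id=vol.patient_id,
    )


def resample_mask(
    mask: SegmentationMask, target_spacing: float = DEFAULT_TARGET_SPACING_MM
) -> SegmentationMask:
    """Resample a binary mask with nearest-neighbour interpolation."""
    if target_spacing <= 0:
        raise ParameterError("target spacing must be positive")
    out = mask.voxels.astype(float)
    new_shape = _iso_lengths(out.shape, mask.spacing, target_spacing)
    for axis in range(3):
        if new_shape[axis] != out.shape[axis] or not np.isclose(
            mask.spacing[axis], target_spacing
        ):
            mat = interp_matrix(out.shape[axis], new_shape[axis], kernel="nearest")
            out = apply_along_axis_matrix(out, mat, axis)
    return SegmentationMask(voxels=(out > 0.5).astype(np.uint8), spacing=(target_spacing,) * 3)


def resize_slices(vol: CTVolume, size: int = DEFAULT_SLICE_SIZE_PX) -> CTVolume:
    """Resize every axial slice to ``size`` x ``size`` with bilinear interpolation.

    Non-square slices are stretched anisotropically; in-plane spacing is
    rescaled accordingly so physical extent bookkeeping stays consistent.
    """
    if size < 2:
        raise ParameterError("slice size must be at least 2 pixels")
    s, r, c = vol.voxels.shape
    out = np.asarray(vol.voxels, dtype=float)
    if r != size:
        out = apply_along_axis_matrix(out, interp_matrix(r, size, "linear"), 1)
    if c != size:
        out = apply_along_axis_matrix(out, interp_matrix(c, size, "linear"), 2)
    return CTVolume(
        voxels=out,
        spacing=(vol.spacing[0], vol.spacing[1] * r / size, vol.spacing[2] * c / size),
        patient_id=vol.patient_id,
    )


def clip_hu(
    vol: CTVolume,
    lo: float = DEFAULT_HU_CLIP[0],
    hi: float = DEFAULT_HU_CLIP[1],
) -> CTVolume:
    """Clip voxel values to [lo, hi] HU (defaults +/-300 HU)."""
    if lo >= hi:
        raise ParameterError("clip bounds require lo < hi")
    return CTVolume(
        voxels=np.clip(vol.voxels, lo, hi),
        spacing=vol.spacing,
        patient_id=vol.patient_id,
    )


def compute_normalization_stats(
    training_volumes: Iterable[CTVolume],
) -> NormalizationStats:
    """Pool mean/std over all voxels of all training volumes (post-clipping)."""
    n = 0
    total = 0.0
    total_sq = 0.0
    for vol in training_volumes:
        v = vol.voxels
        n += v.size
        total += float(v.sum())
        total_sq += float(np.square(v).sum())
    if n == 0:
        raise ParameterError("need at least one training volume")
    mean = total / n
    var = total_sq / n - mean * mean
    if var <= 1e-12:
        raise DegenerateDataError("pooled variance of training voxels is zero")
    return NormalizationStats(mean=mean, std=float(np.sqrt(var)))


def normalize(vol: CTVolume, stats: NormalizationStats) -> CTVolume:
    """Z-score the volume with training-set statistics."""
    return CTVolume(
        voxels=(vol.voxels - stats.mean) / stats.std,
        spacing=vol.spacing,
        patient_id=vol.patient_id,
    )


def prepare(
    vol: CTVolume,
    target_spacing: float = DEFAULT_TARGET_SPACING_MM,
    size: int = DEFAULT_SLICE_SIZE_PX,
    hu_clip: tuple[float, float] = DEFAULT_HU_CLIP,
) -> CTVolume:
    """Stats-free part of the chain: resample -> resize -> clip (still HU)."""
    return clip_hu(resize_slices(resample_isotropic(vol, target_spacing), size), *hu_clip)


def preprocess(
    vol: CTVolume,
    stats: NormalizationStats,
    target_spacing: float = DEFAULT_TARGET_SPACING_MM,
    size: int = DEFAULT_SLICE_SIZE_PX,
    hu_clip: tuple[float, float] = DEFAULT_HU_CLIP,
) -> PreprocessedVolume:
    """Full chain: resample -> resize -> clip -> normalize.

    Deterministic: identical inputs give bit-identical outputs.
    """
    out = normalize(prepare(vol, target_spacing, size, hu_clip), stats)
    return PreprocessedVolume(slices=out.voxels, patient_id=vol.patient_id)
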