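"""The four input formats used by the sanity tests.

From one (volume, mask, label) cohort, four datasets are derived:

* ``ORIGINAL_WP`` — the preprocessed volume with the target present;
* ``WOP`` — target voxels zeroed to 0 HU (water) before preprocessing;
* ``TARGET_ONLY`` — per-slice tight crop of the target, everything outside
  the mask zeroed, resized to the encoder input size; slices that do not
  intersect the mask are dropped;
* ``NOISE`` — the anatomy-free noise images of :mod:`sanityscan.noise`.

A separate classifier is trained per format, and each is evaluated on test
patients rendered in every format.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from ._interp import apply_along_axis_matrix, interp_matrix
from .errors import AlignmentError, ConfigurationError, EmptyTargetError, ParameterError
from .noise import PatchSelectionCriteria, generate_noise_volume
from .volume import (
    DEFAULT_SLICE_SIZE_PX,
    CTVolume,
    NormalizationStats,
    PreprocessedVolume,
    SegmentationMask,
    clip_hu,
    normalize,
    prepare,
    preprocess,
    resample_isotropic,
    resample_mask,
)

__all__ = [
    "InputFormat",
    "FormatDataset",
    "remove_target",
    "crop_target_only",
    "build_format_dataset",
]


class InputFormat(str, Enum):
    """Exactly four input formats exist."""

    ORIGINAL_WP = "wp"
    WOP = "wop"
    TARGET_ONLY = "target"
    NOISE = "noise"


MASK_REQUIRING_FORMATS = (InputFormat.WOP, InputFormat.TARGET_ONLY)


@dataclass(frozen=True)
class FormatDataset:
    """One preprocessed item per patient, all produced by one format pipeline."""

    format: InputFormat
    items: list  # of (PreprocessedVolume, int, str)

    @property
    def patient_ids(self) -> list[str]:
        return [pid for _, _, pid in self.items]

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab, _ in self.items], dtype=int)


def remove_target(vol: CTVolume, mask: SegmentationMask) -> CTVolume:
    """Zero the target region (mask == 1) in the HU domain.

    0 HU is the attenuation of water, matching how removal is displayed on
    a standard soft-tissue window.  Applied before preprocessing; inputs
    are never mutated.
    """
    mask.check_aligned(vol)
    out = vol.voxels.copy()
    out[mask.voxels.astype(bool)] = 0.0
    return CTVolume(voxels=out, spacing=vol.spacing, patient_id=vol.patient_id)


def crop_target_only(
    vol: CTVolume,
    mask: SegmentationMask,
    size: int = DEFAULT_SLICE_SIZE_PX,
    margin: int = 0,
) -> CTVolume:
    """Keep only the target: per-slice bounding-box crop resized to size x size.

    Only slices intersecting the mask are retained; within each slice the
    axis-aligned bounding box of the mask (plus ``margin`` voxels) is
    extracted, out-of-mask voxels inside the box are zeroed, and the box is
    resized with bilinear interpolation.
    """
    mask.check_aligned(vol)
    if size < 2:
        raise ParameterError("size must be at least 2")
    mvox = mask.voxels.astype(bool)
    keep = np.flatnonzero(mvox.any(axis=(1, 2)))
    if keep.size == 0:
        raise EmptyTargetError("mask is empty: nothing to crop")
    out = np.empty((keep.size, size, size))
    for k, t in enumerate(keep):
        m = mvox[t]
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        r0 = max(rows[0] - margin, 0)
        r1 = min(rows[-1] + margin + 1, m.shape[0])
        c0 = max(cols[0] - margin, 0)
        c1 = min(cols[-1] + margin + 1, m.shape[1])
        box = np.where(m[r0:r1, c0:c1], vol.voxels[t, r0:r1, c0:c1], 0.0)
        wr = interp_matrix(box.shape[0], size, "linear") if box.shape[0] != size else None
        wc = interp_matrix(box.shape[1], size, "linear") if box.shape[1] != size else None
        img = box
        if wr is not None:
            img = wr @ img
        if wc is not None:
            img = img @ wc.T
        out[k] = img
    if keep.size < 2:
        # a CTVolume needs >=2 slices; duplicate the single retained slice
        out = np.repeat(out, 2, axis=0)
    return CTVolume(
        voxels=out, spacing=(vol.spacing[0], 1.0, 1.0), patient_id=vol.patient_id
    )


def render_format(
    vol: CTVolume,
    mask: Optional[SegmentationMask],
    fmt: InputFormat,
    noise_criteria: PatchSelectionCriteria = PatchSelectionCriteria(),
    size: int = DEFAULT_SLICE_SIZE_PX,
    prepared: Optional[CTVolume] = None,
) -> np.ndarray:
    """Render one patient in one format on the HU scale (pre-normalization).

    ``prepared`` may carry a cached result of :func:`sanityscan.volume.prepare`
    for this volume; the WP and NOISE pipelines share it.
    """
    if fmt in MASK_REQUIRING_FORMATS and mask is None:
        raise ConfigurationError(f"format {fmt.value} requires a segmentation mask")
    if fmt is InputFormat.ORIGINAL_WP:
        prepared = prepared if prepared is not None else prepare(vol, size=size)
        return prepared.voxels
    if fmt is InputFormat.WOP:
        return prepare(remove_target(vol, mask), size=size).voxels
    if fmt is InputFormat.TARGET_ONLY:
        iso = resample_isotropic(vol)
        iso_mask = resample_mask(mask)
        cropped = crop_target_only(iso, iso_mask, size=size)
        return clip_hu(cropped).voxels
    if fmt is InputFormat.NOISE:
        prepared = prepared if prepared is not None else prepare(vol, size=size)
        return generate_noise_volume(prepared, noise_criteria, upsampled_size=size).slices
    raise ConfigurationError(f"unknown format {fmt}")


def build_format_dataset(
    cohort: Sequence,
    fmt: InputFormat,
    stats: NormalizationStats,
    noise_criteria: PatchSelectionCriteria = PatchSelectionCriteria(),
    size: int = DEFAULT_SLICE_SIZE_PX,
) -> FormatDataset:
    """Render a whole cohort in one format and z-score with training stats.

    ``cohort`` is a sequence of (CTVolume, SegmentationMask | None, label).
    ``stats`` must come from the training split of the same format.
    Deterministic: rerunning on the same cohort gives identical datasets.
    """
    items = []
    for vol, mask, label in cohort:
        slices = render_format(vol, mask, fmt, noise_criteria, size)
        normed = (slices - stats.mean) / stats.std
        items.append((PreprocessedVolume(slices=normed, patient_id=vol.patient_id), int(label), vol.patient_id))
    return FormatDataset(format=fmt, items=items)
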