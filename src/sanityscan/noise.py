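"""Noise-image generation from sequential CT slices.

A noise image summarizes a scan's noise texture with the anatomy removed:
adjacent axial slices are subtracted (shared anatomy cancels), a Sobel
gradient map flags residual structure, the difference image is tiled into
non-overlapping 30 x 30 patches, and only patches whose histogram looks
like homogeneous noise are kept — near-zero skewness, Pearson kurtosis
close to the Gaussian value 3, bounded standard deviation, and a single
histogram peak.  Selected patches are averaged into one 30 x 30 noise
image per difference image and upsampled with windowed-sinc interpolation
to the encoder input size.

The per-patient output stack has s - 1 slices for an s-slice source volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._interp import apply_along_axis_matrix, interp_matrix
from .errors import DegenerateDataError, InsufficientSlicesError, ParameterError
from .volume import CTVolume, PreprocessedVolume

__all__ = [
    "DifferenceImage",
    "PatchStats",
    "PatchSelectionCriteria",
    "NoiseVolume",
    "difference_images",
    "edge_suppress",
    "extract_patches",
    "patch_statistics",
    "select_uniform_patches",
    "average_patches",
    "generate_noise_volume",
]

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 30
DEFAULT_UPSAMPLED_SIZE = 299
DEFAULT_EDGE_QUANTILE = 0.90
DEFAULT_EDGE_PATCH_FRACTION = 0.10


@dataclass(frozen=True)
class DifferenceImage:
    """Subtraction of adjacent slices: D_t = I_t - I_{t-1}, 1 <= t < s."""

    pixels: np.ndarray
    index: int

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", arr)
        if arr.ndim != 2:
            raise ParameterError("a difference image is 2-D")
        if self.index < 1:
            raise ParameterError("difference-image index starts at 1")


@dataclass(frozen=True)
class PatchStats:
    """First-order histogram statistics of one patch.

    Kurtosis is the Pearson (non-excess) fourth standardized moment, so a
    Gaussian patch scores 3.0.  ``degenerate`` marks zero-variance patches,
    which are never selected.
    """

    skewness: float
    kurtosis: float
    std: float
    n_peaks: int
    degenerate: bool = False


@dataclass(frozen=True)
class PatchSelectionCriteria:
    """Acceptance bounds for 'uniform noise' patches.

    ``std_max`` is on the HU-difference scale of the unnormalized volume;
    if noise generation runs on z-scored inputs, rescale it by the
    training std.
    """

    skew_bound: float = 0.1
    kurtosis_center: float = 3.0
    kurtosis_tol: float = 0.5
    std_max: float = 16.0
    max_peaks: int = 1
    patch_size: int = DEFAULT_PATCH_SIZE
    edge_quantile: float = DEFAULT_EDGE_QUANTILE
    edge_patch_fraction: float = DEFAULT_EDGE_PATCH_FRACTION

    def __post_init__(self):
        if self.patch_size < 2:
            raise ParameterError("patch_size must be at least 2")
        if min(self.skew_bound, self.kurtosis_tol, self.std_max) <= 0:
            raise ParameterError("selection bounds must be positive")


@dataclass(frozen=True)
class NoiseVolume:
    """Stack of s - 1 upsampled noise images for one patient."""

    slices: np.ndarray
    patient_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.slices, dtype=float)
        object.__setattr__(self, "slices", arr)
        if arr.ndim != 3:
            raise ParameterError("noise slices must form a 3-D stack")


def _slice_stack(vol) -> np.ndarray:
    if isinstance(vol, CTVolume):
        return vol.voxels
    if isinstance(vol, PreprocessedVolume):
        return vol.slices
    return np.asarray(vol, dtype=float)


def difference_images(vol) -> list[DifferenceImage]:
    """Subtract adjacent slices: s slices give s - 1 difference images."""
    stack = _slice_stack(vol)
    if stack.shape[0] < 2:
        raise InsufficientSlicesError("need at least 2 slices to difference")
    diffs = np.diff(stack, axis=0)
    return [DifferenceImage(pixels=diffs[t - 1], index=t) for t in range(1, stack.shape[0])]


def _sobel_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.sobel(img, axis=0, mode="reflect")
    gy = ndimage.sobel(img, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def edge_suppress(
    d: DifferenceImage, threshold_quantile: float = DEFAULT_EDGE_QUANTILE
) -> np.ndarray:
    """Flag residual structure: Sobel magnitude above an image quantile.

    Returns a boolean exclusion map; downstream, patches whose flagged
    fraction exceeds the tolerated fraction are dropped.  An all-zero
    difference image flags nothing.
    """
    mag = _sobel_magnitude(d.pixels)
    if not np.any(mag > 0):
        return np.zeros_like(mag, dtype=bool)
    thr = np.quantile(mag, threshold_quantile)
    return mag > thr


def extract_patches(d: DifferenceImage, size: int = DEFAULT_PATCH_SIZE) -> list[np.ndarray]:
    """Tile the image into non-overlapping size x size patches.

    The grid is anchored at the top-left corner; trailing remainders
    smaller than one patch are discarded (a 299 x 299 image yields
    9 x 9 = 81 patches at the default size).
    """
    if size < 2:
        raise ParameterError("patch size must be at least 2")
    img = d.pixels
    ny, nx = img.shape[0] // size, img.shape[1] // size
    return [
        img[i * size : (i + 1) * size, j * size : (j + 1) * size]
        for i in range(ny)
        for j in range(nx)
    ]


def _count_histogram_peaks(values: np.ndarray) -> int:
    """Count local maxima of a lightly smoothed value histogram.

    Freedman-Diaconis bin width, 3-bin moving-average smoothing, and a peak
    is a strict local maximum above 5% of the modal count.  Plateau maxima
    (equal neighbouring bins) count once.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    vmin, vmax = v[0], v[-1]
    q25 = v[int(0.25 * (v.size - 1))]
    q75 = v[int(0.75 * (v.size - 1))]
    iqr = q75 - q25
    if iqr <= 0:
        width = (vmax - vmin) / 10 or 1.0
    else:
        width = 2 * iqr / np.cbrt(v.size)
    nbins = int(np.clip(np.ceil((vmax - vmin) / width), 2, 128))
    scale = nbins / (vmax - vmin) if vmax > vmin else 1.0
    idx = np.minimum(((v - vmin) * scale).astype(np.int64), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    floor = 0.05 * smooth.max()
    padded = np.concatenate(([-np.inf], smooth, [-np.inf]))
    peaks = 0
    i = 1
    while i <= len(smooth):
        if padded[i] > padded[i - 1] and padded[i] >= floor:
            j = i
            while j + 1 <= len(smooth) and padded[j + 1] == padded[i]:
                j += 1
            if padded[j + 1] < padded[i]:
                peaks += 1
            i = j + 1
        else:
            i += 1
    return peaks


def patch_statistics(patch: np.ndarray, histogram_bins: int | None = None) -> PatchStats:
    """Moment-based skewness, Pearson kurtosis, sample std, and peak count."""
    v = np.asarray(patch, dtype=float).ravel()
    if v.size < 2:
        raise ParameterError("patch too small for statistics")
    mean = v.mean()
    centered = v - mean
    var = np.mean(centered**2)
    if var <= 1e-24:
        return PatchStats(0.0, 0.0, 0.0, 1, degenerate=True)
    std = float(np.sqrt(v.var(ddof=1)))
    m2 = var
    skew = float(np.mean(centered**3) / m2**1.5)
    kurt = float(np.mean(centered**4) / m2**2)
    n_peaks = _count_histogram_peaks(v)
    return PatchStats(skewness=skew, kurtosis=kurt, std=std, n_peaks=n_peaks)


def _passes(stats: PatchStats, crit: PatchSelectionCriteria) -> bool:
    return (
        not stats.degenerate
        and abs(stats.skewness) <= crit.skew_bound
        and abs(stats.kurtosis - crit.kurtosis_center) <= crit.kurtosis_tol
        and stats.std < crit.std_max
        and stats.n_peaks <= crit.max_peaks
    )


def select_uniform_patches(
    patches: Sequence[np.ndarray],
    criteria: PatchSelectionCriteria = PatchSelectionCriteria(),
    exclusion: np.ndarray | None = None,
    patch_offsets: Sequence[tuple[int, int]] | None = None,
) -> list[np.ndarray]:
    """Return the patches passing all four statistical criteria.

    If an ``exclusion`` map (from :func:`edge_suppress`) is given along with
    each patch's top-left offset, patches whose flagged-pixel fraction
    exceeds ``criteria.edge_patch_fraction`` are dropped first.  Selection
    is order-independent: it is a pure per-patch filter.
    """
    selected = []
    for k, patch in enumerate(patches):
        if exclusion is not None and patch_offsets is not None:
            i0, j0 = patch_offsets[k]
            size = patch.shape[0]
            frac = exclusion[i0 : i0 + size, j0 : j0 + size].mean()
            if frac > criteria.edge_patch_fraction:
                continue
        if _passes(patch_statistics(patch), criteria):
            selected.append(patch)
    return selected


def average_patches(patches: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of the selected patches."""
    if len(patches) == 0:
        raise DegenerateDataError("no qualifying patches to average")
    return np.mean(np.stack(patches), axis=0)


def _fast_moments(flat_patches: np.ndarray):
    """Vectorized mean/std/skew/kurt over rows of (n_patches, n_pix)."""
    npix = flat_patches.shape[1]
    mean = flat_patches.mean(axis=1, dtype=np.float64)
    c = flat_patches - mean[:, None].astype(flat_patches.dtype)
    c2 = c * c
    m2 = c2.mean(axis=1, dtype=np.float64)
    m3 = (c2 * c).mean(axis=1, dtype=np.float64)
    m4 = (c2 * c2).mean(axis=1, dtype=np.float64)
    std = np.sqrt(m2 * npix / (npix - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    return mean, std, skew, kurt, m2


def generate_noise_volume(
    vol,
    criteria: PatchSelectionCriteria = PatchSelectionCriteria(),
    upsampled_size: int = DEFAULT_UPSAMPLED_SIZE,
) -> NoiseVolume:
    """Full per-patient noise pipeline.

    For each of the s - 1 difference images: Sobel edge exclusion, patch
    tiling, statistical selection, averaging, and windowed-sinc upsampling
    to ``upsampled_size``.  If no patch qualifies for a difference image,
    the patch with the least Sobel energy is substituted (and the event
    logged) so the output always has s - 1 slices.
    """
    stack = _slice_stack(vol)
    if stack.shape[0] < 2:
        raise InsufficientSlicesError("need at least 2 slices")
    pid = getattr(vol, "patient_id", "")
    size = criteria.patch_size
    up = interp_matrix(size, upsampled_size, kernel="lanczos")
    ny, nx = stack.shape[1] // size, stack.shape[2] // size

    diffs = np.diff(np.asarray(stack, dtype=np.float32), axis=0)
    nt = diffs.shape[0]
    # batched per-slice Sobel magnitude (separable [1,2,1] x [-1,0,1])
    smooth = np.array([1.0, 2.0, 1.0], dtype=np.float32)
    deriv = np.array([1.0, 0.0, -1.0], dtype=np.float32)
    gx = ndimage.correlate1d(diffs, deriv, axis=1, mode="reflect")
    gx = ndimage.correlate1d(gx, smooth, axis=2, mode="reflect")
    gy = ndimage.correlate1d(diffs, deriv, axis=2, mode="reflect")
    gy = ndimage.correlate1d(gy, smooth, axis=1, mode="reflect")
    # squared Sobel magnitude: quantile thresholding is monotone-invariant
    mag2 = gx * gx
    mag2 += gy * gy

    def _tile(arr):
        return (
            arr[:, : ny * size, : nx * size]
            .reshape(nt, ny, size, nx, size)
            .transpose(0, 1, 3, 2, 4)
            .reshape(nt, ny * nx, size * size)
        )

    flat = _tile(diffs)
    mag_tiled = _tile(mag2)
    thr = np.quantile(mag2.reshape(nt, -1), criteria.edge_quantile, axis=1)
    zero_mag = ~np.any(mag2.reshape(nt, -1) > 0, axis=1)
    excl_frac = (mag_tiled > thr[:, None, None]).mean(axis=2)
    excl_frac[zero_mag] = 0.0

    mean, std, skew, kurt, m2 = _fast_moments(flat.reshape(-1, size * size))
    for arr in (mean, std, skew, kurt, m2):
        arr.shape = (nt, ny * nx)
    keep = (
        (excl_frac <= criteria.edge_patch_fraction)
        & (m2 > 1e-24)
        & (np.abs(skew) <= criteria.skew_bound)
        & (np.abs(kurt - criteria.kurtosis_center) <= criteria.kurtosis_tol)
        & (std < criteria.std_max)
    )
    # peak counting only on the moment survivors (the expensive predicate)
    for t, k in zip(*np.nonzero(keep)):
        if _count_histogram_peaks(flat[t, k]) > criteria.max_peaks:
            keep[t, k] = False

    out = np.empty((nt, upsampled_size, upsampled_size))
    for t in range(nt):
        if not np.any(keep[t]):
            sobel_energy = mag_tiled[t].sum(axis=1)
            fallback = int(np.argmin(sobel_energy))
            logger.warning(
                "patient %s, difference image %d: no qualifying patches; "
                "substituting the minimum-Sobel-energy patch",
                pid,
                t + 1,
            )
            noise30 = flat[t, fallback].reshape(size, size)
        else:
            noise30 = flat[t, keep[t]].mean(axis=0).reshape(size, size)
        out[t] = up @ noise30 @ up.T
    return NoiseVolume(slices=out, patient_id=pid)
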