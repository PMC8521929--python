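"""Synthetic CT-like phantom cohorts with injectable class-correlated confounds.

Each phantom is a thin axial slab of an abdomen-like HU volume: a
soft-tissue background with class-independent clutter structures, an
elliptical organ, and (for the positive class) a bright focal lesion
inside the organ.  The anatomy is constant along the slice axis — the
slab models a through-section of the organ over a few centimetres, the
regime in which adjacent CT slices share their anatomy — while the tissue
noise is independent per voxel.  Adjacent-slice subtraction therefore
cancels the anatomy exactly, and any class signal that survives the
noise-image pipeline on a confound-free cohort is a pipeline bug, not a
property of the data.

The segmentation mask marks organ union lesion.  Three optional confounds
can be tied to the class label, standing in for scanner/protocol
differences between data sources:

* ``texture_exponent_by_class`` — per-class spectral shaping of the tissue
  noise (power ~ f^-beta in-plane), mimicking reconstruction-kernel
  noise-texture differences;
* ``hu_offset_by_class`` — per-class global HU shift (calibration /
  contrast-phase differences);
* ``smoothing_sigma_by_class`` — per-class in-plane Gaussian smoothing
  (reconstruction smoothness differences).

With no confounds configured, the class-conditional distribution of every
voxel outside the lesion is identical by construction.

All randomness flows from ``numpy.random.SeedSequence``: the cohort seed is
spawned into one child sequence per phantom, so individual phantoms are
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .volume import CTVolume, SegmentationMask

__all__ = ["PhantomSpec", "PhantomCohort", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study-condition parameters for one phantom cohort.

    Geometry is in voxels of the native in-plane grid; intensities are HU.
    The default grid (12 slices of 128 x 128 at 1.25 x 1.0 x 1.0 mm)
    resamples to 15 isotropic slices, sized so that a full cross-format
    experiment runs on a single CPU in seconds per cohort.
    """

    grid: tuple[int, int, int] = (10, 128, 128)
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0)
    organ_center: tuple[float, float] = (64.0, 64.0)   # (row, col)
    organ_radii: tuple[float, float] = (16.0, 12.0)    # in-plane ellipse;
    # ~2% of the field of view, like an abdominal organ in a full scan —
    # target removal must be a small edit relative to the whole image
    organ_hu: float = 60.0
    organ_hu_jitter: float = 12.0      # per-patient enhancement variability
    background_hu: float = -80.0
    lesion_radius: float = 6.0         # in-plane voxels
    lesion_contrast_hu: float = 40.0
    lesion_contrast_jitter_frac: float = 0.4
    tissue_noise_std: float = 14.0     # HU
    edge_softness: float = 0.8         # in-plane Gaussian sigma on the anatomy
    center_jitter: tuple[float, float] = (10.0, 10.0)
    radius_jitter_frac: float = 0.10
    background_jitter_hu: float = 8.0
    clutter_blobs: int = 6             # class-independent background structures
    clutter_hu: tuple[float, float] = (10.0, 30.0)
    clutter_radius: tuple[float, float] = (6.0, 16.0)
    texture_exponent_by_class: Optional[tuple[float, float]] = None
    hu_offset_by_class: Optional[tuple[float, float]] = None
    smoothing_sigma_by_class: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.organ_radii) or self.lesion_radius <= 0:
            raise ParameterError("radii must be positive")
        if self.grid[0] < 2:
            raise ParameterError("the slab needs at least 2 slices")
        for ax in range(2):
            c, r = self.organ_center[ax], self.organ_radii[ax]
            n = self.grid[ax + 1]
            jit = self.center_jitter[ax]
            rmax = r * (1 + self.radius_jitter_frac)
            if c - jit - rmax < 0 or c + jit + rmax > n - 1:
                raise GeometryError(
                    f"organ (with jitter) does not fit inside the grid on "
                    f"in-plane axis {ax}"
                )


@dataclass(frozen=True)
class PhantomCohort:
    """A balanced two-class list of (volume, mask, label) with provenance."""

    items: list  # of (CTVolume, SegmentationMask, int)
    spec: PhantomSpec
    seed: int


def _ellipse(shape2d, center, radii):
    yy, xx = np.ogrid[: shape2d[0], : shape2d[1]]
    d = ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2
    return d <= 1.0


def _shaped_noise(shape, std, beta, rng):
    """In-plane white or spectrally shaped (power ~ f^-beta) Gaussian noise."""
    white = rng.standard_normal(shape)
    if beta is None or beta == 0.0:
        return std * white
    s, r, c = shape
    fy = np.fft.fftfreq(r)[:, None]
    fx = np.fft.rfftfreq(c)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = f.flat[np.abs(f).argsort(None)[1]]  # avoid the DC singularity
    amp = f ** (-beta / 2.0)
    spec = np.fft.rfft2(white, axes=(1, 2)) * amp[None, :, :]
    shaped = np.fft.irfft2(spec, s=(r, c), axes=(1, 2))
    shaped /= shaped.std()
    return std * shaped


def generate_phantom(
    spec: PhantomSpec, label: int, rng: np.random.Generator | None = None
) -> tuple[CTVolume, SegmentationMask]:
    """Generate one phantom volume and its target mask for a class label.

    The lesion is inserted iff ``label == 1``; the mask is organ union
    lesion (the whole target organ, lesion included).  The random stream is
    consumed identically for both labels, so phantoms generated from the
    same generator state differ only by the lesion contrast.
    """
    if label not in (0, 1):
        raise ParameterError("label must be 0 or 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    shape = spec.grid
    inplane = shape[1:]
    jit = np.array(spec.center_jitter)
    center = np.array(spec.organ_center) + rng.uniform(-jit, jit)
    radii = np.array(spec.organ_radii) * (
        1.0 + rng.uniform(-spec.radius_jitter_frac, spec.radius_jitter_frac, size=2)
    )
    organ2d = _ellipse(inplane, center, radii)

    # anatomy is a single in-plane image replicated along z (thin-slab model)
    anatomy2d = np.full(inplane, spec.background_hu + rng.uniform(
        -spec.background_jitter_hu, spec.background_jitter_hu))
    # class-independent background clutter: soft structures that make local
    # statistics and qualifying patch counts vary patient-to-patient
    for _ in range(spec.clutter_blobs):
        ccenter = rng.uniform((0.0, 0.0), np.array(inplane) - 1.0)
        cr = rng.uniform(*spec.clutter_radius)
        camp = rng.uniform(*spec.clutter_hu) * rng.choice((-1.0, 1.0))
        anatomy2d[_ellipse(inplane, ccenter, (cr, cr))] += camp
    anatomy2d[organ2d] = spec.organ_hu + rng.uniform(
        -spec.organ_hu_jitter, spec.organ_hu_jitter
    )

    lr = spec.lesion_radius
    frac = rng.uniform(-0.4, 0.4, size=2)
    jf = spec.lesion_contrast_jitter_frac
    contrast = spec.lesion_contrast_hu * (1.0 + rng.uniform(-jf, jf))
    lesion2d = np.zeros(inplane, dtype=bool)
    if label == 1:
        lcenter = center + frac * np.maximum(radii - lr, 0)
        lesion2d = organ2d & _ellipse(inplane, lcenter, (lr, lr))
        anatomy2d[lesion2d] += contrast

    if spec.edge_softness > 0:
        anatomy2d = ndimage.gaussian_filter(anatomy2d, sigma=spec.edge_softness)

    beta = None
    if spec.texture_exponent_by_class is not None:
        beta = float(spec.texture_exponent_by_class[label])
    noise = _shaped_noise(shape, spec.tissue_noise_std, beta, rng)
    voxels = anatomy2d[None, :, :] + noise

    if spec.smoothing_sigma_by_class is not None:
        sigma = float(spec.smoothing_sigma_by_class[label])
        if sigma > 0:
            voxels = ndimage.gaussian_filter(voxels, sigma=(0.0, sigma, sigma))
    if spec.hu_offset_by_class is not None:
        voxels = voxels + float(spec.hu_offset_by_class[label])

    mask2d = (organ2d | lesion2d).astype(np.uint8)
    mask = SegmentationMask(
        voxels=np.repeat(mask2d[None, :, :], shape[0], axis=0),
        spacing=spec.spacing,
    )
    vol = CTVolume(voxels=voxels, spacing=spec.spacing)
    return vol, mask


def generate_cohort(
    spec: PhantomSpec, n_per_class: int, seed: int | None = None
) -> PhantomCohort:
    """Generate a balanced cohort of 2 * n_per_class phantoms.

    Per-phantom generators are spawned from the cohort seed, so item k is
    reproducible without regenerating the rest of the cohort.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be at least 1")
    if seed is None:
        seed = spec.seed
    children = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    items = []
    k = 0
    for label in (0, 1):
        for i in range(n_per_class):
            rng = np.random.default_rng(children[k])
            vol, mask = generate_phantom(spec, label, rng)
            pid = f"phantom-{label}-{i:03d}"
            vol = CTVolume(voxels=vol.voxels, spacing=vol.spacing, patient_id=pid)
            items.append((vol, mask, label))
            k += 1
    return PhantomCohort(items=items, spec=spec, seed=seed)
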