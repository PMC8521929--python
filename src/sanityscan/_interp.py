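"""Separable 1-D interpolation matrices for volume resampling and slice resizing.

Resampling a regular grid with a separable kernel reduces, per axis, to a
dense (n_out, n_in) weight matrix applied along that axis.  Building the
matrix once and applying it with a matrix product is orders of magnitude
faster on small medical volumes than generic per-voxel resamplers, and the
weights are trivially auditable.

Two kernels are provided:

* ``linear`` — bilinear interpolation when applied along both in-plane axes.
* ``lanczos`` — windowed sinc, sinc(x)*sinc(x/a) for |x| < a (Lanczos
  window, default radius a = 3), the standard realization of sinc
  interpolation on a finite grid.

Coordinate convention: sample i of a signal with spacing h sits at physical
position (i + 0.5) * h (pixel-center / half-sample convention).  Output
sample j of the resized signal maps to input index
u_j = (j + 0.5) * n_in / n_out - 0.5, which preserves the physical extent
and reduces to the identity when n_out == n_in.  Out-of-range taps are
clamped to the edge sample and each row is renormalized to sum to one, so
constants are reproduced exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lanczos_kernel", "interp_matrix", "apply_along_axis_matrix"]


def lanczos_kernel(x: np.ndarray, a: int = 3) -> np.ndarray:
    """Lanczos-windowed sinc kernel: sinc(x) * sinc(x / a) on |x| < a."""
    x = np.asarray(x, dtype=float)
    out = np.sinc(x) * np.sinc(x / a)
    return np.where(np.abs(x) < a, out, 0.0)


def _kernel(name: str, a: int):
    if name == "linear":
        return (lambda x: np.clip(1.0 - np.abs(x), 0.0, None)), 1
    if name == "lanczos":
        return (lambda x: lanczos_kernel(x, a)), a
    if name == "nearest":
        # box kernel of width 1; ties broken toward the lower index
        return (lambda x: ((x > -0.5) & (x <= 0.5)).astype(float)), 1
    raise ValueError(f"unknown interpolation kernel {name!r}")


def interp_matrix(n_in: int, n_out: int, kernel: str = "linear", a: int = 3) -> np.ndarray:
    """Build the (n_out, n_in) weight matrix resizing a length-n_in signal.

    Rows sum to one; when ``n_out == n_in`` the matrix is the identity for
    every kernel (all kernels interpolate: k(0)=1, k(m)=0 for integer m!=0).
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("signal lengths must be positive")
    kern, radius = _kernel(kernel, a)
    u = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5  # input-index coords
    base = np.floor(u).astype(int)
    offsets = np.arange(-radius + 1, radius + 1)
    taps = base[:, None] + offsets[None, :]              # (n_out, 2*radius)
    w = kern(u[:, None] - taps)
    w /= w.sum(axis=1, keepdims=True)
    taps = np.clip(taps, 0, n_in - 1)                    # edge clamp
    mat = np.zeros((n_out, n_in))
    np.add.at(mat, (np.repeat(np.arange(n_out), taps.shape[1]), taps.ravel()), w.ravel())
    return mat


def apply_along_axis_matrix(arr: np.ndarray, mat: np.ndarray, axis: int) -> np.ndarray:
    """Apply an (n_out, n_in) interpolation matrix along ``axis`` of ``arr``."""
    moved = np.moveaxis(arr, axis, -1)
    out = moved @ mat.T
    return np.moveaxis(out, -1, axis)
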