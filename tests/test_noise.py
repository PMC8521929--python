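"""Noise-image pipeline: differencing, edge exclusion, patch statistics, selection."""

import numpy as np
import pytest
from scipy import stats as sps

from sanityscan import (
    DifferenceImage,
    PatchSelectionCriteria,
    average_patches,
    difference_images,
    edge_suppress,
    extract_patches,
    generate_noise_volume,
    patch_statistics,
    select_uniform_patches,
)
from sanityscan.errors import DegenerateDataError, InsufficientSlicesError
from sanityscan.volume import CTVolume


# ---------------------------------------------------------------------------
# Difference images
# ---------------------------------------------------------------------------

def test_difference_images_count_and_values(rng):
    stack = rng.normal(size=(10, 40, 40))
    diffs = difference_images(stack)
    assert len(diffs) == 9
    for t, d in enumerate(diffs, start=1):
        assert d.index == t
        np.testing.assert_allclose(d.pixels, stack[t] - stack[t - 1])


def test_difference_images_constant_volume_all_zero():
    diffs = difference_images(np.full((5, 8, 8), 3.0))
    for d in diffs:
        assert np.all(d.pixels == 0.0)


def test_difference_images_ramp_gives_constant():
    c = 2.5
    stack = np.arange(6)[:, None, None] * c * np.ones((6, 8, 8))
    for d in difference_images(stack):
        np.testing.assert_allclose(d.pixels, c)


def test_difference_images_needs_two_slices():
    with pytest.raises(InsufficientSlicesError):
        difference_images(np.zeros((1, 8, 8)))


# ---------------------------------------------------------------------------
# Edge suppression
# ---------------------------------------------------------------------------

def test_edge_suppress_zero_image_flags_nothing():
    d = DifferenceImage(np.zeros((60, 60)), index=1)
    assert not edge_suppress(d).any()


def test_edge_suppress_white_noise_flag_rate(rng):
    d = DifferenceImage(rng.normal(size=(120, 120)), index=1)
    flagged = edge_suppress(d, threshold_quantile=0.90)
    # by construction the quantile flags ~10% of pixels on featureless noise
    assert abs(flagged.mean() - 0.10) < 0.02


def test_edge_suppress_step_edge_is_flagged(rng):
    img = np.zeros((90, 90)) + 0.01 * rng.normal(size=(90, 90))
    img[:, 45:] += 50.0  # ideal vertical step
    flagged = edge_suppress(DifferenceImage(img, index=1))
    # the Sobel response of an ideal step concentrates on the two columns
    # adjacent to the discontinuity; those are flagged completely, while
    # the quantile rule flags at most ~10% of the remaining noise pixels
    assert flagged[:, 44].mean() == 1.0
    assert flagged[:, 45].mean() == 1.0
    assert flagged[:, :40].mean() < 0.15


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

def test_patch_grid_combinatorics(rng):
    d = DifferenceImage(rng.normal(size=(299, 299)), index=1)
    patches = extract_patches(d, size=30)
    assert len(patches) == 81  # floor(299/30)^2
    assert all(p.shape == (30, 30) for p in patches)


def test_single_patch_equals_image(rng):
    img = rng.normal(size=(30, 30))
    patches = extract_patches(DifferenceImage(img, index=1), size=30)
    assert len(patches) == 1
    np.testing.assert_array_equal(patches[0], img)


def test_undersized_image_gives_empty_list(rng):
    d = DifferenceImage(rng.normal(size=(20, 20)), index=1)
    assert extract_patches(d, size=30) == []


def test_patches_tile_without_overlap(rng):
    img = np.arange(90 * 90, dtype=float).reshape(90, 90)
    patches = extract_patches(DifferenceImage(img, index=1), size=30)
    seen = np.concatenate([p.ravel() for p in patches])
    assert len(seen) == len(np.unique(seen))  # no pixel reused


# ---------------------------------------------------------------------------
# Patch statistics
# ---------------------------------------------------------------------------

def test_gaussian_patch_statistics_match_direct_formulas(rng):
    for _ in range(5):
        p = rng.normal(0, 5, size=(30, 30))
        st = patch_statistics(p)
        v = p.ravel()
        assert st.skewness == pytest.approx(sps.skew(v), abs=1e-10)
        assert st.kurtosis == pytest.approx(sps.kurtosis(v, fisher=False), abs=1e-10)
        assert st.std == pytest.approx(v.std(ddof=1), abs=1e-10)


def test_gaussian_patches_usually_within_selection_bounds(rng):
    hits = 0
    n = 200
    for _ in range(n):
        st = patch_statistics(rng.normal(0, 5, size=(30, 30)))
        if abs(st.skewness) <= 0.1 and abs(st.kurtosis - 3.0) <= 0.5:
            hits += 1
    assert hits / n > 0.6  # most Gaussian patches look Gaussian


def test_constant_patch_is_degenerate():
    st = patch_statistics(np.full((30, 30), 2.0))
    assert st.degenerate
    sel = select_uniform_patches([np.full((30, 30), 2.0)])
    assert sel == []


def test_two_component_mixture_has_two_peaks(rng):
    a = 10.0
    p = np.concatenate(
        [np.full(450, -a), np.full(450, +a)]
    ) + 0.3 * rng.normal(size=900)
    st = patch_statistics(p.reshape(30, 30))
    assert st.n_peaks == 2


def test_single_gaussian_has_one_peak(rng):
    st = patch_statistics(rng.normal(size=(30, 30)))
    assert st.n_peaks == 1


# ---------------------------------------------------------------------------
# Selection and averaging
# ---------------------------------------------------------------------------

def _brute_force_filter(patches, crit):
    out = []
    for p in patches:
        v = p.ravel()
        if v.std() == 0:
            continue
        skew = sps.skew(v)
        kurt = sps.kurtosis(v, fisher=False)
        std = v.std(ddof=1)
        npeaks = patch_statistics(p).n_peaks
        if (
            abs(skew) <= crit.skew_bound
            and abs(kurt - crit.kurtosis_center) <= crit.kurtosis_tol
            and std < crit.std_max
            and npeaks <= crit.max_peaks
        ):
            out.append(p)
    return out


def test_selection_empty_input():
    assert select_uniform_patches([]) == []


def test_selection_matches_brute_force_on_constructed_patches(rng):
    """100 patches straddling every bound vs an independent filter."""
    crit = PatchSelectionCriteria()
    patches = []
    for i in range(100):
        kind = i % 5
        if kind == 0:  # plain Gaussian, should mostly pass
            p = rng.normal(0, 8, size=(30, 30))
        elif kind == 1:  # high std, must fail std<16
            p = rng.normal(0, 30, size=(30, 30))
        elif kind == 2:  # skewed (exponential), must fail |skew|<=0.1
            p = rng.exponential(5, size=(30, 30))
        elif kind == 3:  # heavy-tailed, should fail kurtosis
            p = rng.standard_t(3, size=(30, 30)) * 5
        else:  # bimodal, must fail the single-peak rule
            p = np.concatenate(
                [np.full(450, -10.0), np.full(450, 10.0)]
            ).reshape(30, 30) + 0.3 * rng.normal(size=(30, 30))
        patches.append(p)
    selected = select_uniform_patches(patches, crit)
    expected = _brute_force_filter(patches, crit)
    assert len(selected) == len(expected)
    for s, e in zip(selected, expected):
        np.testing.assert_array_equal(s, e)


def test_selection_order_independent(rng):
    patches = [rng.normal(0, 8, size=(30, 30)) for _ in range(40)]
    sel_fwd = select_uniform_patches(patches)
    sel_rev = select_uniform_patches(patches[::-1])
    key = lambda plist: sorted(p.tobytes() for p in plist)
    assert key(sel_fwd) == key(sel_rev)


def test_average_patches_identity_and_symmetry(rng):
    p = rng.normal(size=(30, 30))
    np.testing.assert_array_equal(average_patches([p]), p)
    np.testing.assert_allclose(average_patches([p, -p]), 0.0, atol=1e-15)
    with pytest.raises(DegenerateDataError):
        average_patches([])


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _noise_phantom(rng, s=6, n=120, std=8.0):
    return CTVolume(
        rng.normal(0, std, size=(s, n, n)), spacing=(1.0, 1.0, 1.0)
    )


def test_noise_volume_shape_and_determinism(rng):
    vol = _noise_phantom(rng)
    nv1 = generate_noise_volume(vol, upsampled_size=299)
    nv2 = generate_noise_volume(vol, upsampled_size=299)
    assert nv1.slices.shape == (5, 299, 299)
    np.testing.assert_array_equal(nv1.slices, nv2.slices)


def test_noise_volume_std_matches_difference_arithmetic(rng):
    """Independent Gaussian slices: difference std is sqrt(2) * slice std.

    The per-pixel std of the averaged noise image is the difference std
    shrunk by the number of averaged patches; we check the patch-level std
    seen by the selector instead, which is pure variance arithmetic.
    """
    std = 6.0
    vol = _noise_phantom(rng, s=8, std=std)
    diffs = difference_images(vol)
    patch_stds = [
        patch_statistics(p).std
        for d in diffs
        for p in extract_patches(d, 30)
    ]
    assert np.median(patch_stds) == pytest.approx(np.sqrt(2) * std, rel=0.05)


def test_noise_volume_fallback_on_hopeless_image(rng, caplog):
    # steep global gradient: every patch fails the selection criteria
    ramp = np.linspace(0, 4000, 120)[None, None, :] * np.ones((3, 120, 1))
    vol = CTVolume(ramp + rng.normal(0, 100, size=(3, 120, 120)), spacing=(1, 1, 1))
    import logging

    with caplog.at_level(logging.WARNING, logger="sanityscan.noise"):
        nv = generate_noise_volume(vol, upsampled_size=64)
    assert nv.slices.shape[0] == 2  # cardinality preserved
    assert any("no qualifying patches" in r.message for r in caplog.records)


def test_structure_does_not_leak_into_noise_images(rng):
    """Adding a high-contrast object leaves the noise output distribution
    statistically indistinguishable from the object-free phantom."""
    base = rng.normal(0, 8, size=(6, 120, 120))
    vol_plain = CTVolume(base.copy(), spacing=(1, 1, 1))
    with_obj = base.copy()
    for t in range(6):  # high-contrast object whose boundary drifts slice to
        with_obj[t, 40:80, 40 + 2 * t : 80 + 2 * t] += 120.0  # slice, like anatomy
    vol_obj = CTVolume(with_obj, spacing=(1, 1, 1))
    nv_plain = generate_noise_volume(vol_plain, upsampled_size=64)
    nv_obj = generate_noise_volume(vol_obj, upsampled_size=64)
    # the object is static across slices so differencing cancels it; edge
    # and selection rules must remove any residual boundary structure
    stat = sps.ks_2samp(
        nv_plain.slices.ravel()[::7], nv_obj.slices.ravel()[::7]
    )
    assert stat.pvalue > 0.01
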