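"""Adaptive thresholding, thinning and the density variants."""

import numpy as np
import pytest
from scipy import ndimage

from octava.errors import DegenerateImageError, ParameterError
from octava.vessel_density import (
    BinaryMask,
    binarize,
    otsu_threshold,
    skeletonize,
    vd_binary,
    vd_original,
    vd_proposed,
    vd_skel_baseline,
    vd_weighted,
    vessel_density,
)


def brute_force_otsu(image):
    """Independent oracle: exhaustive within-class variance minimisation.

    Same class convention as the implementation ({< t} vs {>= t}), computed
    the slow way from the raw pixel sets.
    """
    arr = np.round(np.asarray(image)).astype(int)
    n = arr.size
    best, best_t = np.inf, None
    for t in range(256):
        lo = arr[arr < t]
        hi = arr[arr >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        s = (lo.size * lo.var() + hi.size * hi.var()) / n
        if s < best - 1e-12:
            best, best_t = s, t
    return best_t


class TestOtsu:
    def test_two_level_image_smallest_minimizer(self):
        img = np.zeros((10, 10))
        img[:5] = 200
        assert otsu_threshold(img) == 1

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 37.0))

    def test_matches_exhaustive_oracle_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            img = rng.integers(0, 256, size=(32, 32)).astype(float)
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_bimodal_threshold_separates_modes(self):
        rng = np.random.default_rng(8)
        img = np.where(rng.random((64, 64)) < 0.3,
                       rng.normal(200, 10, (64, 64)),
                       rng.normal(50, 10, (64, 64)))
        t = otsu_threshold(np.clip(img, 0, 255))
        assert 80 < t < 180


class TestBinarize:
    @pytest.mark.parametrize(
        "t,expected_frac",
        [(255, 0.0), (-1, 1.0)],
    )
    def test_extreme_thresholds(self, t, expected_frac):
        img = np.arange(100).reshape(10, 10).astype(float)
        assert binarize(img, t).grid.mean() == expected_frac

    def test_checkerboard_keeps_bright_cells(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        mask = binarize(img, 128)
        assert (mask.grid == (img == 255)).all()


def _n_components(grid):
    return ndimage.label(grid, structure=np.ones((3, 3)))[1]


class TestSkeletonize:
    def test_empty_mask(self):
        assert skeletonize(np.zeros((10, 10), bool)).pixel_count == 0

    def test_thin_line_unchanged_endpoints_preserved(self):
        line = np.zeros((5, 24), bool)
        line[2, 2:22] = True
        assert (skeletonize(line).grid == line).all()

    def test_filled_rectangle_thins_to_single_width1_curve(self):
        rect = np.zeros((9, 25), bool)
        rect[2:7, 2:23] = True
        skel = skeletonize(rect).grid
        assert _n_components(skel) == 1
        # width 1: no 2x2 solid block anywhere
        assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()
        # curve-like: almost every pixel has <= 2 neighbours, with a few
        # junction pixels allowed at the end artefacts of the rectangle
        nbr = ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                               mode="constant")[skel] - 1
        assert (nbr <= 4).all()
        assert (nbr > 2).sum() <= 8  # two Y-shaped end artefacts

    def test_properties_on_random_blobs(self, random_blobs):
        """Subset, idempotence and component-count preservation."""
        for blob in random_blobs:
            skel = skeletonize(blob).grid
            assert not (skel & ~blob).any()
            assert (skeletonize(skel).grid == skel).all()
            assert _n_components(skel) == _n_components(blob)


class TestVesselDensity:
    @pytest.mark.parametrize(
        "p,dims,expected",
        [(0, (10, 10), 0.0), (100, (10, 10), 100.0), (1024, (320, 320), 1.0)],
    )
    def test_pixel_fraction(self, p, dims, expected):
        grid = np.zeros(dims, bool)
        grid.ravel()[:p] = True
        assert vessel_density(grid) == pytest.approx(expected)

    def test_skeleton_density_not_above_mask_density(self, random_blobs):
        for blob in random_blobs[:10]:
            skel = skeletonize(blob)
            assert vessel_density(skel, dims=blob.shape) <= vessel_density(blob)


class TestBaselineVariants:
    def test_original_is_intensity_mass(self):
        assert vd_original(np.zeros((4, 4))) == 0.0
        assert vd_original(np.full((4, 4), 255.0)) == 100.0
        assert vd_original(np.full((4, 4), 51.0)) == pytest.approx(20.0)

    def test_binary_counts_pixels_above_threshold(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        assert vd_binary(img, 255) == 0.0
        assert vd_binary(img, 128) == 50.0
        rng = np.random.default_rng(5)
        noisy = rng.integers(0, 256, (16, 16)).astype(float)
        assert vd_binary(noisy, 100) == pytest.approx(
            100.0 * (noisy > 100).sum() / noisy.size
        )

    def test_weighted_interpolates_below_threshold(self):
        assert vd_weighted(np.full((4, 4), 200.0), 128) == 100.0
        assert vd_weighted(np.zeros((4, 4)), 128) == 0.0
        assert vd_weighted(np.full((4, 4), 64.0), 128) == pytest.approx(50.0)

    def test_skel_baseline_equals_proposed_at_otsu_threshold(self, vessel_sample):
        img = vessel_sample.image
        t = otsu_threshold(img)
        _, _, vd = vd_proposed(img)
        assert vd_skel_baseline(img, t) == pytest.approx(vd)

    def test_skel_baseline_empty_after_threshold(self):
        assert vd_skel_baseline(np.full((8, 8), 10.0), 200) == 0.0

    def test_lattice_unchanged_by_thinning(self):
        img = np.zeros((33, 33))
        img[::8, :] = 255
        lattice_frac = 100.0 * (img > 128).sum() / img.size
        assert vd_skel_baseline(img, 128) == pytest.approx(lattice_frac)

    def test_invalid_thresholds_rejected(self):
        img = np.zeros((4, 4))
        with pytest.raises(ParameterError):
            vd_binary(img, 300)
        with pytest.raises(ParameterError):
            vd_weighted(img, 0)


class TestProposedPipeline:
    def test_recovers_true_centerline_density(self, density_target_samples):
        s = density_target_samples[4.0]
        _, _, vd = vd_proposed(s.image)
        true = s.true_quadrant_density["global"]
        assert abs(vd - true) / true <= 0.25

    def test_monotone_in_target_density(self, density_target_samples):
        vds = [vd_proposed(density_target_samples[t].image)[2]
               for t in (1.0, 2.0, 4.0)]
        assert vds[0] < vds[1] < vds[2]

    def test_robust_to_brightness_shift(self, vessel_sample):
        """Global +40 gray levels barely moves the adaptive-threshold VD."""
        img = vessel_sample.image
        _, _, v0 = vd_proposed(img)
        shifted = np.clip(img.astype(int) + 40, 0, 255).astype(np.uint8)
        _, _, v1 = vd_proposed(shifted)
        assert abs(v1 - v0) / v0 <= 0.10

    def test_noise_free_background_below_vessel_fixtures(
        self, density_target_samples
    ):
        from octava.synthetic_octa import SyntheticParams, generate_vessel_image

        bg = generate_vessel_image(
            SyntheticParams(target_density=0.0, noise_sigma=0.0, seed=13)
        )
        assert bg.true_centerlines.sum() == 0
        _, _, v_bg = vd_proposed(bg.image)
        for t, s in density_target_samples.items():
            assert v_bg < vd_proposed(s.image)[2]

    def test_degenerate_image_propagates(self):
        with pytest.raises(DegenerateImageError):
            vd_proposed(np.zeros((16, 16)))
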