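"""FAZ enhancement, candidate detection, selection, growth and area."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octava.errors import NoFazError, ParameterError
from octava.faz_segmentation import (
    FazConfig,
    compute_faz_area,
    detect_avascular_candidates,
    enhance_tophat,
    region_growing_refine,
    segment_faz,
    select_faz_region,
)
from octava.image_io import AngioImage

from .conftest import as_angio


def dice(a, b):
    return 2.0 * (a & b).sum() / max(a.sum() + b.sum(), 1)


class TestEnhanceTophat:
    def test_constant_image_maps_to_zero(self):
        out = enhance_tophat(np.full((32, 32), 80.0), FazConfig())
        assert (out == 0).all()

    def test_single_bright_pixel_preserved(self):
        img = np.zeros((32, 32))
        img[10, 12] = 200
        out = enhance_tophat(img, FazConfig(tophat_radius_px=5))
        assert out[10, 12] == 200

    def test_vessel_background_contrast_increases(self, vessel_sample):
        cfg = FazConfig()
        arr = vessel_sample.image.astype(float)
        enh = enhance_tophat(arr, cfg)
        on = vessel_sample.true_centerlines

        def contrast(a):
            return a[on].mean() / max(a[~on].mean(), 1e-9)

        assert contrast(enh) > contrast(arr)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ParameterError):
            enhance_tophat(np.zeros((16, 16)), FazConfig(tophat_radius_px=20))


class TestDetectCandidates:
    def test_flat_image_yields_frame_covering_candidate(self):
        labels, nlab = detect_avascular_candidates(
            np.zeros((100, 100)), FazConfig()
        )
        assert nlab == 1
        assert (labels == 1).sum() == 100 * 100

    def test_candidate_centroid_near_disk_center(self, vessel_sample):
        from scipy import ndimage

        cfg = FazConfig()
        enh = enhance_tophat(vessel_sample.image.astype(float), cfg)
        labels, nlab = detect_avascular_candidates(enh, cfg)
        assert nlab >= 1
        best = min(
            range(1, nlab + 1),
            key=lambda lab: np.hypot(
                *(np.array(ndimage.center_of_mass(labels == lab)) - 159.5)
            ),
        )
        cy, cx = ndimage.center_of_mass(labels == best)
        assert np.hypot(cy - 159.5, cx - 159.5) <= 5.0

    def test_dense_lattice_leaves_no_candidate(self):
        """Grid cells smaller than min_region_px all get filtered out."""
        cfg = FazConfig()
        img = np.zeros((320, 320))
        img[::12, :] = 255
        img[:, ::12] = 255
        labels, nlab = detect_avascular_candidates(enhance_tophat(img, cfg), cfg)
        assert nlab == 0


class TestSelectRegion:
    def test_single_candidate_returned(self):
        labels = np.zeros((50, 50), int)
        labels[5:15, 5:15] = 1
        assert select_faz_region(labels, (24.5, 24.5)) == 1

    def test_equal_area_centered_wins(self):
        labels = np.zeros((51, 51), int)
        labels[23:28, 23:28] = 1  # centred 5x5
        labels[0:5, 0:5] = 2  # corner 5x5
        assert select_faz_region(labels, (25.0, 25.0)) == 1

    def test_score_formula_decides_between_area_and_distance(self):
        """Exhaustive evaluation of area / (1 + lambda d) off-centre."""
        labels = np.zeros((200, 200), int)
        labels[90:110, 120:170] = 1  # area 1000, centroid (99.5, 144.5)
        labels[0:40, 0:100] = 2  # area 4000, centroid (19.5, 49.5)
        center = (99.5, 99.5)
        lam = 0.01
        scores = {}
        for lab in (1, 2):
            cy, cx = np.argwhere(labels == lab).mean(axis=0)
            d = np.hypot(cy - center[0], cx - center[1])
            scores[lab] = (labels == lab).sum() / (1 + lam * d)
        expected = max(scores, key=scores.get)
        assert select_faz_region(labels, center, lam) == expected

    def test_empty_label_map_raises(self):
        with pytest.raises(NoFazError):
            select_faz_region(np.zeros((10, 10), int), (4.5, 4.5))


class TestRegionGrowing:
    def test_zero_tolerance_fills_constant_plateau(self):
        img = np.zeros((20, 20))
        img[5:10, 5:10] = 7
        img[5:10, 10:15] = 9
        seed = np.zeros((20, 20), bool)
        seed[6:9, 6:9] = True
        grown = region_growing_refine(img, seed, FazConfig(growth_tolerance=0))
        assert (grown == (img == 7)).all()

    def test_full_tolerance_floods_uniform_image(self):
        seed = np.zeros((15, 15), bool)
        seed[7, 7] = True
        grown = region_growing_refine(
            np.full((15, 15), 5.0), seed, FazConfig(growth_tolerance=255)
        )
        assert grown.all()

    def test_result_contains_seed(self, vessel_sample):
        seed = vessel_sample.true_faz_mask.copy()
        grown = region_growing_refine(
            vessel_sample.image.astype(float), seed, FazConfig()
        )
        assert (grown | ~seed).all()

    def test_empty_seed_rejected(self):
        with pytest.raises(ParameterError):
            region_growing_refine(np.zeros((10, 10)), np.zeros((10, 10), bool),
                                  FazConfig())


class TestComputeArea:
    def test_full_mask_is_fov_squared(self):
        assert compute_faz_area(np.ones((320, 320), bool), 3) == 9.0

    def test_pixel_count_conversion(self):
        mask = np.zeros((320, 320), bool)
        mask.ravel()[:10240] = True
        assert compute_faz_area(mask, 3) == pytest.approx(0.9)

    def test_disk_phantom_close_to_analytic_area(self):
        yy, xx = np.mgrid[0:320, 0:320]
        disk = np.hypot(yy - 159.5, xx - 159.5) <= 40
        analytic = np.pi * 40**2 * 9 / 320**2
        assert compute_faz_area(disk, 3) == pytest.approx(analytic, rel=0.02)

    @given(
        p=st.integers(min_value=0, max_value=64 * 64),
        fov=st.sampled_from([3, 6]),
    )
    @settings(max_examples=50, deadline=None)
    def test_area_inverts_to_exact_pixel_count(self, p, fov):
        mask = np.zeros((64, 64), bool)
        mask.ravel()[:p] = True
        area = compute_faz_area(mask, fov)
        assert area * 64 * 64 / fov**2 == pytest.approx(p, abs=1e-9)

    def test_scale_equivariance_on_upsampled_mask(self):
        yy, xx = np.mgrid[0:160, 0:160]
        disk = np.hypot(yy - 79.5, xx - 79.5) <= 30
        up = np.kron(disk, np.ones((2, 2), bool))
        assert compute_faz_area(up, 3) == pytest.approx(
            compute_faz_area(disk, 3)
        )


class TestSegmentFaz:
    def test_recovery_within_tolerance(self, faz_radius_samples):
        for r, s in faz_radius_samples.items():
            res = segment_faz(as_angio(s))
            truth = compute_faz_area(s.true_faz_mask, 3)
            assert res.area_mm2 == pytest.approx(truth, rel=0.15)
            assert dice(res.mask, s.true_faz_mask) >= 0.85

    def test_areas_strictly_increase_with_radius(self, faz_radius_samples):
        areas = [segment_faz(as_angio(faz_radius_samples[r])).area_mm2
                 for r in (0.2, 0.3, 0.4, 0.5)]
        assert areas == sorted(areas) and len(set(areas)) == 4

    def test_deterministic(self, faz_radius_samples):
        img = as_angio(faz_radius_samples[0.3])
        a, b = segment_faz(img), segment_faz(img)
        assert (a.mask == b.mask).all()

    def test_warns_on_non_scp3_input(self, faz_radius_samples):
        s = faz_radius_samples[0.3]
        img = AngioImage(pixels=s.image, fov_mm=6, plexus="DCP",
                        laterality="OD")
        with pytest.warns(UserWarning, match="3 mm SCP"):
            segment_faz(img)

    def test_mask_is_single_connected_component(self, faz_radius_samples):
        from scipy import ndimage

        res = segment_faz(as_angio(faz_radius_samples[0.4]))
        assert ndimage.label(res.mask)[1] == 1
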