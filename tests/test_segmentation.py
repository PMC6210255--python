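"""Segmentation pipeline tests against generator ground truth and oracles."""

import numpy as np
import pytest
from scipy import ndimage

from glucolens import (
    SceneSpec,
    SegmentationError,
    clean_binary,
    compute_ratio,
    find_red_area,
    find_reference_circle,
    render_frame,
    thickness_to_ratio,
)
from glucolens.segmentation import ReferenceCircle, fit_circle, to_gray_binary


def _rgb(gray2d):
    return np.stack([gray2d] * 3, axis=2).astype(np.uint8)


class TestGrayBinary:
    def test_black_frame_has_no_foreground(self):
        with pytest.raises(SegmentationError, match="no foreground"):
            to_gray_binary(np.zeros((64, 64, 3), dtype=np.uint8))

    def test_failed_frame_yields_flagged_result(self):
        result = compute_ratio(np.zeros((64, 64, 3), dtype=np.uint8))
        assert not result.ok
        assert any("no foreground" in f for f in result.qc_flags)

    def test_binarization_idempotent_on_binary_raster(self):
        rng = np.random.default_rng(0)
        mask = rng.random((64, 64)) > 0.5
        binary = to_gray_binary(_rgb(mask * 255))
        again = to_gray_binary(_rgb(binary * 255))
        assert np.array_equal(binary, mask)
        assert np.array_equal(again, binary)

    def test_foreground_is_rim_plus_red_disc(self):
        """On a hard-edged render, the bright class is exactly rim + disc."""
        spec = SceneSpec(red_area_fraction=0.418, noise_sigma=0.0,
                         edge_softness=0.0, seed=1)
        frame, gt = render_frame(spec)
        binary = to_gray_binary(frame)
        rr, cc = np.ogrid[:spec.height, :spec.width]
        d2 = (rr - spec.sample_center[0]) ** 2 + (cc - spec.sample_center[1]) ** 2
        rim = (d2 <= spec.sample_radius**2) & \
              (d2 > (spec.sample_radius - spec.rim_width) ** 2)
        disc = d2 <= gt["red_radius_px"] ** 2
        truth = int((rim | disc).sum())
        assert abs(int(binary.sum()) - truth) / truth <= 0.02


class TestCleanBinary:
    def test_speck_removal_keeps_only_the_disc(self):
        """One 10^4-px disc plus 50 specks: census says only the disc survives."""
        mask = np.zeros((512, 512), dtype=bool)
        rr, cc = np.ogrid[:512, :512]
        mask[(rr - 256) ** 2 + (cc - 256) ** 2 <= 57**2] = True  # ~10^4 px
        rng = np.random.default_rng(42)
        specks = rng.integers(0, 512, size=(50, 2))
        for r, c in specks:
            mask[r, c] = True
        n_before, _ = ndimage.label(mask)[1], None
        cleaned, flags = clean_binary(mask, min_object_px=64)
        labeled, n_after = ndimage.label(cleaned)
        assert n_after == 1
        assert flags == []
        # the survivor is the disc (eroded), not a speck cluster
        assert cleaned.sum() > 0.9 * np.pi * 55**2
        # anti-extensive in component count and support
        assert n_after <= n_before
        dilated = ndimage.binary_dilation(mask, iterations=2)
        assert not np.any(cleaned & ~dilated)

    def test_empty_mask_flagged(self):
        cleaned, flags = clean_binary(np.zeros((32, 32), dtype=bool))
        assert not cleaned.any()
        assert "empty-after-clean" in flags

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_component_count_never_increases_on_blob_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((256, 256), dtype=bool)
        rr, cc = np.ogrid[:256, :256]
        for _ in range(6):
            r0, c0 = rng.integers(30, 226, size=2)
            rad = rng.integers(8, 25)
            mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        n_before = ndimage.label(mask)[1]
        cleaned, _ = clean_binary(mask, min_object_px=64)
        assert ndimage.label(cleaned)[1] <= n_before


class TestReferenceCircle:
    def test_three_points_determine_exact_circle(self):
        pts = np.array([[0.0, 5.0], [5.0, 0.0], [0.0, -5.0]])
        center, radius, rms = fit_circle(pts)
        assert center == pytest.approx((0.0, 0.0), abs=1e-9)
        assert radius == pytest.approx(5.0, abs=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_rasterized_disc_recovered_within_half_pixel(self):
        mask = np.zeros((512, 512), dtype=bool)
        rr, cc = np.ogrid[:512, :512]
        mask[(rr - 256) ** 2 + (cc - 256) ** 2 <= 200**2] = True
        ref = find_reference_circle(mask)
        assert ref.center[0] == pytest.approx(256, abs=0.5)
        assert ref.center[1] == pytest.approx(256, abs=0.5)
        assert ref.radius == pytest.approx(200, abs=0.5)
        assert ref.flags == ()

    def test_fit_agrees_with_grid_search_oracle(self):
        """Algebraic fit matches exhaustive geometric-residual minimisation."""
        mask = np.zeros((256, 256), dtype=bool)
        rr, cc = np.ogrid[:256, :256]
        mask[(rr - 130) ** 2 + (cc - 120) ** 2 <= 80**2] = True
        comp = mask & ~ndimage.binary_erosion(mask)
        pts = np.argwhere(comp).astype(float)

        best = (None, np.inf)
        for r0 in np.arange(129.0, 131.01, 0.25):
            for c0 in np.arange(119.0, 121.01, 0.25):
                for rad in np.arange(78.0, 81.01, 0.25):
                    res = np.sum((np.hypot(pts[:, 0] - r0, pts[:, 1] - c0)
                                  - rad) ** 2)
                    if res < best[1]:
                        best = ((r0, c0, rad), res)
        (r0, c0, rad), _ = best
        center, radius, _ = fit_circle(pts)
        assert center[0] == pytest.approx(r0, abs=0.3)
        assert center[1] == pytest.approx(c0, abs=0.3)
        assert radius == pytest.approx(rad, abs=0.3)

    def test_ellipse_flagged_non_circular(self):
        mask = np.zeros((512, 512), dtype=bool)
        rr, cc = np.ogrid[:512, :512]
        mask[((rr - 256) / 1.2) ** 2 + (cc - 256) ** 2 <= 150**2] = True
        ref = find_reference_circle(mask)
        assert "non-circular reference" in ref.flags

    def test_annulus_with_interior_disc_fits_outer_edge(self):
        """Hole filling makes the rim, not the central disc, the reference."""
        rr, cc = np.ogrid[:512, :512]
        d2 = (rr - 256) ** 2 + (cc - 256) ** 2
        mask = ((d2 <= 200**2) & (d2 > 190**2)) | (d2 <= 130**2)
        ref = find_reference_circle(mask)
        assert ref.radius == pytest.approx(200, abs=1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(SegmentationError):
            find_reference_circle(np.zeros((16, 16), dtype=bool))


class TestRedArea:
    def test_pure_gray_frame_has_no_red(self):
        frame = _rgb(np.full((64, 64), 128))
        ref = ReferenceCircle(center=(32.0, 32.0), radius=20.0,
                              area=np.pi * 400, rms_residual=0.0)
        with pytest.raises(SegmentationError, match="no red area"):
            find_red_area(frame, ref)

    def test_red_area_within_2pct_of_truth(self, anchor_frame):
        frame, gt = anchor_frame
        binary = to_gray_binary(frame)
        cleaned, _ = clean_binary(binary)
        ref = find_reference_circle(cleaned, boundary_offset=2)
        _, area, _ = find_red_area(frame, ref)
        assert area == pytest.approx(gt["red_area_px"], rel=0.02)

    def test_partially_outside_disc_counts_only_inside(self):
        """Red disc straddling the reference: count equals the brute-force
        intersection census."""
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        rr, cc = np.ogrid[:200, :200]
        disc = (rr - 100) ** 2 + (cc - 140) ** 2 <= 40**2
        img[disc] = (200, 30, 30)
        ref = ReferenceCircle(center=(100.0, 100.0), radius=60.0,
                              area=np.pi * 3600, rms_residual=0.0)
        _, area, _ = find_red_area(img, ref)
        inside = disc & ((rr - 100) ** 2 + (cc - 100) ** 2 <= 60**2)
        expected = int(inside.sum())
        assert area == pytest.approx(expected, rel=0.02)
        assert area < disc.sum()


class TestComputeRatio:
    def test_deterministic_for_fixed_frame(self):
        frame, _ = render_frame(SceneSpec(red_area_fraction=0.462, seed=9))
        a = compute_ratio(frame)
        b = compute_ratio(frame)
        assert a.ratio == b.ratio
        assert a.red_area == b.red_area
        assert np.array_equal(a.red_mask, b.red_mask)

    def test_lowest_anchor_within_printed_spread(self, anchor_frame):
        frame, _ = anchor_frame
        result = compute_ratio(frame)
        assert 0.408 <= result.ratio <= 0.428

    def test_full_coverage_close_to_one(self):
        frame, _ = render_frame(SceneSpec(red_area_fraction=1.0,
                                          noise_sigma=0.0, seed=0))
        result = compute_ratio(frame)
        assert 0.98 <= result.ratio <= 1.05
        if result.ratio > 1.0:
            assert "ratio-above-one" in result.qc_flags

    def test_noise_repeatability_matches_printed_spread(self):
        """At read noise sigma=8 the per-frame ratio scatter stays within the
        order of the bench calibration's +/-0.007."""
        ratios = []
        for seed in range(20):
            frame, _ = render_frame(SceneSpec(red_area_fraction=0.418,
                                              noise_sigma=8.0, seed=100 + seed))
            ratios.append(compute_ratio(frame).ratio)
        assert np.std(ratios) <= 0.01

    def test_ratio_increases_with_anchor_thickness(self, pdms_map):
        measured = []
        for seed, t_mm in enumerate((0.135, 2.247, 5.343), start=1):
            raf = thickness_to_ratio(pdms_map, t_mm)
            frame, _ = render_frame(SceneSpec(red_area_fraction=raf, seed=seed))
            measured.append(compute_ratio(frame).ratio)
        assert measured[0] < measured[1] < measured[2]
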