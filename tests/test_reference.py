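import itertools

import numpy as np
import pytest

from lamap.priors import default_priors
from lamap.reference import (
    AxisFitError,
    CandidateRegion2D,
    CoincidentCentroidsError,
    SliceDetection,
    detect_references_slice,
    extract_regions_2d,
    fit_reference_axes,
    isotropy_ratio,
    pair_geometry_logprior,
    pair_shape_loglik,
)
from lamap.volume import CTVolume

PRIOR = default_priors()


def _disc_mask(shape, center, radius):
    jj, ii = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2


def _region_from_pixels(pixels_xy, spacing=(1.0, 1.0), slice_index=0):
    mask = np.zeros(
        (int(max(y for _, y in pixels_xy)) + 2, int(max(x for x, _ in pixels_xy)) + 2),
        dtype=bool,
    )
    for x, y in pixels_xy:
        mask[int(y), int(x)] = True
    regions = extract_regions_2d(mask, spacing, slice_index, min_area_mm2=0.0)
    assert len(regions) == 1
    return regions[0]


class TestRegionExtraction:
    def test_two_discs_found_with_centroids_at_centers(self):
        mask = _disc_mask((200, 200), (50, 60), 20) | _disc_mask((200, 200), (140, 130), 20)
        regions = extract_regions_2d(mask, (1.0, 1.0))
        assert len(regions) == 2
        centroids = sorted(r.centroid_mm for r in regions)
        assert centroids[0] == pytest.approx((50, 60), abs=0.5)
        assert centroids[1] == pytest.approx((140, 130), abs=0.5)

    def test_empty_mask_gives_no_regions(self):
        assert extract_regions_2d(np.zeros((50, 50), bool), (1.0, 1.0)) == []

    def test_small_area_regions_filtered(self):
        mask = _disc_mask((60, 60), (30, 30), 3)  # ~28 mm^2 < 50 mm^2
        assert extract_regions_2d(mask, (1.0, 1.0)) == []

    def test_one_pixel_line_has_zero_isotropy(self):
        mask = np.zeros((5, 90), dtype=bool)
        mask[2, 3:83] = True  # 80-px line, area 80 mm^2 passes the filter
        (region,) = extract_regions_2d(mask, (1.0, 1.0))
        assert region.eigenvalues[0] == pytest.approx(0.0, abs=1e-12)
        assert isotropy_ratio(region) == 0.0


class TestIsotropyRatio:
    def test_filled_disc_is_nearly_isotropic(self):
        mask = _disc_mask((60, 60), (30, 30), 25)
        (region,) = extract_regions_2d(mask, (1.0, 1.0))
        assert 0.97 <= isotropy_ratio(region) <= 1.0

    def test_rectangle_matches_discrete_uniform_variance(self):
        """A 10x40 px rectangle: covariance is diag((10^2-1)/12, (40^2-1)/12)."""
        pixels = [(x, y) for x in range(40) for y in range(10)]
        region = _region_from_pixels(pixels)
        brute = np.cov(np.array(pixels).T, ddof=0)  # independent direct covariance
        np.testing.assert_allclose(region.covariance_mm2, brute, atol=1e-9)
        expected = (10**2 - 1) / (40**2 - 1)
        assert isotropy_ratio(region) == pytest.approx(expected, rel=1e-12)

    def test_unit_square_is_perfectly_isotropic(self):
        region = _region_from_pixels([(0, 0), (1, 0), (0, 1), (1, 1)])
        np.testing.assert_allclose(region.covariance_mm2, 0.25 * np.eye(2), atol=1e-12)
        assert isotropy_ratio(region) == 1.0


class TestPairScores:
    def test_perfect_circles_score_zero(self):
        assert pair_shape_loglik(1.0, 1.0, PRIOR.sigma_r) == 0.0

    def test_one_normalized_deviation_scores_minus_one(self):
        assert pair_shape_loglik(1 - PRIOR.sigma_r, 1.0, PRIOR.sigma_r) == pytest.approx(-1)

    def test_shape_loglik_direct_arithmetic(self):
        assert pair_shape_loglik(0.9, 0.8, 0.1) == pytest.approx(-5.0)

    def test_geometry_prior_zero_at_the_means(self):
        theta = np.radians(PRIOR.theta_bar)
        d = PRIOR.delta_bar * np.array([np.cos(theta), np.sin(theta)])
        assert pair_geometry_logprior((0, 0), tuple(d), PRIOR) == pytest.approx(0, abs=1e-18)

    @pytest.mark.parametrize(
        "delta_scale,theta_scale",
        [(1 + PRIOR.sigma_delta, 1.0), (1.0, 1 + PRIOR.sigma_theta)],
    )
    def test_geometry_prior_minus_one_at_one_sigma(self, delta_scale, theta_scale):
        theta = np.radians(PRIOR.theta_bar * theta_scale)
        delta = PRIOR.delta_bar * delta_scale
        d = delta * np.array([np.cos(theta), np.sin(theta)])
        assert pair_geometry_logprior((0, 0), tuple(d), PRIOR) == pytest.approx(-1, rel=1e-9)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(CoincidentCentroidsError):
            pair_geometry_logprior((5, 5), (5, 5), PRIOR)


def _slice_with_discs_and_decoys():
    mask = np.zeros((200, 200), dtype=bool)
    theta = np.radians(PRIOR.theta_bar)
    aa = np.array([50.0, 30.0])
    da = aa + PRIOR.delta_bar * np.array([np.cos(theta), np.sin(theta)])
    mask |= _disc_mask(mask.shape, aa, 14)
    mask |= _disc_mask(mask.shape, da, 10)
    mask[5:13, 100:180] = True  # elongated decoys
    mask[180:188, 10:90] = True
    mask[100:108, 150:195] = True
    return mask, aa, da


class TestSliceDetection:
    def test_disc_pair_beats_decoys_in_theta_consistent_order(self):
        mask, aa, da = _slice_with_discs_and_decoys()
        regions = extract_regions_2d(mask, (1.0, 1.0))
        assert len(regions) == 5
        det = detect_references_slice(regions, PRIOR)
        assert det.aa.centroid_mm == pytest.approx(tuple(aa), abs=0.5)
        assert det.da.centroid_mm == pytest.approx(tuple(da), abs=0.5)

    def test_matches_brute_force_over_all_ordered_pairs(self):
        mask, _, _ = _slice_with_discs_and_decoys()
        regions = extract_regions_2d(mask, (1.0, 1.0))
        det = detect_references_slice(regions, PRIOR)
        best = max(
            (
                (
                    pair_shape_loglik(a.isotropy_ratio, b.isotropy_ratio, PRIOR.sigma_r)
                    + pair_geometry_logprior(a.centroid_mm, b.centroid_mm, PRIOR),
                    i,
                    j,
                )
                for (i, a), (j, b) in itertools.permutations(enumerate(regions), 2)
            ),
        )
        assert det.score == pytest.approx(best[0])
        assert det.aa is regions[best[1]] and det.da is regions[best[2]]

    def test_reversed_order_scores_strictly_lower(self):
        mask, aa, da = _slice_with_discs_and_decoys()
        regions = extract_regions_2d(mask, (1.0, 1.0))
        det = detect_references_slice(regions, PRIOR)
        reversed_score = pair_shape_loglik(
            det.da.isotropy_ratio, det.aa.isotropy_ratio, PRIOR.sigma_r
        ) + pair_geometry_logprior(det.da.centroid_mm, det.aa.centroid_mm, PRIOR)
        assert reversed_score < det.score

    def test_single_region_gives_no_detection(self):
        mask = _disc_mask((100, 100), (50, 50), 20)
        regions = extract_regions_2d(mask, (1.0, 1.0))
        assert detect_references_slice(regions, PRIOR) is None

    def test_score_invariant_to_in_plane_translation(self):
        mask, _, _ = _slice_with_discs_and_decoys()
        regions = extract_regions_2d(mask, (1.0, 1.0))
        shifted = np.zeros((220, 220), dtype=bool)
        shifted[15:215, 10:210] = mask
        regions_shifted = extract_regions_2d(shifted, (1.0, 1.0))
        s0 = detect_references_slice(regions, PRIOR).score
        s1 = detect_references_slice(regions_shifted, PRIOR).score
        assert s1 == pytest.approx(s0, rel=1e-9)


def _synthetic_detections(aa_path, da_path, n_slices):
    """Build SliceDetection rows from two centroid trajectories (functions of k)."""
    detections = []
    for k in range(n_slices):
        regions = []
        for centroid in (aa_path(k), da_path(k)):
            regions.append(
                CandidateRegion2D(
                    slice_index=k,
                    pixel_count=600,
                    centroid_mm=tuple(centroid),
                    covariance_mm2=np.eye(2) * 50,
                    eigenvalues=(50.0, 50.0),
                )
            )
        detections.append(
            SliceDetection(slice_index=k, aa=regions[0], da=regions[1], score=0.0)
        )
    return detections


class TestAxisFitting:
    VOL = CTVolume(np.zeros((40, 16, 16)), spacing=(1.0, 1.0, 1.0))

    def test_collinear_centroids_fit_exactly(self):
        axes = fit_reference_axes(
            _synthetic_detections(
                lambda k: (30 + 0.1 * k, 20), lambda k: (80, 70 - 0.05 * k), 40
            ),
            self.VOL,
        )
        for k in (0, 20, 39):
            assert axes.aa.at_z(k)[:2] == pytest.approx((30 + 0.1 * k, 20), abs=1e-9)
            assert axes.da.at_z(k)[:2] == pytest.approx((80, 70 - 0.05 * k), abs=1e-9)
        assert axes.aa.direction[2] > 0 and axes.da.direction[2] > 0

    def test_outlier_slices_are_rejected(self):
        """10% far outliers: fit stays within 1 mm of the uncontaminated line."""

        def aa_path(k):
            return (30 + 0.1 * k, 20) if k % 10 != 7 else (130, 140)

        axes = fit_reference_axes(
            _synthetic_detections(aa_path, lambda k: (80, 70), 40), self.VOL
        )
        for k in (0, 20, 39):
            clean = np.array([30 + 0.1 * k, 20])
            assert np.linalg.norm(axes.aa.at_z(k)[:2] - clean) < 1.0

    def test_two_slices_insufficient(self):
        with pytest.raises(AxisFitError):
            fit_reference_axes(
                _synthetic_detections(lambda k: (30, 20), lambda k: (80, 70), 2),
                self.VOL,
            )
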