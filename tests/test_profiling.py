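"""Contours, rays, binning and condition averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import skimage.draw as draw

from chromring.profiling import (
    BinnedProfile,
    MaskError,
    RadialRay,
    attach_edge_crossings,
    bin_and_normalize,
    condition_profile,
    extract_contour,
    filter_resolvable_rays,
    nucleolus_edge_profile,
    profile_nucleus,
    sample_rays,
)

from conftest import truth_nucleolus_mask2d


def disk_mask(shape, centre, radius):
    m = np.zeros(shape, bool)
    rr, cc = draw.disk(centre, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestExtractContour:
    def test_3x3_square_has_8_perimeter_pixels(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        c = extract_contour(m)
        assert len(c) == 8
        assert (2, 2) not in {tuple(p) for p in c}  # interior pixel excluded

    def test_contour_is_ordered_and_closed(self):
        m = disk_mask((40, 40), (20, 20), 12.3)
        c = extract_contour(m).astype(float)
        steps = np.hypot(*np.diff(np.vstack([c, c[:1]]), axis=0).T)
        assert steps.max() <= math.sqrt(2) + 1e-9  # adjacent pixels only

    def test_disk_perimeter_near_circumference(self):
        # 8-connected pixel chains overestimate smooth perimeters by ~5%
        m = disk_mask((64, 64), (32, 32), 20.4)
        c = extract_contour(m).astype(float)
        per = np.hypot(*np.diff(np.vstack([c, c[:1]]), axis=0).T).sum()
        assert per == pytest.approx(2 * math.pi * 20, rel=0.06)

    def test_every_boundary_pixel_near_polygon(self):
        from scipy.ndimage import binary_erosion

        m = disk_mask((50, 50), (24, 26), 15.2)
        boundary = m & ~binary_erosion(m)
        c = extract_contour(m).astype(float)
        by, bx = np.nonzero(boundary)
        d2 = ((by[:, None] - c[:, 0]) ** 2 + (bx[:, None] - c[:, 1]) ** 2).min(axis=1)
        assert np.sqrt(d2).max() <= 1.0

    def test_multi_component_mask_rejected(self):
        m = np.zeros((10, 10), bool)
        m[1:3, 1:3] = True
        m[6:9, 6:9] = True
        with pytest.raises(MaskError):
            extract_contour(m)

    def test_empty_mask_rejected(self):
        with pytest.raises(MaskError):
            extract_contour(np.zeros((5, 5), bool))


class TestSampleRays:
    def test_constant_field_samples_constant(self):
        m = disk_mask((41, 41), (20, 20), 15)
        rays = sample_rays(np.full((41, 41), 7.0), (20, 20), extract_contour(m))
        for r in rays:
            assert np.allclose(r.intensities, 7.0)

    def test_circular_contour_ray_lengths(self):
        m = disk_mask((41, 41), (20, 20), 15.2)
        rays = sample_rays(np.zeros((41, 41)), (20, 20), extract_contour(m))
        lengths = np.array([r.length for r in rays])
        assert np.all(np.abs(lengths - 15.2) <= 1.0)

    def test_linear_gradient_matches_bilinear_formula(self):
        yy, xx = np.mgrid[0:41, 0:41]
        img = 2.0 * yy + 3.0 * xx + 1.0  # bilinear interp is exact on planes
        m = disk_mask((41, 41), (20, 20), 14)
        rays = sample_rays(img, (20.0, 20.0), extract_contour(m))
        rng = np.random.default_rng(1)
        for _ in range(10):
            ray = rays[rng.integers(len(rays))]
            k = rng.integers(len(ray.distances))
            y, x = ray.positions()[:, k]
            assert ray.intensities[k] == pytest.approx(2 * y + 3 * x + 1, rel=1e-9)

    def test_final_sample_exactly_at_contour(self):
        m = disk_mask((41, 41), (20, 20), 13)
        rays = sample_rays(np.zeros((41, 41)), (20, 20), extract_contour(m))
        for r in rays:
            assert r.distances[-1] == pytest.approx(r.length, abs=1e-12)
            ey, ex = r.positions()[:, -1]
            assert (ey, ex) == pytest.approx(r.end, abs=1e-9)

    def test_centre_outside_contour_rejected(self):
        m = disk_mask((41, 41), (20, 20), 10)
        with pytest.raises(ValueError):
            sample_rays(np.zeros((41, 41)), (2.0, 2.0), extract_contour(m))


class TestRayFilter:
    def _rays_with_spans(self, spans, edge=5.0):
        out = []
        for i, span in enumerate(spans):
            L = edge + span
            d = np.linspace(0, L, 12)
            out.append(
                RadialRay(index=i, distances=d, intensities=np.zeros(12),
                          length=L, edge_crossing=edge)
            )
        return out

    def test_long_rays_all_retained(self):
        rays = self._rays_with_spans([20.0] * 6)
        kept, discarded = filter_resolvable_rays(rays, 9.0)
        assert len(kept) == 6 and discarded == 0

    def test_short_rays_all_discarded_with_warning(self):
        rays = self._rays_with_spans([5.0] * 4)
        with pytest.warns(UserWarning):
            kept, discarded = filter_resolvable_rays(rays, 9.0)
        assert kept == [] and discarded == 4

    def test_mixed_spans_match_bruteforce(self):
        spans = [3.0, 8.9, 9.0, 12.5, 30.0]
        rays = self._rays_with_spans(spans)
        kept, discarded = filter_resolvable_rays(rays, 9.0)
        expect = [s >= 9.0 for s in spans]
        assert [r.length - r.edge_crossing >= 9.0 for r in rays] == expect
        assert len(kept) == sum(expect)

    def test_missing_edge_information_rejected(self):
        ray = RadialRay(index=0, distances=np.array([0.0, 1.0]),
                        intensities=np.zeros(2), length=1.0)
        with pytest.raises(ValueError):
            filter_resolvable_rays([ray], 9.0)


class TestBinning:
    def test_constant_rays_give_flat_unit_profile(self):
        rays = [
            RadialRay(index=i, distances=np.arange(0, 21, 0.5),
                      intensities=np.full(42, 3.3), length=20.0)
            for i in range(4)
        ]
        p = bin_and_normalize(rays)
        assert np.allclose(p.values, 1.0)
        assert p.normalized

    def test_sample_at_zero_distance_goes_to_first_bin(self):
        ray = RadialRay(index=0, distances=np.array([0.0, 10.0]),
                        intensities=np.array([5.0, 1.0]), length=10.0)
        p = bin_and_normalize([ray])
        assert p.n_per_bin[0] == 1   # the 0-distance sample sits in bin 2.5%
        assert p.n_per_bin[-1] == 1  # the contour sample in the closed last bin

    def test_pooled_binning_matches_bruteforce_loop(self):
        rng = np.random.default_rng(7)
        rays = []
        for i in range(10):
            d = np.sort(rng.uniform(0, 30, 100))
            d[0] = 0.0
            rays.append(
                RadialRay(index=i, distances=np.unique(d),
                          intensities=rng.random(len(np.unique(d))),
                          length=float(np.unique(d)[-1]))
            )
        p = bin_and_normalize(rays)
        sums = np.zeros(20)
        counts = np.zeros(20)
        for r in rays:
            for dist, val in zip(r.distances, r.intensities):
                rel = dist / r.length * 100
                b = 19 if rel >= 100 else int(rel // 5)
                sums[b] += val
                counts[b] += 1
        expected = sums / counts
        assert np.allclose(p.values, expected / expected.max())
        assert p.n_per_bin.sum() == sum(len(r.distances) for r in rays)

    @given(st.integers(0, 2**31 - 1))
    def test_binning_is_exhaustive_and_exclusive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        d = np.unique(np.r_[0.0, rng.uniform(0, 15, n)])
        ray = RadialRay(index=0, distances=d, intensities=rng.random(len(d)),
                        length=float(d[-1]))
        p = bin_and_normalize([ray])
        assert p.n_per_bin.sum() == len(d)

    def test_zero_length_ray_rejected(self):
        with pytest.raises(ValueError):
            RadialRay(index=0, distances=np.array([0.0]),
                      intensities=np.array([1.0]), length=0.0)

    def test_all_zero_profile_flagged_unnormalized(self):
        ray = RadialRay(index=0, distances=np.arange(0, 10.5, 0.5),
                        intensities=np.zeros(21), length=10.0)
        with pytest.warns(UserWarning):
            p = bin_and_normalize([ray])
        assert not p.normalized


class TestConditionProfile:
    def test_identical_profiles_have_zero_band(self):
        p = BinnedProfile(values=np.linspace(0.1, 1.0, 20))
        cp = condition_profile([p, p, p])
        assert np.allclose(cp.ci_halfwidth, 0.0)
        assert np.allclose(cp.mean, p.values)

    def test_single_profile_degenerate(self):
        p = BinnedProfile(values=np.linspace(0.1, 1.0, 20))
        with pytest.warns(UserWarning):
            cp = condition_profile([p])
        assert cp.n == 1
        assert np.allclose(cp.ci_halfwidth, 0.0)

    def test_mean_and_sem_match_bruteforce(self):
        rng = np.random.default_rng(3)
        mat = rng.random((20, 20))
        profiles = [BinnedProfile(values=row) for row in mat]
        cp = condition_profile(profiles)
        assert np.allclose(cp.mean, mat.mean(axis=0))
        sem = mat.std(axis=0, ddof=1) / math.sqrt(20)
        assert np.allclose(cp.ci_halfwidth, 1.96 * sem)

    def test_mixed_normalization_rejected(self):
        a = BinnedProfile(values=np.ones(20), normalized=True)
        b = BinnedProfile(values=np.ones(20), normalized=False)
        with pytest.raises(ValueError):
            condition_profile([a, b])


class TestEdgeProfile:
    def test_circular_nucleolus_geometry(self):
        # ray crossing a radius-10px nucleolus: a sample 15 px from the centre
        # lies 5 px (0.5 µm at 0.1 µm pitch) beyond the edge
        d = np.arange(0.0, 20.5, 0.5)
        ray = RadialRay(index=0, distances=d, intensities=np.ones(len(d)),
                        length=20.0, edge_crossing=10.0)
        ep = nucleolus_edge_profile([ray], voxel_xy=0.1, bin_width_um=0.25)
        # sample at 15 px -> 0.5 µm -> bin centre 0.625 (third bin)
        assert ep.bin_centres_um[int(0.5 // 0.25)] == pytest.approx(0.625)
        assert ep.n_per_bin.sum() == np.sum(d > 10.0)

    @pytest.mark.parametrize("mode,first_is_max", [("fasted", True), ("fed", False)])
    def test_edge_profile_shape_by_condition(self, mode, first_is_max,
                                             fed_scene_clean, fasted_scene_clean):
        from chromring.profiling import extract_contour, sample_rays

        s = fasted_scene_clean if mode == "fasted" else fed_scene_clean
        contour = extract_contour(s.mask2d)
        rays = sample_rays(s.chromatin[s.central_z], s.annotation[1:], contour)
        rays = attach_edge_crossings(rays, truth_nucleolus_mask2d(s))
        ep = nucleolus_edge_profile(rays, s.config.voxel_xy)
        argmax = int(np.nanargmax(ep.values))
        assert (argmax == 0) == first_is_max

    def test_2d_and_3d_masks_give_matching_profiles(self, fed_scene_clean):
        from chromring.io import central_plane_from_3d

        s = fed_scene_clean
        p2 = profile_nucleus(s.chromatin[s.central_z], s.mask2d, s.annotation[1:])
        z, m2 = central_plane_from_3d(s.mask3d)
        p3 = profile_nucleus(s.chromatin[z], m2, s.annotation[1:])
        assert np.abs(p2.values - p3.values).max() < 0.01
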