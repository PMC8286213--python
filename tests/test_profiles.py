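"""Profile extraction, peak-to-valley ratios and surface-shape classes."""

import numpy as np
import pytest
from scipy import ndimage

import petharm as ph
from petharm.errors import ProfilesUnavailableError, UndefinedPtvError
from petharm.image import PetImage
from petharm.profiles import (
    Profile,
    classify_shape,
    extract_profiles,
    largest_slice,
    mean_ptv,
    peak_to_valley,
    surface_data,
)
from petharm.segmentation import SphereMask, segment_sphere


def make_profile(values, in_region=None, angle=0.0):
    values = np.asarray(values, dtype=float)
    pos = np.arange(values.size, dtype=float)
    if in_region is None:
        in_region = np.ones(values.size, dtype=bool)
    return Profile(pos, values, np.asarray(in_region, dtype=bool), angle_deg=angle)


def ring_image(rim=0.5, size=61, radius=14.0):
    """Radially symmetric slab with an overshoot rim at ``radius`` mm.

    The rim is several voxels wide so bilinear sampling at arbitrary
    angles resolves it.
    """
    x = np.arange(size) - size // 2
    r = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
    plane = np.where(r <= radius, 1.0, 0.1) + rim * np.exp(-((r - radius) ** 2) / 16.0)
    vox = np.repeat(plane[:, :, None], 5, axis=2)
    img = PetImage(vox, (1, 1, 1), (-(size // 2), -(size // 2), -2))
    mask = np.zeros_like(vox, dtype=bool)
    mask[:, :, 2] = r <= radius
    idx = np.unravel_index(np.argmax(np.where(mask, vox, -np.inf)), vox.shape)
    sm = SphereMask(ph.SphereSpec(2 * radius, (0, 0, 0)), mask, float(vox[idx]), idx)
    return img, sm


class TestLargestSlice:
    def test_equatorial_slice_of_a_sphere_mask(self, identity_masks):
        m = identity_masks[37.0]
        iz = largest_slice(m)
        # sphere centres lie in the z = 0 plane of the 2-mm grid
        areas = m.mask.sum(axis=(0, 1))
        assert areas[iz] == areas.max()

    def test_single_slice_mask(self):
        _, sm = ring_image()
        assert largest_slice(sm) == 2

    def test_tie_broken_toward_centroid(self):
        mask = np.zeros((5, 5, 7), dtype=bool)
        mask[1:4, 1:4, 1] = True   # area 9
        mask[1:4, 1:4, 5] = True   # area 9
        mask[2, 2, 3] = True       # centroid pulled to z = 3; slice 1 vs 5 tie
        sm = SphereMask(ph.SphereSpec(6.0, (0, 0, 0)), mask, 1.0, (2, 2, 3))
        assert largest_slice(sm) in (1, 5)
        mask[2, 2, 2] = True  # centroid now below 3 -> slice 1 wins
        sm = SphereMask(ph.SphereSpec(6.0, (0, 0, 0)), mask, 1.0, (2, 2, 3))
        assert largest_slice(sm) == 1


class TestExtractProfiles:
    def test_six_profiles_at_thirty_degree_spacing(self, blurred_image, spec):
        m = segment_sphere(blurred_image, spec.sphere_by_diameter(37.0))
        profiles = extract_profiles(blurred_image, m)
        assert [p.angle_deg for p in profiles] == [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]

    def test_radially_symmetric_image_gives_identical_profiles(self):
        img, sm = ring_image()
        profiles = extract_profiles(img, sm)
        ptvs = [peak_to_valley(p) for p in profiles]
        assert np.ptp(ptvs) < 0.02 * np.mean(ptvs)

    def test_degenerate_footprint_rejected(self):
        vox = np.zeros((9, 9, 3))
        vox[4, 2:7, 1] = 5.0  # one voxel wide
        img = PetImage(vox, (4.1, 4.1, 4.1), (0, 0, 0))
        mask = vox > 0
        sm = SphereMask(ph.SphereSpec(10.0, (4 * 4.1, 4 * 4.1, 4.1)), mask, 5.0, (4, 4, 1))
        with pytest.raises(ProfilesUnavailableError):
            extract_profiles(img, sm)


class TestPeakToValley:
    def test_flat_top_scores_unity(self):
        p = make_profile([1, 2, 5, 5, 5, 5, 5, 2, 1],
                         [False, False, True, True, True, True, True, False, False])
        assert peak_to_valley(p) == pytest.approx(1.0)

    def test_worked_example_five_three_four(self):
        # in-region {5,3,4,3,5}, out-of-region edges at 5
        p = make_profile([5, 5, 3, 4, 3, 5, 5],
                         [False, True, True, True, True, True, False])
        assert peak_to_valley(p) == pytest.approx(5 / 3, abs=1e-9)

    def test_non_positive_valley_rejected(self):
        p = make_profile([1, 0.0, 0.0, 0.0, 1], [True] * 5)
        with pytest.raises(UndefinedPtvError):
            peak_to_valley(p)

    def test_ptv_at_least_one(self, sharp_psf_image, spec):
        for d in (37.0, 28.0, 22.0):
            m = segment_sphere(sharp_psf_image, spec.sphere_by_diameter(d))
            for p in extract_profiles(sharp_psf_image, m):
                assert peak_to_valley(p) >= 1.0

    def test_scale_invariance(self, sharp_psf_image, spec):
        m = segment_sphere(sharp_psf_image, spec.sphere_by_diameter(37.0))
        a = mean_ptv(extract_profiles(sharp_psf_image, m))
        scaled = sharp_psf_image.copy_with(sharp_psf_image.voxels * 12.5)
        b = mean_ptv(extract_profiles(scaled, m))
        assert a.mean == pytest.approx(b.mean, rel=1e-9)


class TestClassifyShape:
    def test_flat_for_constant_region(self):
        profiles = [make_profile([0.1, 1, 1, 1, 1, 1, 0.1],
                                 [False, True, True, True, True, True, False], a)
                    for a in range(6)]
        assert classify_shape(profiles) == "flat"

    def test_concave_for_rim_and_valley(self):
        vals = [0.1, 1.5, 1.0, 0.9, 1.0, 1.5, 0.1]
        flags = [False, True, True, True, True, True, False]
        profiles = [make_profile(vals, flags, a) for a in range(6)]
        assert classify_shape(profiles) == "concave"

    def test_conical_for_partial_volume_dome(self, blurred_image, spec):
        m = segment_sphere(blurred_image, spec.sphere_by_diameter(13.0))
        assert classify_shape(extract_profiles(blurred_image, m)) == "conical"

    def test_simulated_overshoot_is_concave(self, sharp_psf_image, spec):
        m = segment_sphere(sharp_psf_image, spec.sphere_by_diameter(37.0))
        assert classify_shape(extract_profiles(sharp_psf_image, m)) == "concave"


class TestMeanPtv:
    def test_six_identical_flat_profiles(self):
        profiles = [make_profile([0.2, 1, 1, 1, 1, 1, 0.2],
                                 [False, True, True, True, True, True, False], a)
                    for a in range(6)]
        res = mean_ptv(profiles)
        assert res.measurable and res.shape == "flat"
        assert res.mean == pytest.approx(1.0)
        assert res.sd == pytest.approx(0.0)

    def test_hand_computed_mean_and_sd(self):
        ptvs = [1.6, 1.7, 1.8, 1.7, 1.6, 1.8]
        profiles = []
        for k, x in enumerate(ptvs):
            # rim value x, central valley 1.0 -> per-profile PTV exactly x
            vals = [0.1, x, 1.0, 1.0, 1.0, x, 0.1]
            flags = [False, True, True, True, True, True, False]
            profiles.append(make_profile(vals, flags, k * 30.0))
        res = mean_ptv(profiles)
        assert res.shape == "concave"
        assert res.mean == pytest.approx(1.70, abs=1e-9)
        assert res.sd == pytest.approx(0.0894427, abs=1e-4)

    def test_conical_sphere_not_measurable(self, blurred_image, spec):
        m = segment_sphere(blurred_image, spec.sphere_by_diameter(13.0))
        res = mean_ptv(extract_profiles(blurred_image, m))
        assert not res.measurable
        assert np.isnan(res.mean)

    def test_rotational_consistency(self):
        img, sm = ring_image()
        base = mean_ptv(extract_profiles(img, sm)).mean
        rot_vox = ndimage.rotate(img.voxels, 15.0, axes=(0, 1), reshape=False, order=3)
        rot = PetImage(rot_vox, img.spacing, img.origin)
        rotated = mean_ptv(extract_profiles(rot, sm)).mean
        assert rotated == pytest.approx(base, rel=0.01)


class TestSurfaceData:
    def test_constant_slice_gives_constant_field(self, identity_image, identity_masks):
        field = surface_data(identity_image, identity_masks[37.0])
        assert field.max() == pytest.approx(19.9)

    def test_output_covers_footprint_bounding_box_plus_margin(self):
        img, sm = ring_image(radius=9.0)
        field = surface_data(img, sm, 2)
        foot = sm.mask[:, :, 2]
        idx = np.argwhere(foot)
        expect = idx.max(axis=0) - idx.min(axis=0) + 3  # +1 voxel margin each side
        assert field.shape == tuple(expect)

    def test_ring_field_peaks_on_annulus(self):
        img, sm = ring_image(rim=1.0)
        field = surface_data(img, sm, 2)
        ci, cj = np.array(field.shape) // 2
        assert field.max() > field[ci, cj]
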