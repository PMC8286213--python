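"""Simulator stages: rasterisation, blur, edge enhancement, noise, ensembles."""

import numpy as np
import pytest

import petharm as ph
from petharm.errors import GeometryClippedError, InvalidParameterError
from petharm.image import PetImage
from petharm.metrics import image_roughness
from petharm.segmentation import place_background_battery, segment_all_spheres
from petharm.simulate import (
    DEFAULT_VOXEL_PRESETS_MM,
    calibrate_noise_level,
    ground_truth_masks,
)


class TestRasterize:
    def test_partial_volumes_recover_analytic_sphere_volume(self, spec, identity_image):
        img = identity_image
        frac = (img.voxels - 2.4) / (19.9 - 2.4)
        xs, ys, zs = img.coordinate_grids()
        for s in spec.spheres:
            c = s.centre_mm
            near = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 < (
                s.radius_mm + 6.0
            ) ** 2
            est = frac[near].sum() * img.voxel_volume_mm3
            assert est == pytest.approx(s.volume_mm3, rel=0.01)

    def test_zero_contrast_fill_is_constant_inside_body(self, spec):
        img = ph.rasterize(spec, ph.FillSpec(2.4, 2.4), (4.0, 4.0, 4.0))
        xs, ys, zs = img.coordinate_grids()
        inside = spec.inside_body(xs, ys, zs) & ~spec.inside_lung(xs, ys, zs)
        # exclude the one-voxel shell at the body edge (centre-in test)
        assert np.allclose(img.voxels[inside], 2.4)

    def test_values_bounded_by_fill(self, identity_image):
        assert identity_image.voxels.max() <= 19.9 + 1e-12
        assert identity_image.voxels.min() >= 0.0

    def test_lung_insert_is_cold(self, spec, identity_image):
        xs, ys, zs = identity_image.coordinate_grids()
        lung = spec.inside_lung(xs, ys, zs)
        assert np.allclose(identity_image.voxels[lung & (np.abs(zs) < 80)], 0.0)

    def test_clipped_grid_rejected(self, spec, fill):
        with pytest.raises(GeometryClippedError):
            ph.rasterize(spec, fill, (2.0, 2.0, 2.0), shape=(50, 50, 50),
                         origin=(-50.0, -50.0, -50.0))


class TestResolutionBlur:
    def test_zero_width_identity(self, identity_image):
        iso = ph.IsotopeSpec("ideal", 60.0, 0.0)
        out = ph.resolution_blur(identity_image, iso, 0.0)
        np.testing.assert_array_equal(out.voxels, identity_image.voxels)

    def test_conserves_total_activity(self, identity_image):
        out = ph.resolution_blur(identity_image, ph.GA68, 4.5)
        assert out.total_activity_kbq() == pytest.approx(
            identity_image.total_activity_kbq(), rel=1e-3
        )

    def test_wider_positron_range_lowers_sphere_maxima(self, spec, identity_image):
        ga = ph.resolution_blur(identity_image, ph.GA68, 4.5)
        f18 = ph.resolution_blur(identity_image, ph.F18, 4.5)
        for d, m in ground_truth_masks(spec, identity_image, mode="centre").items():
            assert ga.voxels[m].max() < f18.voxels[m].max()


class TestEdgeEnhance:
    def test_zero_strength_identity(self, blurred_image):
        out = ph.edge_enhance(blurred_image, 0.0)
        np.testing.assert_array_equal(out.voxels, blurred_image.voxels)

    def test_overshoot_peak_sits_off_centre(self, spec, identity_image):
        blurred = ph.resolution_blur(identity_image, ph.GA68, 4.5)
        out = ph.edge_enhance(blurred, 3.0)
        s = spec.sphere_by_diameter(37.0)
        ic = identity_image.nearest_index(s.centre_mm)
        # profile along x through the sphere centre
        line = out.voxels[:, ic[1], ic[2]]
        ix = np.arange(line.size)
        near = np.abs(identity_image.axis_coords(0) - s.centre_mm[0]) < s.radius_mm + 6
        peak_idx = ix[near][np.argmax(line[near])]
        assert line[peak_idx] > line[ic[0]] * 1.02  # rim exceeds interior plateau
        assert abs(peak_idx - ic[0]) >= 5  # rim is millimetres off centre

    def test_output_non_negative(self, blurred_image):
        out = ph.edge_enhance(blurred_image, 5.0)
        assert out.voxels.min() >= 0.0


class TestAddNoise:
    def test_zero_level_identity(self, blurred_image):
        out = ph.add_noise(blurred_image, 0.0, 4.0, seed=1)
        np.testing.assert_array_equal(out.voxels, blurred_image.voxels)

    def test_same_seed_bitwise_identical(self, blurred_image):
        a = ph.add_noise(blurred_image, 0.2, 4.0, seed=42)
        b = ph.add_noise(blurred_image, 0.2, 4.0, seed=42)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c = ph.add_noise(blurred_image, 0.2, 4.0, seed=43)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_negative_level_rejected(self, blurred_image):
        with pytest.raises(InvalidParameterError):
            ph.add_noise(blurred_image, -0.1, 4.0, seed=1)

    def test_closed_loop_calibration_hits_target_roughness(self, spec, fill):
        """Tuning noise_level to background IR = 0.10 lands within 20%."""
        target = 0.10
        recon = ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4)

        def run(level, seed=1):
            sc = ph.ScannerProfile(voxel_spacing_mm=(2.7, 2.7, 3.3), noise_level=level)
            img = ph.simulate_acquisition(spec, fill, sc, recon, seed=seed)
            masks = segment_all_spheres(img, spec)
            battery = place_background_battery(img, spec, masks)
            return image_roughness(battery, 37.0)

        level = calibrate_noise_level(run, target, initial=0.2, n_iter=2)
        measured = [run(level, seed=s) for s in (2, 3, 4)]
        assert np.mean(measured) == pytest.approx(target, rel=0.20)


class TestPostFilter:
    def test_zero_width_identity_and_constant_invariance(self, identity_image):
        out = ph.post_filter(identity_image, 0.0)
        np.testing.assert_array_equal(out.voxels, identity_image.voxels)
        const = PetImage(np.full((20, 20, 20), 3.3), (2, 2, 2), (0, 0, 0))
        smoothed = ph.post_filter(const, 6.4)
        assert np.allclose(smoothed.voxels[5:15, 5:15, 5:15], 3.3)

    def test_smoothing_never_raises_sharp_maxima(self, spec, fill, scanner_2mm):
        imgs = {
            w: ph.simulate_acquisition(
                spec, fill, scanner_2mm, ph.ReconConfig("psf", gaussian_fwhm_mm=w), seed=1
            )
            for w in (2.0, 6.4)
        }
        masks = ground_truth_masks(spec, imgs[2.0], mode="centre")
        for d, m in masks.items():
            assert imgs[6.4].voxels[m].max() <= imgs[2.0].voxels[m].max() + 1e-9


class TestSimulateAcquisition:
    def test_deterministic_under_seed(self, spec, fill):
        sc = ph.ScannerProfile(noise_level=0.25)
        recon = ph.ReconConfig("bpl", penalisation=400.0)
        a = ph.simulate_acquisition(spec, fill, sc, recon, seed=7)
        b = ph.simulate_acquisition(spec, fill, sc, recon, seed=7)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_meta_records_parameters(self, spec, fill, scanner_2mm):
        recon = ph.ReconConfig("bpl", penalisation=800.0)
        img = ph.simulate_acquisition(spec, fill, scanner_2mm, recon, seed=3)
        assert img.meta["recon"]["label"] == "BPL_800"
        assert img.meta["seed"] == 3

    def test_calibration_bias_propagates_multiplicatively(self, spec, fill):
        sc = ph.ScannerProfile(voxel_spacing_mm=(2.7, 2.7, 3.3), calibration_bias=1.10)
        recon = ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4)
        img = ph.simulate_acquisition(spec, fill, sc, recon, seed=1)
        masks = segment_all_spheres(img, spec)
        battery = place_background_battery(img, spec, masks)
        assert battery.grand_mean(37.0) / 2.4 == pytest.approx(1.10, rel=0.01)


class TestSimulateEnsemble:
    def test_zero_jitter_gives_identical_scanners(self, spec, fill):
        base = ph.ScannerProfile(voxel_spacing_mm=(4.1, 4.1, 4.1), noise_level=0.0)
        jit = ph.JitterSpec(calibration_bias_sd=0.0)
        ens = ph.simulate_ensemble(
            spec, fill, ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4),
            3, base, jit, seed=5,
        )
        ref = ens[0][0].voxels
        for img, profile in ens[1:]:
            np.testing.assert_array_equal(img.voxels, ref)

    def test_bias_dispersion_recovered_from_background(self, spec, fill):
        """Across-scanner SD of the measured background level ~ bias SD (3%)."""
        base = ph.ScannerProfile(voxel_spacing_mm=(4.1, 4.1, 4.1), noise_level=0.0)
        jit = ph.JitterSpec(calibration_bias_sd=0.03)
        recon = ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4)
        sds = []
        for rep in range(10):
            ens = ph.simulate_ensemble(spec, fill, recon, 6, base, jit, seed=200 + rep)
            levels = []
            for img, profile in ens:
                centre = img.nearest_index((-90.0, 0.0, 0.0))  # quiet background spot
                levels.append(img.voxels[centre] / 2.4)
            sds.append(np.std(levels, ddof=1))
        assert np.mean(sds) == pytest.approx(0.03, rel=0.35)

    def test_voxel_presets_cover_reported_matrix_sizes(self):
        in_plane = {p[0] for p in DEFAULT_VOXEL_PRESETS_MM}
        assert in_plane == {2.7, 4.1, 5.5}

    def test_too_few_scanners_rejected(self, spec, fill):
        with pytest.raises(InvalidParameterError):
            ph.simulate_ensemble(
                spec, fill, ph.ReconConfig("conventional", gaussian_fwhm_mm=6.4), 1
            )
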