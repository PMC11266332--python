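"""Geometry, counting model, thinning and the β-smoothing surrogate."""

import math

import numpy as np
import pytest
from scipy import ndimage, stats

from petiq import (
    AcquisitionConfig,
    ConfigError,
    GeometryError,
    Lesion,
    PatientSpec,
    PhantomSpec,
    ReconParams,
    beta_smooth,
    build_nema_phantom,
    build_patient_volume,
    decay_compensated_time,
    simulate_acquisition,
    subcentimeter_fraction,
    thin_counts,
)
from petiq.grids import CountVolume, Grid
from petiq.phantom import FWHM_TO_SIGMA, sphere_center_blur_fraction


class TestPhantomGeometry:
    def test_default_sphere_diameters(self, spec_41):
        assert sorted(spec_41.sphere_diameters_mm) == [10, 13, 17, 22, 28, 37]

    @pytest.mark.parametrize(
        "diameter, expected_ml",
        [(10.0, 4.0 / 3.0 * math.pi * 5.0**3 / 1000.0), (37.0, 4.0 / 3.0 * math.pi * 18.5**3 / 1000.0)],
    )
    def test_sphere_mask_volume_converges(self, spec_41, diameter, expected_ml):
        # voxel-counted volume approaches the analytic ball volume as spacing
        # shrinks; the 10 mm sphere is the 0.52 ml reference object
        spec1 = PhantomSpec(
            sphere_diameters_mm=(diameter,),
            sphere_activity_kBq_ml=spec_41.sphere_activity_kBq_ml,
        )
        errors = []
        for h in (2.0, 1.0):
            vol = build_nema_phantom(spec1, (h, h, h))
            count = int(np.sum(vol.data == spec_41.sphere_activity_kBq_ml))
            measured_ml = count * vol.grid.voxel_volume_ml
            errors.append(abs(measured_ml - expected_ml) / expected_ml)
        assert errors[1] < errors[0] or errors[1] < 0.01
        assert errors[1] < 0.05

    def test_voxel_at_sphere_center_gets_sphere_activity(self, spec_41, coarse_truth):
        grid = coarse_truth.grid
        for c in spec_41.sphere_centers_mm:
            idx = tuple(
                int(round((c[ax] - grid.origin[ax]) / grid.spacing[ax])) for ax in range(3)
            )
            assert coarse_truth.data[idx] == spec_41.sphere_activity_kBq_ml

    def test_compartment_activities_and_lung_zero(self, spec_41, coarse_truth):
        vals = set(np.unique(coarse_truth.data))
        assert vals == {
            0.0,
            spec_41.bottle_activity_kBq_ml,
            spec_41.background_activity_kBq_ml,
            spec_41.sphere_activity_kBq_ml,
        }
        # lung insert column is zero activity
        grid = coarse_truth.grid
        i = int(round(-grid.origin[0] / grid.spacing[0]))
        j = int(round(-grid.origin[1] / grid.spacing[1]))
        k = int(round(-grid.origin[2] / grid.spacing[2]))
        assert coarse_truth.data[i, j, k] == 0.0

    def test_overlapping_spheres_rejected(self):
        with pytest.raises(GeometryError):
            PhantomSpec(sphere_ring_radius_mm=10.0)

    def test_nonpositive_voxel_rejected(self, spec_41):
        with pytest.raises(ConfigError):
            build_nema_phantom(spec_41, (0.0, 2.0, 2.0))

    def test_ratio_presets(self):
        s = PhantomSpec.for_ratio("10:1")
        assert (s.sphere_activity_kBq_ml, s.background_activity_kBq_ml) == (38.9, 4.0)
        assert PhantomSpec.for_ratio("2:1").true_ratio == pytest.approx(12.0 / 5.4)


class TestAcquisition:
    def test_zero_time_gives_zero_counts(self, spec_41, coarse_truth):
        acq = AcquisitionConfig(time_per_bed_s=0.0, voxel_size_mm=(4, 4, 4), seed=1)
        counts = simulate_acquisition(coarse_truth, acq)
        assert counts.data.sum() == 0

    def test_expected_counts_arithmetic(self):
        # uniform 4 kBq/ml on the clinical 2.34×2.34×2.78 grid, 21 cps/kBq,
        # 90 s -> 115.1 expected counts per voxel
        grid = Grid.centered((40, 40, 20), (2.34, 2.34, 2.78))
        truth = np.full(grid.shape, 4.0)
        from petiq.grids import ActivityVolume

        vol = ActivityVolume(truth, grid)
        acq = AcquisitionConfig(time_per_bed_s=90.0, psf_fwhm_mm=0.0, seed=3)
        expected = 4.0 * grid.voxel_volume_ml * 21.0 * 90.0
        assert expected == pytest.approx(115.1, abs=0.05)
        counts = simulate_acquisition(vol, acq)
        n = counts.data.size
        assert counts.data.mean() == pytest.approx(expected, abs=3 * math.sqrt(expected / n))

    def test_doubling_time_doubles_expectation(self, spec_41, coarse_truth):
        a1 = AcquisitionConfig(time_per_bed_s=90.0, voxel_size_mm=(4, 4, 4), seed=5)
        a2 = AcquisitionConfig(time_per_bed_s=180.0, voxel_size_mm=(4, 4, 4), seed=5)
        c1 = simulate_acquisition(coarse_truth, a1, noiseless=True)
        c2 = simulate_acquisition(coarse_truth, a2, noiseless=True)
        np.testing.assert_allclose(c2.data, 2.0 * c1.data, rtol=1e-12)

    def test_identical_seeds_bitwise_identical(self, spec_41, coarse_truth, coarse_acq):
        c1 = simulate_acquisition(coarse_truth, coarse_acq)
        c2 = simulate_acquisition(coarse_truth, coarse_acq)
        assert np.array_equal(c1.data, c2.data)

    def test_counts_convert_back_to_concentration(self, coarse_truth, coarse_acq):
        c = simulate_acquisition(coarse_truth, coarse_acq, noiseless=True)
        act = c.to_activity()
        # away from edges the blurred background equals the filled background
        assert act.units == "kBq/ml"
        assert act.data.max() <= coarse_truth.data.max() + 1e-9


class TestThinning:
    def test_zero_reduction_identity(self, coarse_truth, coarse_acq):
        counts = simulate_acquisition(coarse_truth, coarse_acq)
        thinned = thin_counts(counts, 0.0, seed=9)
        assert np.array_equal(thinned.data, counts.data)

    def test_invalid_reduction_rejected(self, coarse_truth, coarse_acq):
        counts = simulate_acquisition(coarse_truth, coarse_acq)
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ConfigError):
                thin_counts(counts, bad, seed=0)

    def test_expected_total_conserved(self, coarse_truth, coarse_acq):
        counts = simulate_acquisition(coarse_truth, coarse_acq)
        r = 0.33
        thinned = thin_counts(counts, r, seed=11)
        total = float(counts.data.sum())
        expected = (1 - r) * total
        sd = math.sqrt(total * r * (1 - r))
        assert abs(float(thinned.data.sum()) - expected) < 4 * sd

    def test_thinned_poisson_is_poisson(self):
        # Poisson(20) thinned at r=0.5 must be indistinguishable from a
        # direct Poisson(10) sample (Poisson thinning theorem)
        rng = np.random.default_rng(42)
        lam, r, n = 20.0, 0.5, 20000
        grid = Grid.centered((n, 1, 1), (1, 1, 1))
        base = CountVolume(rng.poisson(lam, size=(n, 1, 1)).astype(np.int64), grid, 1.0)
        thinned = thin_counts(base, r, seed=43)
        direct = rng.poisson(lam * (1 - r), size=n)
        stat = stats.ks_2samp(thinned.data.ravel(), direct)
        assert stat.pvalue > 0.01

    def test_scale_tracks_keep_fraction(self, coarse_truth, coarse_acq):
        counts = simulate_acquisition(coarse_truth, coarse_acq)
        thinned = thin_counts(counts, 0.5, seed=1)
        assert thinned.scale == pytest.approx(0.5 * counts.scale)


class TestBetaSmoothing:
    def test_beta_zero_is_identity(self, coarse_truth):
        out = beta_smooth(coarse_truth, ReconParams(0.0))
        np.testing.assert_array_equal(out.data, coarse_truth.data)

    def test_global_mean_preserved(self, coarse_truth):
        out = beta_smooth(coarse_truth, ReconParams(600.0))
        assert out.data.mean() == pytest.approx(coarse_truth.data.mean(), rel=1e-6)

    def test_noise_variance_strictly_decreases_in_beta(self):
        rng = np.random.default_rng(7)
        grid = Grid.centered((40, 40, 40), (2.0, 2.0, 2.0))
        from petiq.grids import ActivityVolume

        white = ActivityVolume(rng.normal(10.0, 1.0, grid.shape), grid)
        variances = [
            beta_smooth(white, ReconParams(b)).data.var() for b in (150, 300, 450, 600)
        ]
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_sigma_scaling_law(self):
        assert ReconParams(300.0, 3.0).sigma_mm == pytest.approx(3.0)
        assert ReconParams(600.0, 3.0).sigma_mm == pytest.approx(3.0 * math.sqrt(2.0))
        with pytest.raises(ConfigError):
            ReconParams(-1.0)


class TestDecayCompensation:
    def test_zero_delay(self):
        assert decay_compensated_time(90.0, 0.0) == 90.0

    def test_one_half_life_doubles(self):
        assert decay_compensated_time(90.0, 67.71) == pytest.approx(180.0)

    def test_sixty_minute_delay(self):
        # the session schedule doubles 90 -> 180 -> 360 s; the exact
        # compensation for a 60 min delay is 166.3 s (rounded up in practice)
        assert decay_compensated_time(90.0, 60.0) == pytest.approx(166.3, abs=0.05)


class TestPatientVolume:
    def test_no_lesions_liver_max_is_liver_suv(self):
        spec = PatientSpec(lesions=())
        vol = build_patient_volume(spec, (4, 4, 4))
        from petiq import make_sphere_voi, voi_stats

        liver = make_sphere_voi(spec.liver_center_mm, 30.0, vol.grid)
        st = voi_stats(vol, liver)
        assert st.max == spec.liver_suv
        assert st.sd == 0.0

    def test_half_of_default_lesions_subcentimeter(self):
        assert subcentimeter_fraction(PatientSpec()) == 0.5

    def test_lesion_outside_body_rejected(self):
        with pytest.raises(GeometryError):
            PatientSpec(lesions=(Lesion((400.0, 0.0, 0.0), 10.0, 8.0),))

    @pytest.mark.parametrize("diameter", [17.0, 22.0, 37.0])
    def test_psf_calibration_restores_peak(self, diameter):
        # blurring the calibrated volume with the stated PSF must bring the
        # lesion peak back to its nominal SUVmax (within 5% for d >= 17 mm)
        fwhm = 4.2
        spec = PatientSpec(lesions=(Lesion((90.0, 0.0, 0.0), diameter, 10.0),))
        vol = build_patient_volume(spec, (1.5, 1.5, 1.5), calibrate_psf_fwhm_mm=fwhm)
        sigma_vox = fwhm * FWHM_TO_SIGMA / 1.5
        blurred = ndimage.gaussian_filter(vol.data, sigma_vox, mode="nearest")
        assert blurred.max() == pytest.approx(10.0, rel=0.05)

    def test_blur_fraction_closed_form_matches_numeric(self):
        # independent oracle: numerically convolve a fine-grid ball
        radius, sigma = 8.0, 2.0
        h = 0.5
        n = int(2 * (radius + 6 * sigma) / h)
        grid = Grid.centered((n, n, n), (h, h, h))
        X, Y, Z = grid.meshgrid()
        ball = ((X**2 + Y**2 + Z**2) <= radius**2).astype(float)
        central = ndimage.gaussian_filter(ball, sigma / h, mode="constant")[n // 2, n // 2, n // 2]
        assert sphere_center_blur_fraction(radius, sigma) == pytest.approx(central, abs=0.01)
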