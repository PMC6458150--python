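"""Temporal dynamics: Sigma_t^2, ACF, exposure correction, D estimation."""

import math

import numpy as np
import pytest

from ipws.cubes import AcquisitionMeta, ReferenceCube, TemporalCube
from ipws.dynamics import (
    EstimationError,
    acf_cube,
    background_acf,
    compute_sigma_t2,
    estimate_D_map,
    estimate_D_mean,
    exposure_attenuation_factor,
    exposure_correction,
    fractional_moving_mass,
    sensitivity_range,
    snr_filter,
    temporal_acf,
)
from ipws.phantom import (
    NoiseModel,
    PhantomCondition,
    make_ensemble,
    make_phantom_suite,
    phantom_meta,
    render_interference,
    render_reference,
    simulate_brownian,
)

from conftest import make_ar1_cube


class TestSigmaT2:
    def test_static_noiseless_cube_is_zero(self, temporal_meta):
        cube = TemporalCube(np.full((64, 4, 4), 0.01), temporal_meta)
        assert compute_sigma_t2(cube).sigma_t2.max() < 1e-30

    def test_cosine_trace_variance(self, temporal_meta):
        # deltaI = a cos(w t) over integer periods: Sigma_t^2 = a^2/2
        t = np.arange(64)
        a = 2e-3
        trace = 0.01 + a * np.cos(2 * np.pi * 4 * t / 64)
        cube = TemporalCube(np.tile(trace[:, None, None], (1, 3, 3)), temporal_meta)
        assert compute_sigma_t2(cube).sigma_t2 == pytest.approx(a**2 / 2, rel=1e-10)

    def test_reference_subtraction_centers_pure_noise(self, temporal_meta, rng):
        # pure-noise cube minus its own noise level: mean within +-3 SE of 0
        noise_sd = 1e-4
        sample = TemporalCube(0.01 + noise_sd * rng.standard_normal((64, 16, 16)),
                              temporal_meta)
        ref = ReferenceCube(0.01 + noise_sd * rng.standard_normal((64, 16, 16)),
                            temporal_meta)
        s = compute_sigma_t2(sample, ref)
        per_pixel_se = noise_sd**2 * math.sqrt(2.0 / 64) / math.sqrt(256)
        assert abs(s.spatial_mean) < 3 * per_pixel_se * 3  # generous 3-sigma band

    def test_negative_residuals_clamped_and_flagged(self, temporal_meta, rng):
        quiet = TemporalCube(0.01 + 1e-6 * rng.standard_normal((64, 4, 4)),
                             temporal_meta)
        loud_ref = ReferenceCube(0.01 + 1e-3 * rng.standard_normal((64, 4, 4)),
                                 temporal_meta)
        s = compute_sigma_t2(quiet, loud_ref)
        assert not s.valid_mask.any()
        assert s.sigma_t2.max() == 0.0

    def test_meta_mismatch_rejected(self, temporal_meta, rng):
        cube = TemporalCube(np.full((64, 4, 4), 0.01), temporal_meta)
        other = temporal_meta.replace(pixel_size=0.2)
        ref = ReferenceCube(0.01 + rng.random((64, 4, 4)) * 1e-5, other)
        with pytest.raises(Exception):
            compute_sigma_t2(cube, ref)


class TestExposureCorrection:
    def test_short_exposure_limit_is_identity(self):
        assert exposure_attenuation_factor(0.01) == pytest.approx(1.0, abs=5e-3)
        assert exposure_correction(1.0, t_c=1.0, exposure_time=1e-6) == \
            pytest.approx(1.0, rel=1e-5)

    def test_x_equal_one_closed_form(self):
        # f(1) = 2(e^-1) / ... = 2/e exactly: 2 * (1 - 1 + e^-1) = 2/e
        assert exposure_attenuation_factor(1.0) == pytest.approx(2.0 / math.e)
        assert exposure_correction(1.0, t_c=0.032, exposure_time=0.032) == \
            pytest.approx(math.e / 2.0)

    def test_attenuation_monotone_in_x(self):
        x = np.linspace(0.01, 20, 200)
        f = exposure_attenuation_factor(x)
        assert np.all(np.diff(f) < 0)

    def test_nonpositive_tc_rejected(self):
        with pytest.raises(ValueError):
            exposure_correction(1.0, t_c=0.0, exposure_time=0.01)

    def test_corrected_sigma_invariant_under_exposure_sweep(self):
        """Simulated variance falls with exposure; the closed-form correction
        restores a constant value (within 10%)."""
        from ipws.phantom import analytic_sigma_t2

        base = phantom_meta(n_frames=201)
        rng = np.random.default_rng(21)
        ens = make_ensemble(50, 0.001, (24, 24), base, medium_viscosity=0.0219,
                            rng=rng)  # fast spheres: t_c ~ 4.5 ms
        t_c = 1.0 / (4 * base.wavenumber**2 * ens.true_D)
        corrected, raw = [], []
        for exposure in (0.004, 0.012, 0.032):
            meta = phantom_meta(n_frames=201, exposure_time=exposure,
                                frame_interval=0.032)
            traj = simulate_brownian(ens, 0.032, 201, substeps=12, seed=5,
                                     exposure_time=exposure)
            cube = render_interference(traj, ens, meta, (24, 24))
            s = compute_sigma_t2(cube)
            raw.append(s.spatial_mean)
            corrected.append(exposure_correction(s.spatial_mean, t_c, exposure))
        assert raw[2] < 0.75 * raw[0]  # attenuation is real
        spread = (max(corrected) - min(corrected)) / np.mean(corrected)
        assert spread < 0.10


class TestFractionalMovingMass:
    def test_unit_calibration_is_identity(self, temporal_meta, rng):
        cube = TemporalCube(0.01 + 1e-4 * rng.standard_normal((64, 4, 4)),
                            temporal_meta)
        s = compute_sigma_t2(cube)
        np.testing.assert_array_equal(fractional_moving_mass(s), s.sigma_t2)

    def test_negative_calibration_rejected(self):
        with pytest.raises(ValueError):
            fractional_moving_mass(np.ones((2, 2)), -1.0)

    def test_mf_linear_in_volume_fraction(self):
        """Spatial-mean m_f proportional to Phi through the origin."""
        phis = (0.0005, 0.001, 0.002)
        means = []
        for phi in phis:
            real = make_phantom_suite([PhantomCondition(radius_nm=50,
                                                        volume_fraction=phi)],
                                      seed=31, shape=(32, 32), substeps=4)[0]
            s = compute_sigma_t2(real.cube, real.reference)
            means.append(s.spatial_mean)
        coef = np.polyfit(phis, means, 1)
        fit = np.polyval(coef, phis)
        ss_res = np.sum((np.array(means) - fit)**2)
        ss_tot = np.sum((np.array(means) - np.mean(means))**2)
        assert 1 - ss_res / ss_tot > 0.98
        assert abs(coef[1]) < 0.2 * max(means)  # intercept ~ origin

    def test_mf_increases_with_radius_at_fixed_phi(self):
        means = []
        for r in (25, 50, 100):
            real = make_phantom_suite([PhantomCondition(radius_nm=r)],
                                      seed=37, shape=(32, 32), substeps=4)[0]
            means.append(compute_sigma_t2(real.cube, real.reference).spatial_mean)
        assert means[0] < means[1] < means[2]


class TestTemporalAcf:
    def test_constant_trace_zero_acf(self):
        res = temporal_acf(np.full(64, 3.0), 0.032)
        np.testing.assert_allclose(res.acf, 0.0, atol=1e-20)

    def test_matches_direct_lag_sums(self, rng):
        trace = rng.standard_normal(128)
        res = temporal_acf(trace, frame_interval=0.01)
        d = trace - trace.mean()
        brute = np.array([np.sum(d[:128 - m] * d[m:]) / 128 for m in range(128)])
        np.testing.assert_allclose(res.acf, brute, atol=1e-12)

    def test_cosine_acf(self):
        # cos(2 pi f t), integer cycles: acf(m)/acf(0) ~ cos(2 pi f m)
        n, cycles = 512, 8
        t = np.arange(n)
        trace = np.cos(2 * np.pi * cycles * t / n)
        res = temporal_acf(trace, frame_interval=1.0, normalize=True)
        # exactness: FFT path equals the direct lag-sum oracle to < 1e-6
        d = trace - trace.mean()
        brute = np.array([np.sum(d[:n - m] * d[m:]) / n for m in range(40)])
        np.testing.assert_allclose(res.acf[:40], brute / brute[0], atol=1e-6)
        # and the normalized early lags follow cos(2 pi f m) up to the
        # O(1/(n sin w)) edge terms of the finite biased estimator
        m = np.arange(10)
        expected = np.cos(2 * np.pi * cycles * m / n) * (1 - m / n)
        np.testing.assert_allclose(res.acf[:10], expected, atol=0.02)

    def test_ar1_correlation_time_recovery(self):
        cube = make_ar1_cube(t_c=0.32, n_frames=2000, shape=(4, 4),
                             frame_interval=0.032, seed=8)
        tcs = [temporal_acf(cube.intensities[:, i, j], 0.032).t_c
               for i in range(4) for j in range(4)]
        assert np.nanmedian(tcs) == pytest.approx(0.32, rel=0.10)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            temporal_acf(np.ones(3), 0.032)


class TestSnrFilter:
    def test_threshold_is_sqrt2(self):
        bg = np.array([1.0, 0.1])
        acf = np.zeros((2, 1, 3))
        acf[0] = [[0.999, math.sqrt(2) + 1e-9, 2.0]]
        mask = snr_filter(acf, bg)
        np.testing.assert_array_equal(mask, [[False, True, True]])

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            snr_filter(np.ones((2, 2, 2)), np.array([0.0]))

    def test_empty_phantom_mostly_filtered(self):
        """A no-sphere cube against its own reference: >= 95% invalid."""
        meta = phantom_meta(n_frames=201)
        nm = NoiseModel()
        rng = np.random.default_rng(41)
        a = render_reference(meta, (24, 24), 0.0092, nm, rng)
        b = render_reference(meta, (24, 24), 0.0092, nm, rng)
        delta = a.intensities - a.intensities.mean(axis=0)
        acfs = acf_cube(delta)
        mask = snr_filter(acfs, background_acf(b))
        assert mask.mean() < 0.05


class TestEstimateDMean:
    def test_exact_exponential_ensemble(self):
        """Ensemble with exact ACF exp(-tau/t_c), t_c = 0.5 s: D = 1/(4 k^2 t_c)
        recovered to < 2% (long traces keep the sample-mean bias negligible)."""
        t_c = 0.5
        cube = make_ar1_cube(t_c=t_c, n_frames=8000, shape=(16, 16),
                             frame_interval=0.032, seed=2)
        bg = np.zeros(33)
        bg[0] = 1e-12
        res = estimate_D_mean(cube, bg)
        k = cube.meta.wavenumber
        assert k == pytest.approx(16.68, rel=1e-3)
        expected = 1.0 / (4 * k**2 * t_c)
        assert expected == pytest.approx(1.80e-3, rel=0.01)
        assert res.mean_D == pytest.approx(expected, rel=0.02)

    def test_frozen_cube_raises_estimation_error(self, temporal_meta, rng):
        frozen = TemporalCube(0.01 + 1e-6 * rng.standard_normal((64, 8, 8)),
                              temporal_meta)
        ref = ReferenceCube(0.01 + 1e-3 * rng.standard_normal((64, 8, 8)),
                            temporal_meta)
        with pytest.raises(EstimationError):
            estimate_D_mean(frozen, ref)

    def test_phantom_recovery_within_15_percent(self):
        real = make_phantom_suite([PhantomCondition(radius_nm=50)], seed=17,
                                  shape=(48, 48))[0]
        res = estimate_D_mean(real.cube, real.reference)
        assert res.mean_D == pytest.approx(real.manifest.true_D, rel=0.15)

    def test_geometric_average_mode_runs(self):
        real = make_phantom_suite([PhantomCondition(radius_nm=50)], seed=18,
                                  shape=(24, 24), substeps=4)[0]
        res = estimate_D_mean(real.cube, real.reference, acf_average="geometric")
        assert res.mean_D > 0
        assert res.provenance["acf_average"] == "geometric"

    def test_matches_brute_force_loop_implementation(self):
        """FFT/vectorized pipeline equals an explicit-loop re-implementation
        of the same eleven steps on an 8x8 cube, to 1e-10 relative."""
        real = make_phantom_suite([PhantomCondition(radius_nm=50)], seed=19,
                                  shape=(8, 8), substeps=4)[0]
        cube, ref = real.cube, real.reference
        res = estimate_D_mean(cube, ref, slope_lags=(1, 2), max_lag=8)

        n = cube.n_frames
        n_lags = 8
        # background ACF: spatial mean of per-pixel lag sums
        rdat = ref.intensities
        bg = np.zeros(n_lags)
        for i in range(8):
            for j in range(8):
                d = rdat[:, i, j] - rdat[:, i, j].mean()
                for m in range(n_lags):
                    bg[m] += np.sum(d[:n - m] * d[m:]) / n
        bg /= 64.0
        # per-pixel ACFs, SNR filter, background subtraction, normalization
        curves = []
        for i in range(8):
            for j in range(8):
                d = cube.intensities[:, i, j] - cube.intensities[:, i, j].mean()
                c = np.array([np.sum(d[:n - m] * d[m:]) / n for m in range(n_lags)])
                if c[0] < math.sqrt(2) * bg[0]:
                    continue
                c = c - bg
                if c[0] <= 0:
                    continue
                curves.append(c / c[0])
        mean_curve = np.mean(curves, axis=0)
        cut = n_lags
        for m in range(1, n_lags):
            if mean_curve[m] <= 0:
                cut = m
                break
        assert cut > 2
        decay = (math.log(mean_curve[2]) - math.log(mean_curve[1])) / \
            cube.meta.frame_interval
        d_brute = -decay / (4 * cube.meta.wavenumber**2)
        assert res.mean_D == pytest.approx(d_brute, rel=1e-10)
        assert res.n_valid_pixels == len(curves)


class TestEstimateDMap:
    def test_sigma_zero_equals_per_pixel_path(self):
        real = make_phantom_suite([PhantomCondition(radius_nm=50)], seed=23,
                                  shape=(16, 16), substeps=4)[0]
        a = estimate_D_map(real.cube, real.reference, gaussian_sigma_px=0.0)
        b = estimate_D_map(real.cube, real.reference, gaussian_sigma_px=2.0)
        assert a.valid_mask.any()
        # smoothed and unsmoothed agree on average but differ pixelwise
        assert not np.array_equal(a.D, b.D)

    def test_uniform_cube_map_is_uniform(self):
        real = make_phantom_suite([PhantomCondition(radius_nm=37.5)], seed=29,
                                  shape=(32, 32))[0]
        res = estimate_D_map(real.cube, real.reference, gaussian_sigma_px=2.0)
        vals = res.D[res.valid_mask]
        assert vals.size > 100
        assert vals.std() / vals.mean() < 0.35

    def test_two_region_cube_separates(self, rng):
        """Pixels from two AR(1) populations with 4x different decay rates:
        region medians separate by > 2x."""
        fast = make_ar1_cube(t_c=0.05, n_frames=402, shape=(8, 16), seed=51)
        slow = make_ar1_cube(t_c=0.20, n_frames=402, shape=(8, 16), seed=52)
        data = np.concatenate([fast.intensities, slow.intensities], axis=1)
        cube = TemporalCube(data, fast.meta)
        bg = np.zeros(4)
        bg[0] = 1e-12
        res = estimate_D_map(cube, bg, gaussian_sigma_px=0.0)
        d_fast = np.nanmedian(res.D[:8])
        d_slow = np.nanmedian(res.D[8:])
        assert d_fast > 2 * d_slow


class TestSensitivityRange:
    def test_phantom_window(self):
        k = 2 * np.pi * 1.46 / 0.55
        d_min, d_max = sensitivity_range(0.032, 6.432, k)
        assert d_min == pytest.approx(1.40e-4, rel=0.01)
        assert d_max == pytest.approx(2.81e-2, rel=0.01)

    def test_longer_acquisition_halves_d_min(self):
        k = 17.0
        a = sensitivity_range(0.032, 6.432, k)
        b = sensitivity_range(0.032, 12.864, k)
        assert b[0] == pytest.approx(a[0] / 2)
        assert a[0] < a[1] and b[0] < b[1]
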