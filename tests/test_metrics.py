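"""FWHM, depth SNR, contrast ratio / CNR and ROI statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwus import (
    PeakTruncatedError,
    ReconGrid,
    ROIStats,
    cnr,
    contrast_ratio,
    fwhm,
    psf_lateral_fwhm,
    roi_stats,
    snr_depth,
)


class TestFwhm:
    def test_gaussian_closed_form(self):
        x = np.linspace(-10, 10, 2001)
        sigma = 1.7
        width = fwhm(np.exp(-(x**2) / (2 * sigma**2)), x)
        assert width == pytest.approx(2 * math.sqrt(2 * math.log(2)) * sigma, rel=0.01)

    def test_triangle_half_base(self):
        x = np.linspace(-2, 2, 401)
        w = 1.3
        v = np.clip(1 - np.abs(x) / w, 0, None)
        assert fwhm(v, x) == pytest.approx(w, rel=1e-6)

    def test_truncated_peak_signaled(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(PeakTruncatedError):
            fwhm(np.exp(-x), x)  # never falls below half on the left

    def test_plateau_resolved_to_midpoint(self):
        x = np.arange(11.0)
        v = np.array([0, 0, 0.2, 1, 1, 1, 1, 1, 0.2, 0, 0])
        # plateau spans x 3..7; interpolated crossings at 2.375 and 7.625
        assert fwhm(v, x) == pytest.approx(5.25)

    def test_agrees_with_dense_resampling_oracle(self):
        # asymmetric unimodal profile: two-sided Gaussian with unequal widths
        x = np.linspace(-8, 8, 161)
        v = np.where(x < 0.4, np.exp(-((x - 0.4) ** 2) / (2 * 0.8**2)),
                     np.exp(-((x - 0.4) ** 2) / (2 * 1.9**2)))
        fine = np.linspace(x[0], x[-1], 16001)
        vf = np.interp(fine, x, v)
        half = vf.max() / 2
        above = vf >= half
        lo = fine[np.argmax(above)]
        hi = fine[len(above) - 1 - np.argmax(above[::-1])]
        assert fwhm(v, x) == pytest.approx(hi - lo, abs=2 * (fine[1] - fine[0]) + 1e-9)


class TestPsfLateralFwhm:
    def test_recovers_inserted_gaussian_blob(self):
        grid = ReconGrid(-5.0, 5.0, 401, 15.0, 25.0, 101)
        X, Z = np.meshgrid(grid.x_mm, grid.z_mm)
        sx = 0.4  # mm
        env = np.exp(-((X - 0.5) ** 2) / (2 * sx**2) - ((Z - 20.0) ** 2) / (2 * 0.6**2))
        m = psf_lateral_fwhm(env, grid, (0.5, 20.0))
        expected_um = 2 * math.sqrt(2 * math.log(2)) * sx * 1e3
        assert m.fwhm_um == pytest.approx(expected_um, rel=0.02)

    def test_independent_wires_measured_independently(self):
        grid = ReconGrid(-5.0, 5.0, 401, 10.0, 40.0, 301)
        X, Z = np.meshgrid(grid.x_mm, grid.z_mm)

        def blob(z0, sx):
            return np.exp(-(X**2) / (2 * sx**2) - ((Z - z0) ** 2) / (2 * 0.5**2))

        env = blob(15.0, 0.3) + blob(35.0, 0.7)
        m1 = psf_lateral_fwhm(env, grid, (0.0, 15.0))
        m2 = psf_lateral_fwhm(env, grid, (0.0, 35.0))
        assert m1.fwhm_um == pytest.approx(2.3548 * 0.3 * 1e3, rel=0.02)
        assert m2.fwhm_um == pytest.approx(2.3548 * 0.7 * 1e3, rel=0.02)


class TestSnrDepth:
    def test_constant_ratio_stack(self, rng):
        stack = 10.0 + rng.standard_normal((400, 50))
        prof = snr_depth(stack)
        assert np.allclose(prof.snr_db, 20.0, atol=1.0)

    def test_identical_repetitions_flagged_infinite(self):
        stack = np.tile(np.linspace(1, 2, 30), (5, 1))
        assert np.all(np.isinf(snr_depth(stack).snr_db))

    def test_rayleigh_moment_oracle(self, rng):
        # Rayleigh(sigma): mu = sigma sqrt(pi/2), sd = sigma sqrt(2 - pi/2)
        stack = rng.rayleigh(1.0, size=(20000, 12))
        expected = 20 * math.log10(math.sqrt(math.pi / 2) / math.sqrt(2 - math.pi / 2))
        assert np.allclose(snr_depth(stack).snr_db, expected, atol=0.15)
        assert expected == pytest.approx(5.64, abs=0.01)

    def test_requires_two_repetitions(self):
        with pytest.raises(ValueError):
            snr_depth(np.ones((1, 10)))

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_positive_scaling(self, scale):
        base = np.random.default_rng(3).rayleigh(1.0, size=(50, 8))
        a = snr_depth(base).snr_db
        b = snr_depth(base * scale).snr_db
        assert np.allclose(a, b, atol=1e-9)


class TestContrast:
    def test_cr_reference_points(self):
        b = ROIStats(0.9, 0.1, 100, "background")
        assert contrast_ratio(ROIStats(0.9, 0.1, 100, "lesion"), b) == pytest.approx(0.0)
        assert contrast_ratio(ROIStats(0.09, 0.1, 100, "lesion"), b) == pytest.approx(-20.0)
        assert contrast_ratio(ROIStats(0.3, 0.1, 100, "lesion"), b) == pytest.approx(
            20 * math.log10(1 / 3)
        )

    def test_cr_anechoic_flagged_minus_inf(self):
        b = ROIStats(0.9, 0.1, 100)
        assert contrast_ratio(ROIStats(1e-300, 0.0, 10, "lesion"), b) < -1000 or math.isinf(
            contrast_ratio(ROIStats(0.0, 0.0, 10, "lesion"), b)
        )

    def test_cr_antisymmetric_under_role_swap(self):
        a = ROIStats(0.3, 0.05, 50, "lesion")
        b = ROIStats(0.9, 0.1, 50, "background")
        assert contrast_ratio(a, b) == pytest.approx(-contrast_ratio(b, a))

    def test_cnr_zero_when_means_equal(self):
        a = ROIStats(0.5, 0.2, 10)
        b = ROIStats(0.5, 0.1, 10)
        assert cnr(a, b) == 0.0

    def test_cnr_equal_sigmas_closed_form(self):
        a = ROIStats(0.2, 0.3, 10, "lesion")
        b = ROIStats(1.0, 0.3, 10, "background")
        assert cnr(a, b) == pytest.approx(0.8 / (0.3 * math.sqrt(2)))

    def test_cnr_both_modes_arithmetic_oracle(self):
        a = ROIStats(0.2, 0.1, 10, "lesion")
        b = ROIStats(1.0, 0.3, 10, "background")
        assert cnr(a, b, "sum") == pytest.approx(0.8 / math.sqrt(0.09 + 0.01))
        assert cnr(a, b, "difference") == pytest.approx(0.8 / math.sqrt(0.09 - 0.01))

    def test_cnr_sign_flips_on_swap(self):
        a = ROIStats(0.2, 0.1, 10)
        b = ROIStats(1.0, 0.3, 10)
        assert cnr(a, b) == pytest.approx(-cnr(b, a))

    def test_cnr_difference_mode_rejects_dominant_lesion_sigma(self):
        a = ROIStats(0.2, 0.5, 10)
        b = ROIStats(1.0, 0.3, 10)
        with pytest.raises(ValueError):
            cnr(a, b, "difference")


class TestRoiStats:
    GRID = ReconGrid(-10.0, 10.0, 201, 5.0, 25.0, 201)

    def test_constant_image(self):
        env = np.full(self.GRID.shape, 2.5)
        s = roi_stats(env, self.GRID, (0.0, 15.0), 3.0)
        assert s.mu == 2.5 and s.sigma == 0.0

    def test_tiny_radius_single_pixel(self):
        env = np.zeros(self.GRID.shape)
        env[100, 100] = 7.0  # pixel at (x=0, z=15)
        s = roi_stats(env, self.GRID, (0.0, 15.0), 0.05)
        assert s.n == 1 and s.mu == 7.0

    def test_checkerboard_counting_oracle(self):
        env = np.indices(self.GRID.shape).sum(axis=0) % 2 * 2.0
        s = roi_stats(env, self.GRID, (0.0, 15.0), 8.0)
        assert s.mu == pytest.approx(1.0, abs=0.01)
        assert s.sigma == pytest.approx(1.0, abs=0.01)

    def test_empty_roi_rejected(self):
        env = np.ones(self.GRID.shape)
        fan = np.zeros(self.GRID.shape, dtype=bool)
        with pytest.raises(ValueError):
            roi_stats(env, self.GRID, (0.0, 15.0), 1.0, fan=fan)


def test_contrast_magnitude_grows_with_compounding():
    """Anechoic-lesion |CR| is non-decreasing in the number of compounding angles."""
    from pwus.experiments import lesion_contrast_vs_angles

    crs = lesion_contrast_vs_angles(angle_counts=(1, 5, 11, 21), seed=0)
    mags = [abs(crs[n]) for n in (1, 5, 11, 21)]
    assert all(b >= a - 1.0 for a, b in zip(mags, mags[1:]))  # 1 dB simulation slack
    assert mags[-1] > mags[0]
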