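"""Delay-and-sum reconstruction, adaptive weighting, envelope and fan mask."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwus import (
    ArrayGeometry,
    BeamformedImage,
    PlaneWaveSequence,
    ReconGrid,
    ScattererField,
    bmode_pipeline,
    coherence_factor,
    compound,
    das_beamform,
    das_delay,
    envelope,
    fan_mask,
    log_compress,
    simulate_channel_data,
    std_weight,
    weighted_beamform,
)

GRID = ReconGrid(-5.0, 5.0, 101, 15.0, 25.0, 101)


def _point_data(x=0.0, z=20.0, n_angles=5):
    geom = ArrayGeometry()
    seq = PlaneWaveSequence.from_span(n_angles, 16.0)
    scat = ScattererField(np.array([[x, z]]), np.array([1.0]))
    return simulate_channel_data(scat, geom, seq)


class TestDasDelay:
    def test_on_axis_round_trip(self):
        assert das_delay(0.0, 20.0, 0.0, 0.0, 1540.0) == pytest.approx(2 * 20e-3 / 1540.0)

    def test_off_axis_element_never_earlier(self):
        t0 = das_delay(0.0, 20.0, 0.0, 0.0, 1540.0)
        t1 = das_delay(0.0, 20.0, 0.0, 7.75, 1540.0)
        assert t1 >= t0

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.floats(-20, 20), z=st.floats(0.5, 100), xe=st.floats(-8, 8),
        deg=st.floats(-30, 30),
    )
    def test_matches_geometric_path_oracle(self, x, z, xe, deg):
        th = math.radians(deg)
        # independent oracle: explicit transmit-plane distance + Euclidean receive leg
        tx_path = z * math.cos(th) + x * math.sin(th)
        rx_path = math.sqrt((x - xe) ** 2 + z**2)
        oracle = (tx_path + rx_path) * 1e-3 / 1540.0
        assert das_delay(x, z, th, xe, 1540.0) == pytest.approx(oracle, rel=1e-12)

    def test_rejects_nonpositive_depth(self):
        with pytest.raises(ValueError):
            das_delay(0.0, 0.0, 0.0, 0.0, 1540.0)


class TestDasBeamform:
    def test_zero_data_gives_zero_image(self, geometry, seq21):
        data = simulate_channel_data(
            ScattererField(np.empty((0, 2)), np.empty(0)), geometry, seq21, n_samples=512
        )
        bfi = das_beamform(data, GRID)
        assert np.all(bfi.images == 0.0)

    def test_point_scatterer_localized_at_peak(self):
        data = _point_data(x=1.0, z=20.0)
        env = envelope(compound(das_beamform(data, GRID)))
        iz, ix = np.unravel_index(env.argmax(), env.shape)
        assert abs(GRID.x_mm[ix] - 1.0) <= GRID.dx_mm
        assert abs(GRID.z_mm[iz] - 20.0) <= GRID.dz_mm

    def test_linearity_in_channel_amplitude(self):
        data = _point_data()
        bfi = das_beamform(data, GRID)
        data.samples *= 2.0
        bfi2 = das_beamform(data, GRID)
        assert np.allclose(bfi2.images, 2.0 * bfi.images)

    def test_reconstruction_is_deterministic(self):
        data = _point_data()
        a = bmode_pipeline(data, GRID)
        b = bmode_pipeline(data, GRID)
        assert np.array_equal(a.values_db, b.values_db)


class TestCompound:
    def test_single_angle_identity(self):
        img = np.random.default_rng(0).normal(size=(1, 101, 101))
        assert np.array_equal(compound(BeamformedImage(img, GRID)), img[0])

    def test_mean_of_copies_is_copy(self):
        one = np.random.default_rng(1).normal(size=(101, 101))
        stack = np.stack([one] * 4)
        assert np.allclose(compound(BeamformedImage(stack, GRID)), one)

    def test_opposite_signs_cancel(self):
        one = np.random.default_rng(2).normal(size=(101, 101))
        stack = np.stack([one, -one])
        assert np.allclose(compound(BeamformedImage(stack, GRID)), 0.0)


class TestApertureWeights:
    def test_cf_identical_samples_is_one(self):
        assert coherence_factor(np.full(32, 3.7)) == pytest.approx(1.0)

    def test_cf_single_hot_channel(self):
        s = np.zeros(32)
        s[5] = 2.0
        assert coherence_factor(s) == pytest.approx(1 / 32)

    def test_cf_zero_aperture_defined_as_zero(self):
        assert coherence_factor(np.zeros(32)) == 0.0

    def test_cf_noise_expectation(self, rng):
        # i.i.d. zero-mean noise across N=32 channels has E[CF] ~ 1/N
        cf = coherence_factor(rng.normal(size=(32, 20000)), axis=0)
        assert np.mean(cf) == pytest.approx(1 / 32, rel=0.05)

    def test_std_weight_coherent_limit(self):
        assert std_weight(np.full(8, 2.0), eps=0.0) == pytest.approx(1.0)

    def test_std_weight_zero_mean(self):
        w = std_weight(np.array([1.0, -1.0, 1.0, -1.0]))
        assert w == pytest.approx(0.0, abs=1e-9)

    def test_std_weight_arithmetic_oracle(self):
        # [1,1,1,3]: mu = 1.5, population sigma = sqrt(3)/2
        sigma = math.sqrt(3) / 2
        expected = 1.5 / (1.5 + sigma)
        assert std_weight(np.array([1.0, 1.0, 1.0, 3.0]), eps=0.0) == pytest.approx(expected)

    @pytest.mark.parametrize("method", ["coh", "std"])
    def test_weighted_never_exceeds_das(self, method):
        data = _point_data()
        das = das_beamform(data, GRID).images
        weighted = weighted_beamform(data, GRID, method).images
        assert np.all(np.abs(weighted) <= np.abs(das) + 1e-9)


class TestEnvelopeAndCompression:
    def test_pure_tone_envelope_is_amplitude(self):
        z = np.arange(512)
        rf = 3.0 * np.cos(2 * np.pi * 0.125 * z)  # integer cycle count: no leakage
        env = envelope(rf[:, None])[:, 0]
        assert np.allclose(env[50:-50], 3.0, rtol=1e-3)

    def test_zero_in_zero_out(self):
        assert np.all(envelope(np.zeros((64, 4))) == 0.0)

    def test_am_modulation_recovered(self):
        z = np.arange(4096)
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * z / 1500.0)
        rf = mod * np.cos(2 * np.pi * 0.12 * z)
        env = envelope(rf[:, None])[:, 0]
        mid = slice(500, -500)
        assert np.max(np.abs(env[mid] - mod[mid]) / mod[mid]) < 0.02

    def test_log_compress_reference_points(self):
        env = np.array([[1.0, 0.1, 1e-6]])
        db = log_compress(env, dynamic_range_db=60.0)
        assert db[0, 0] == 0.0
        assert db[0, 1] == pytest.approx(-20.0)
        assert db[0, 2] == -60.0

    def test_log_compress_rejects_all_zero(self):
        with pytest.raises(ValueError):
            log_compress(np.zeros((4, 4)))


class TestFanMask:
    def test_center_pixel_valid_far_corner_invalid(self, geometry):
        grid = ReconGrid(-40.0, 40.0, 81, 1.0, 80.0, 80)
        mask = fan_mask(grid, geometry, math.radians(16.0))
        assert mask[40, 40]  # beneath array centre
        assert not mask[0, 0]  # shallow far-lateral corner

    def test_matches_per_pixel_geometric_oracle(self, geometry):
        grid = ReconGrid(-30.0, 30.0, 61, 2.0, 60.0, 59)
        th = math.radians(16.0)
        mask = fan_mask(grid, geometry, th)
        half = geometry.aperture_mm / 2
        oracle = np.zeros(grid.shape, dtype=bool)
        for i, z in enumerate(grid.z_mm):
            for j, x in enumerate(grid.x_mm):
                oracle[i, j] = abs(x) <= half + z * math.tan(th)
        assert np.array_equal(mask, oracle)
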