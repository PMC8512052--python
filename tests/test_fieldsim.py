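"""Array geometry, steering delays, field synthesis and channel-data simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwus import (
    ArrayGeometry,
    PlaneWaveSequence,
    ScattererField,
    element_positions,
    far_field_scan,
    pressure_field,
    simulate_channel_data,
    steering_delays,
)


class TestElementPositions:
    def test_single_element_at_origin(self):
        assert element_positions(ArrayGeometry(n_elements=1)) == pytest.approx([0.0])

    def test_default_array_span(self, geometry):
        pos = element_positions(geometry)
        assert pos[-1] - pos[0] == pytest.approx(31 * 0.5)
        assert len(pos) == 32
        assert np.allclose(np.diff(pos), 0.5)

    @settings(derandomize=True, max_examples=25)
    @given(n=st.integers(1, 128), pitch=st.floats(0.1, 2.0))
    def test_positions_symmetric_about_zero(self, n, pitch):
        pos = element_positions(ArrayGeometry(n_elements=n, pitch_mm=pitch, kerf_mm=0.05))
        assert np.allclose(pos, -pos[::-1])


class TestSteeringDelays:
    def test_zero_angle_all_zero(self, geometry):
        assert np.all(steering_delays(geometry, 0.0) == 0.0)

    def test_adjacent_element_difference(self, geometry):
        tau = steering_delays(geometry, math.radians(10.0), c=1540.0)
        expected = 0.5e-3 * math.sin(math.radians(10.0)) / 1540.0
        assert np.allclose(np.diff(tau), expected)

    def test_sixteen_degree_oracle(self, geometry):
        # independent trigonometric oracle: wavefront arrival-time differences
        angle, c = math.radians(16.0), 1540.0
        pos_m = element_positions(geometry) * 1e-3
        oracle = pos_m * math.sin(angle) / c
        oracle -= oracle.min()
        assert np.allclose(steering_delays(geometry, angle, c), oracle, rtol=1e-12)

    def test_angle_out_of_range(self, geometry):
        with pytest.raises(ValueError):
            steering_delays(geometry, math.radians(95.0))


class TestPressureField:
    def test_spherical_spreading_single_source(self):
        geom = ArrayGeometry(n_elements=1, pitch_mm=0.5)
        r = np.array([5.0, 10.0, 20.0, 40.0])
        amp = pressure_field(geom, np.zeros(1), np.zeros(4), r, sources_per_element=1)
        assert np.allclose(amp * r, amp[0] * r[0], rtol=1e-9)

    def test_unsteered_mainlobe_at_zero(self, geometry):
        angles = np.linspace(-60, 60, 241)
        scan = far_field_scan(geometry, np.zeros(32), angles)
        assert abs(angles[scan.argmax()]) <= 0.5

    @pytest.mark.parametrize("steer", [-16.0, 16.0])
    def test_steered_mainlobe_within_one_degree(self, geometry, steer):
        delays = steering_delays(geometry, math.radians(steer))
        angles = np.linspace(-35, 35, 281)
        scan = far_field_scan(geometry, delays, angles)
        assert abs(angles[scan.argmax()] - steer) <= 1.0

    def test_grating_lobe_at_negative_angles_when_steering_positive(self, geometry):
        # pitch ~ wavelength at 3 MHz: a steered beam grows a grating lobe
        delays = steering_delays(geometry, math.radians(16.0))
        angles = np.linspace(-80, 0, 161)
        scan = far_field_scan(geometry, delays, angles)
        import scipy.signal

        peaks, props = scipy.signal.find_peaks(scan, prominence=0.1 * scan.max())
        lobe_angles = angles[peaks]
        assert np.any(lobe_angles < -30.0)

    def test_rejects_nonpositive_depth(self, geometry):
        with pytest.raises(ValueError):
            pressure_field(geometry, np.zeros(32), np.array([0.0]), np.array([-1.0]))


class TestSimulateChannelData:
    def test_round_trip_arrival_at_central_element(self, geometry):
        z0 = 30.0
        seq = PlaneWaveSequence(angles_rad=(0.0,))
        scat = ScattererField(np.array([[0.0, z0]]), np.array([1.0]))
        data = simulate_channel_data(scat, geometry, seq, sampling_rate=40e6)
        # envelope peak of the central element pair straddles x = 0
        import scipy.signal

        rec = data.samples[0, 15] + data.samples[0, 16]
        env = np.abs(scipy.signal.hilbert(rec))
        t_peak = env.argmax() / 40e6
        x_half = element_positions(geometry)[15] * 1e-3
        expected = (z0 * 1e-3 + math.hypot(x_half, z0 * 1e-3)) / 1540.0
        assert abs(t_peak - expected) <= 1.0 / 40e6

    def test_empty_field_is_silent(self, geometry, seq21):
        scat = ScattererField(np.empty((0, 2)), np.empty(0))
        data = simulate_channel_data(scat, geometry, seq21, noise_std=0.0)
        assert np.all(data.samples == 0.0)

    def test_superposition_of_two_scatterers(self, geometry, seq21):
        s1 = ScattererField(np.array([[2.0, 20.0]]), np.array([1.0]))
        s2 = ScattererField(np.array([[-3.0, 35.0]]), np.array([0.5]))
        n = 2048
        d1 = simulate_channel_data(s1, geometry, seq21, n_samples=n)
        d2 = simulate_channel_data(s2, geometry, seq21, n_samples=n)
        d12 = simulate_channel_data(s1 + s2, geometry, seq21, n_samples=n)
        assert np.allclose(d12.samples, d1.samples + d2.samples, atol=1e-12)

    def test_seeded_noise_is_reproducible(self, geometry, seq21):
        scat = ScattererField(np.array([[0.0, 25.0]]), np.array([1.0]))
        kw = dict(noise_std=0.1, seed=7)
        a = simulate_channel_data(scat, geometry, seq21, **kw)
        b = simulate_channel_data(scat, geometry, seq21, **kw)
        assert np.array_equal(a.samples, b.samples)

    def test_scatterer_beyond_record_rejected(self, geometry, seq21):
        scat = ScattererField(np.array([[0.0, 90.0]]), np.array([1.0]))
        with pytest.raises(ValueError, match="record length"):
            simulate_channel_data(scat, geometry, seq21, n_samples=100)

    def test_sampling_rate_cap_enforced(self, geometry, seq21):
        scat = ScattererField(np.array([[0.0, 10.0]]), np.array([1.0]))
        with pytest.raises(ValueError, match="50 MSa/s"):
            simulate_channel_data(scat, geometry, seq21, sampling_rate=80e6)


class TestSequenceValidation:
    def test_angles_must_increase(self):
        with pytest.raises(ValueError):
            PlaneWaveSequence(angles_rad=(0.1, 0.1))

    def test_angle_magnitude_bounded(self):
        with pytest.raises(ValueError):
            PlaneWaveSequence(angles_rad=(math.radians(95.0),))

    def test_span_constructor(self):
        seq = PlaneWaveSequence.from_span(21, 16.0)
        deg = np.rad2deg(seq.angles_rad)
        assert deg[0] == pytest.approx(-16.0) and deg[-1] == pytest.approx(16.0)
        assert len(deg) == 21
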