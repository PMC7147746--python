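"""Discharge detection, wavefront-speed estimation, space-time patterns,
synchrony and the closed-form estimates, on constructed inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epileptor2d import (burst_synchrony, detect_discharges,
                         discharge_intervals, electrodiffusion_speed,
                         envelope_front, front_arrival_times,
                         nernst_sensitivity, rate_onsets, space_time_pattern,
                         wavefront_speed)
from epileptor2d.analysis import WaveFront


def square_pulse_trace(t, t_on, t_off, low=3.0, high=6.0, edge=2.0):
    """Trapezoidal potassium pulse crossing 4 mM on both edges."""
    K = np.full_like(t, low)
    rise = (t >= t_on) & (t < t_on + edge)
    K[rise] = low + (high - low) * (t[rise] - t_on) / edge
    K[(t >= t_on + edge) & (t < t_off)] = high
    fall = (t >= t_off) & (t < t_off + edge)
    K[fall] = high - (high - low) * (t[fall] - t_off) / edge
    return K


class TestDetectDischarges:
    def test_single_pulse_detected_at_programmed_crossing(self):
        t = np.arange(0, 120, 0.01)
        K = square_pulse_trace(t, 40.0, 70.0)
        events = detect_discharges(t, K)
        assert len(events) == 1
        ev = events[0]
        # crossing of 4 mM on a 3->6 ramp over 2 s happens 1/3 in
        assert ev.onset_t == pytest.approx(40.0 + 2.0 / 3, abs=0.02)
        assert ev.peak_K_o == pytest.approx(6.0)
        # offset at the 3.5 mM hysteresis level on the falling edge
        assert ev.offset_t == pytest.approx(70.0 + 2.0 * 5 / 6, abs=0.02)

    def test_flat_trace_gives_no_events(self):
        t = np.arange(0, 60, 0.01)
        assert detect_discharges(t, np.full_like(t, 3.0)) == []

    def test_chatter_within_min_gap_is_merged(self):
        t = np.arange(0, 60, 0.01)
        K = np.full_like(t, 3.0)
        K[(t > 10) & (t < 14)] = 6.0
        K[(t > 15) & (t < 20)] = 6.0   # 1 s gap < 5 s min_gap
        K[(t > 40) & (t < 45)] = 6.0   # separate event
        events = detect_discharges(t, K)
        assert len(events) == 2
        assert events[0].duration == pytest.approx(10.0, abs=0.1)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_discharges(np.array([]), np.array([]))

    @given(shift=st.floats(-1000, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_time_shift(self, shift):
        t = np.arange(0, 120, 0.02)
        K = square_pulse_trace(t, 30.0, 60.0)
        base = detect_discharges(t, K)
        shifted = detect_discharges(t + shift, K)
        assert len(base) == len(shifted) == 1
        assert shifted[0].onset_t - base[0].onset_t == pytest.approx(
            shift, abs=1e-6)
        assert shifted[0].duration == pytest.approx(base[0].duration,
                                                    abs=1e-6)

    def test_invariant_to_supersampling(self):
        t = np.arange(0, 120, 0.25)
        K = square_pulse_trace(t, 30.0, 60.0)
        t_fine = np.arange(0, 119.75, 0.01)
        K_fine = np.interp(t_fine, t, K)
        ev_a = detect_discharges(t, K)[0]
        ev_b = detect_discharges(t_fine, K_fine)[0]
        assert ev_b.onset_t == pytest.approx(ev_a.onset_t, abs=0.02)
        assert ev_b.duration == pytest.approx(ev_a.duration, abs=0.04)

    def test_intervals(self):
        t = np.arange(0, 300, 0.05)
        K = np.full_like(t, 3.0)
        for on in (50, 150, 250):
            K[(t > on) & (t < on + 20)] = 6.0
        events = detect_discharges(t, K)
        assert np.allclose(discharge_intervals(events), [100.0, 100.0],
                           atol=0.1)


def translating_pulse(speed, r, t, extent=0.5, launch=5.0,
                      low=3.0, high=8.0):
    """K(t, r): a pulse of the given spatial extent moving outward."""
    T, R = np.meshgrid(t, r, indexing="ij")
    front = speed * np.maximum(T - launch, 0.0)
    K = np.where((R <= front) & (R > front - extent), high, low)
    return K


class TestWavefrontSpeed:
    def test_two_point_slope(self):
        front = WaveFront(arrivals=[(0.0, 0.0), (2.0, 20.0)], threshold=4.0,
                          wave_index=0)
        assert wavefront_speed(front).speed == pytest.approx(0.1)

    @pytest.mark.parametrize("speed", [0.01, 0.035, 0.11, 1.0, 10.0])
    def test_recovers_programmed_speed_within_2_percent(self, speed):
        rng = np.random.default_rng(0)
        r = np.arange(0, 3.0, 0.075)
        transit = 2.5 / speed
        span = transit + 20
        t = np.arange(0, span, min(0.25, transit / 100))
        K = translating_pulse(speed, r, t, extent=3.0)
        # jitter the sampling amplitude slightly
        K = K + rng.normal(0, 0.01, K.shape)
        front = front_arrival_times(t, r, K)
        fit = wavefront_speed(front)
        assert fit.speed == pytest.approx(speed, rel=0.02)

    def test_stationary_bump_reports_missing_positions(self):
        r = np.arange(0, 3.0, 0.075)
        t = np.arange(0, 50, 0.25)
        K = np.full((t.size, r.size), 3.0)
        K[:, r <= 1.0] = 8.0
        front = front_arrival_times(t, r, K)
        covered = [a[0] for a in front.arrivals]
        assert max(covered) <= 1.0
        assert len(front.missing) > 0
        with pytest.raises(ValueError, match="simultaneous"):
            wavefront_speed(front)

    def test_second_wave_separable_from_overlapping_first(self):
        """Per-position event indexing keeps two waves apart even when the
        second starts at the centre before the first reaches the rim."""
        r = np.arange(0, 3.0, 0.075)
        t = np.arange(0, 400, 0.25)
        K1 = translating_pulse(0.02, r, t, launch=5.0)
        K2 = translating_pulse(0.02, r, t, launch=150.0)
        K = np.maximum(K1, K2)
        for idx, expected_launch in ((0, 5.0), (1, 150.0)):
            front = front_arrival_times(t, r, K, wave_index=idx)
            fit = wavefront_speed(front)
            assert fit.speed == pytest.approx(0.02, rel=0.02)

    def test_too_few_arrivals_rejected(self):
        front = WaveFront(arrivals=[(0.5, 1.0)], threshold=4.0, wave_index=0)
        with pytest.raises(ValueError, match="at least 2"):
            wavefront_speed(front)


class TestEnvelopeFront:
    def test_recovers_speed_of_noisy_burst_envelope(self):
        rng = np.random.default_rng(1)
        r = np.arange(0, 3.0, 0.075)
        t = np.arange(0, 120, 0.25)
        speed = 0.05
        T, R = np.meshgrid(t, r, indexing="ij")
        recruited = R <= speed * np.maximum(T - 5.0, 0.0)
        # intermittent bursts inside the recruited region
        bursting = rng.random(T.shape) < 0.4
        nu = np.where(recruited & bursting, 80.0, 0.0)
        front = envelope_front(t, r, nu)
        fit = wavefront_speed(front)
        assert fit.speed == pytest.approx(speed, rel=0.1)


class TestRateOnsets:
    def test_potassium_read_at_burst_envelope_onset(self):
        t = np.arange(0, 200, 0.01)
        K = 3.0 + 0.01 * t          # slow ramp
        nu = np.zeros_like(t)
        nu[t >= 100.0] = 50.0       # discharge begins at t = 100
        onsets = rate_onsets(t, nu, K)
        assert len(onsets) == 1
        t_on, K_on = onsets[0]
        assert t_on == pytest.approx(100.0, abs=1.0)
        assert K_on == pytest.approx(4.0, abs=0.02)


class TestSpaceTimePattern:
    def test_synchronous_bursts_have_near_zero_inclination(self):
        t = np.arange(0, 2.0, 0.001)
        y = np.arange(0, 6.0, 0.075)
        V = np.zeros((t.size, y.size))
        for burst_t in (0.5, 1.2):
            V[(t >= burst_t) & (t < burst_t + 0.05), :] = 60.0
        pat = space_time_pattern(t, y, V)
        incl = pat.burst_onset_inclinations(threshold=25.0)
        assert len(incl) == 2
        assert np.allclose(incl, 0.0, atol=1e-6)

    def test_travelling_burst_inclination_is_reciprocal_speed(self):
        t = np.arange(0, 80.0, 0.05)
        y = np.arange(0, 6.0, 0.075)
        V = np.zeros((t.size, y.size))
        speed = 0.1  # mm/s -> inclination 10 s/mm
        T, Y = np.meshgrid(t, y, indexing="ij")
        V[(Y <= speed * T) ] = 60.0
        pat = space_time_pattern(t, y, V)
        incl = pat.burst_onset_inclinations(threshold=25.0)
        assert incl[0] == pytest.approx(10.0, rel=0.05)

    def test_window_outside_data_rejected(self):
        t = np.arange(0, 1.0, 0.01)
        y = np.arange(0, 6.0, 0.075)
        V = np.zeros((t.size, y.size))
        with pytest.raises(ValueError, match="window"):
            space_time_pattern(t, y, V, window=(5.0, 6.0))


class TestBurstSynchrony:
    def test_identical_traces_have_zero_delays(self):
        t = np.arange(0, 100, 0.001)
        sig = np.zeros_like(t)
        for on in (10, 30, 50):
            sig[(t >= on) & (t < on + 0.2)] = 60.0
        table = burst_synchrony(t, {"A": sig, "B": sig.copy()})
        assert len(table) > 0
        assert np.allclose(table["delay"], 0.0)

    def test_shifted_trace_reports_the_shift(self):
        t = np.arange(0, 200, 0.001)
        a = np.zeros_like(t)
        a[(t >= 50) & (t < 80)] = 60.0     # one long discharge
        b = np.zeros_like(t)
        b[(t >= 53) & (t < 83)] = 60.0     # same, 3 s later
        table = burst_synchrony(t, {"A": a, "B": b})
        dis = table[table["kind"] == "discharge"]
        assert len(dis) >= 1
        assert dis["delay"].iloc[0] == pytest.approx(3.0, abs=0.1)

    def test_needs_two_traces(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(ValueError):
            burst_synchrony(t, {"A": np.zeros_like(t)})


class TestClosedFormEstimates:
    def test_electrodiffusion_drift_speed(self):
        # mobility 5e-4 cm^2/(s V), gradient 2 mV per 0.1 mm -> 1 um/s
        assert electrodiffusion_speed(5e-4, 20.0) == pytest.approx(1e-3)
        assert electrodiffusion_speed(5e-4, 0.0) == 0.0
        assert electrodiffusion_speed(5e-4, 40.0) == pytest.approx(2e-3)

    def test_nernst_sensitivities(self):
        assert nernst_sensitivity(7.0) == pytest.approx(3.8, abs=0.01)
        assert nernst_sensitivity(130.0) == pytest.approx(0.2, abs=0.005)
        assert nernst_sensitivity(10.0) == pytest.approx(2.66, abs=0.01)
        with pytest.raises(ValueError):
            nernst_sensitivity(0.0)
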