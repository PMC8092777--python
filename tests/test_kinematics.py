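"""Body-wave evaluation and the two-stage envelope fitting chain."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from fishwake.kinematics import (
    MEASURED_SWIMMING_PARAMS,
    AmplitudeProfile,
    BodyWaveParams,
    FitRegionError,
    FlatTrackError,
    InsufficientDataError,
    MidlineTrack,
    envelope,
    estimate_frequency,
    estimate_point_amplitudes,
    estimate_wavelength,
    evaluate_displacement,
    fit_bodywave,
    fit_envelope,
)
from fishwake.synthetic import TrackGenConfig, generate_track

from conftest import FIT_STATIONS


def sinusoid_track(freq=1.0, amp=0.05, stations=(0.1, 0.5, 0.9), wavelength=None,
                   fps=60.0, duration=4.0, t0=0.0):
    """Plain cosine track builder (independent of the model evaluator)."""
    stations = np.asarray(stations, dtype=float)
    times = t0 + np.arange(int(fps * duration) + 1) / fps
    lag = np.zeros_like(stations) if wavelength is None else 2 * np.pi * stations / wavelength
    disp = amp * np.cos(2 * np.pi * freq * times[None, :] - lag[:, None])
    return MidlineTrack(stations=stations, times=times, displacements=disp)


class TestEvaluateDisplacement:
    def test_zero_envelope_is_identically_zero(self):
        p = BodyWaveParams(0.0, -1.0, 0.0, 1.0, 1.0, 2.0)
        x = np.linspace(0, 1.2, 7)
        assert np.all(evaluate_displacement(x, 0.3, p) == 0.0)

    @pytest.mark.parametrize("speed", sorted(MEASURED_SWIMMING_PARAMS))
    def test_periodic_in_one_tail_beat(self, speed):
        p = MEASURED_SWIMMING_PARAMS[speed]
        x = np.linspace(0, 1.13, 9)
        h0 = evaluate_displacement(x, 0.123, p)
        h1 = evaluate_displacement(x, 0.123 + 1.0 / p.frequency, p)
        np.testing.assert_allclose(h0, h1, rtol=0, atol=1e-12)

    def test_snout_displacement_at_time_zero_is_sum_of_coefficients(self, params152):
        # at x = 0, t = 0 the cosine is 1, so h = a + c = 0.0250 BL
        assert evaluate_displacement(0.0, 0.0, params152) == pytest.approx(0.0250, abs=1e-12)

    def test_rejects_non_finite_and_negative_inputs(self, params152):
        with pytest.raises(ValueError):
            evaluate_displacement(np.nan, 0.0, params152)
        with pytest.raises(ValueError):
            evaluate_displacement(-0.1, 0.0, params152)


class TestEnvelope:
    def test_degenerate_envelopes(self):
        zero = BodyWaveParams(0.0, -1.0, 0.0, 1.0, 1.0, 2.0)
        const = BodyWaveParams(1.0, 0.0, 0.0, 1.0, 1.0, 2.0)
        x = np.linspace(0, 1.2, 5)
        assert np.all(envelope(x, zero) == 0.0)
        np.testing.assert_allclose(envelope(x, const), 1.0)

    def test_hand_value_at_mid_body(self, params152):
        # 0.0187·e^{−5.96·0.4} + 0.00630·e^{2.65·0.4}, evaluated independently
        expected = 0.0187 * math.exp(-2.384) + 0.0063 * math.exp(1.06)
        assert envelope(0.4, params152) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0199079, abs=5e-7)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 0.05),
        b=st.floats(-8.0, 0.0),
        c=st.floats(1e-4, 0.01),
        d=st.floats(0.5, 3.5),
        lam=st.floats(0.5, 2.0),
        f=st.floats(0.5, 3.0),
        x=st.floats(0.0, 1.2),
    )
    def test_envelope_is_supremum_of_displacement(self, a, b, c, d, lam, f, x):
        p = BodyWaveParams(a, b, c, d, lam, f)
        t = np.linspace(0.0, 1.0 / f, 2001)
        peak = np.max(np.abs(evaluate_displacement(x, t, p)))
        env = envelope(x, p)
        assert peak <= env + 1e-12
        assert peak >= env * (1.0 - 1e-5)


class TestAmplitudeEstimation:
    def test_round_trip_matches_envelope(self, clean_track, params152):
        prof = estimate_point_amplitudes(clean_track)
        np.testing.assert_allclose(
            prof.amplitudes, envelope(clean_track.stations, params152), rtol=1e-7
        )

    def test_zero_track_gives_zero_amplitudes(self):
        track = sinusoid_track(amp=0.0)
        prof = estimate_point_amplitudes(track, frequency=1.0)
        np.testing.assert_allclose(prof.amplitudes, 0.0, atol=1e-15)

    def test_single_station_pure_sinusoid(self):
        track = sinusoid_track(freq=1.0, amp=0.05, stations=(0.5,))
        prof = estimate_point_amplitudes(track)
        assert prof.amplitudes[0] == pytest.approx(0.05, rel=1e-7)

    def test_short_track_is_rejected(self, params152):
        cfg = TrackGenConfig(params=params152, duration=2.0)
        track = generate_track(cfg)
        with pytest.raises(InsufficientDataError):
            estimate_point_amplitudes(track, frequency=0.4)


class TestFrequencyEstimation:
    def test_recovers_generating_frequency(self, clean_track):
        assert estimate_frequency(clean_track) == pytest.approx(2.12, rel=1e-6)

    def test_constructed_one_hertz_sinusoid(self):
        assert estimate_frequency(sinusoid_track(freq=1.0)) == pytest.approx(1.0, rel=1e-7)

    def test_invariant_to_sampling_rate_doubling(self, params152):
        base = dict(params=params152, stations=FIT_STATIONS, duration=4.0)
        f60 = estimate_frequency(generate_track(TrackGenConfig(fps=60.0, **base)))
        f120 = estimate_frequency(generate_track(TrackGenConfig(fps=120.0, **base)))
        assert f120 == pytest.approx(f60, rel=1e-7)

    def test_invariant_to_time_shift(self):
        f0 = estimate_frequency(sinusoid_track(freq=1.3))
        f1 = estimate_frequency(sinusoid_track(freq=1.3, t0=0.37))
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_flat_track_is_rejected(self):
        with pytest.raises(FlatTrackError):
            estimate_frequency(sinusoid_track(amp=0.0))


class TestWavelengthEstimation:
    def test_recovers_generating_wavelength(self, clean_track):
        lam = estimate_wavelength(clean_track)
        assert lam == pytest.approx(1.05, rel=1e-6)

    def test_standing_wave_reported_as_infinite(self):
        track = sinusoid_track(wavelength=None)  # all stations in phase
        assert math.isinf(estimate_wavelength(track, frequency=1.0))

    def test_constructed_two_body_length_wave(self):
        track = sinusoid_track(wavelength=2.0, stations=(0.1, 0.3, 0.5, 0.8, 1.1))
        assert estimate_wavelength(track, frequency=1.0) == pytest.approx(2.0, rel=1e-9)

    def test_needs_three_usable_stations(self):
        track = sinusoid_track(stations=(0.2, 0.8), wavelength=1.0)
        with pytest.raises(InsufficientDataError):
            estimate_wavelength(track, frequency=1.0)


class TestEnvelopeFit:
    def test_single_exponential_exact(self):
        x = np.array([0.05, 0.1, 0.45, 0.6, 0.75, 0.85, 1.0, 1.13])
        amps = 0.0063 * np.exp(2.65 * x)
        a, b, c, d = fit_envelope(AmplitudeProfile(x, amps), iterations=1)
        assert c == pytest.approx(0.0063, rel=1e-12)
        assert d == pytest.approx(2.65, rel=1e-12)

    def test_converged_fit_recovers_both_terms(self, params152):
        x = np.array(FIT_STATIONS)
        prof = AmplitudeProfile(x, envelope(x, params152))
        a, b, c, d = fit_envelope(prof, iterations=200)
        assert (a, b, c, d) == pytest.approx((0.0187, -5.96, 0.0063, 2.65), rel=1e-8)

    def test_one_pass_tail_slope_is_biased_low(self, params152):
        """Head-term contamination drags the one-pass d below the generating
        value; a direct nonlinear least-squares fit of the two-exponential
        envelope on the same samples serves as the unbiased oracle."""
        x = np.array(FIT_STATIONS)
        amps = envelope(x, params152)
        _, _, _, d_one = fit_envelope(AmplitudeProfile(x, amps), iterations=1)
        popt, _ = curve_fit(
            lambda xx, a, b, c, d: a * np.exp(b * xx) + c * np.exp(d * xx),
            x, amps, p0=(0.01, -4.0, 0.005, 2.5), maxfev=20000,
        )
        d_oracle = popt[3]
        assert d_oracle == pytest.approx(2.65, rel=1e-6)
        assert d_one < d_oracle
        assert abs(d_one - d_oracle) < 0.15

    def test_one_pass_equals_converged_when_head_term_absent(self):
        x = np.array(FIT_STATIONS)
        amps = 0.005 * np.exp(2.4 * x)
        one = fit_envelope(AmplitudeProfile(x, amps), iterations=1)
        many = fit_envelope(AmplitudeProfile(x, amps), iterations=100)
        # with no head term the stage-2 residuals vanish identically, so the
        # iteration is stationary after the first pass
        assert one[2:] == pytest.approx(many[2:], rel=1e-10)

    def test_nonpositive_residuals_identify_offending_stations(self):
        x = np.array([0.05, 0.1, 0.15, 0.2, 0.45, 0.6, 0.75, 1.0])
        amps = 0.0063 * np.exp(2.65 * x)
        amps[0] *= 0.5  # head amplitude below the tail-term prediction
        with pytest.raises(FitRegionError, match="0.05"):
            fit_envelope(AmplitudeProfile(x, amps), iterations=1)

    def test_too_few_stations_in_region(self):
        x = np.array([0.05, 0.1, 0.45])
        with pytest.raises(InsufficientDataError):
            fit_envelope(AmplitudeProfile(x, np.full(3, 0.01)))


class TestFullFit:
    @pytest.mark.parametrize("speed", sorted(MEASURED_SWIMMING_PARAMS))
    def test_noiseless_round_trip_recovers_all_parameters(self, speed):
        p = MEASURED_SWIMMING_PARAMS[speed]
        track = generate_track(
            TrackGenConfig(params=p, stations=FIT_STATIONS, duration=4.0)
        )
        fit = fit_bodywave(track)
        q = fit.params
        for name in ("a", "b", "c", "d", "wavelength", "frequency"):
            assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-6), name
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_track_degrades_but_retains_fit_quality(self, params152):
        track = generate_track(
            TrackGenConfig(
                params=params152, stations=FIT_STATIONS, duration=4.0,
                noise_sd=0.002, seed=7,
            )
        )
        fit = fit_bodywave(track)
        assert 0.9 < fit.r_squared < 1.0

    def test_time_shifted_track_reconstructs_with_phase_offset(self, params152):
        """The fit absorbs an arbitrary time origin into a global phase."""
        stations = np.array(FIT_STATIONS)
        times = 0.41 + np.arange(241) / 60.0
        disp = evaluate_displacement(stations[:, None], times[None, :], params152)
        track = MidlineTrack(stations, times, disp)
        fit = fit_bodywave(track)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.params.frequency == pytest.approx(2.12, rel=1e-6)
        assert fit.params.wavelength == pytest.approx(1.05, rel=1e-6)

    def test_flat_track_is_rejected(self):
        with pytest.raises(FlatTrackError):
            fit_bodywave(sinusoid_track(amp=0.0))


class TestTrackCsv:
    def test_round_trip_preserves_track(self, clean_track, tmp_path):
        path = tmp_path / "track.csv"
        clean_track.to_csv(path)
        back = MidlineTrack.from_csv(path)
        np.testing.assert_allclose(back.stations, clean_track.stations)
        np.testing.assert_allclose(back.times, clean_track.times)
        np.testing.assert_allclose(back.displacements, clean_track.displacements)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,point_id\n0.0,a\n")
        with pytest.raises(ValueError, match="missing columns"):
            MidlineTrack.from_csv(path)
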