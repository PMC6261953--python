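"""Band-pass filtering, spectral peaks, ripple/theta events, ETAs."""

import numpy as np
import pytest

from thetaoff import (
    RIPPLE_BAND,
    THETA_BAND,
    bandpass,
    detect_ripples,
    detect_theta_run_epochs,
    event_triggered_segments,
    segment_states,
    spectral_peak,
    state_modulation_test,
)
from thetaoff.core import RegularTimeSeries
from thetaoff.synth import SessionConfig, generate_lfp, generate_speed_trace


def tone(freq, duration=10.0, rate=2000.0, amp=1.0):
    t = np.arange(0, duration, 1 / rate)
    return RegularTimeSeries(amp * np.sin(2 * np.pi * freq * t), rate, units="mV")


class TestBandpass:
    def test_passband_tone_amplitude_preserved(self):
        out = bandpass(tone(7.0), THETA_BAND)
        # discard filter edges
        mid = out.data[2000:-2000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_strongly_attenuated(self):
        out = bandpass(tone(7.0), RIPPLE_BAND)
        assert np.abs(out.data[2000:-2000]).max() < 0.01

    def test_zero_in_zero_out(self):
        ts = RegularTimeSeries(np.zeros(4000), 2000.0)
        assert np.all(bandpass(ts, THETA_BAND).data == 0.0)

    def test_linearity(self, rng):
        x = RegularTimeSeries(rng.standard_normal(4000), 2000.0)
        y = RegularTimeSeries(rng.standard_normal(4000), 2000.0)
        lhs = bandpass(x.copy_with(2.0 * x.data + 3.0 * y.data), THETA_BAND).data
        rhs = 2.0 * bandpass(x, THETA_BAND).data + 3.0 * bandpass(y, THETA_BAND).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(RegularTimeSeries(np.zeros(100), 100.0), RIPPLE_BAND)


class TestSpectralPeak:
    @pytest.mark.parametrize(
        "freq,band", [(7.1, THETA_BAND), (144.5, RIPPLE_BAND)]
    )
    def test_pure_tone_peak(self, freq, band):
        ts = tone(freq, duration=20.0)
        peak, confident = spectral_peak(ts, band, nperseg_s=10.0)
        assert confident
        assert peak == pytest.approx(freq, abs=0.15)

    def test_white_noise_flagged_low_confidence(self, rng):
        ts = RegularTimeSeries(rng.standard_normal(40_000), 2000.0)
        peak, confident = spectral_peak(ts, THETA_BAND, nperseg_s=4.0)
        assert THETA_BAND.low_hz <= peak <= THETA_BAND.high_hz
        assert not confident

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            spectral_peak(tone(7.0, duration=1.0), THETA_BAND)


def make_burst_lfp(rng, duration=100.0, rate=2000.0, bursts=(), noise_sd=0.05,
                   freq=150.0, snr=8.0):
    """Noise with Gaussian-envelope ripple bursts at given (center, dur_ms)."""
    n = int(duration * rate)
    t = np.arange(n) / rate
    noise = noise_sd * rng.standard_normal(n)
    bp_noise = bandpass(RegularTimeSeries(noise, rate), RIPPLE_BAND)
    amp = snr * bp_noise.data.std()
    x = noise.copy()
    for tc, dur_ms in bursts:
        sigma = dur_ms / 1000.0 / 4.0
        mask = np.abs(t - tc) < 4 * sigma
        x[mask] += amp * np.exp(-((t[mask] - tc) ** 2) / (2 * sigma**2)) * np.sin(
            2 * np.pi * freq * (t[mask] - tc)
        )
    return RegularTimeSeries(x, rate, units="mV")


class TestDetectRipples:
    def test_pure_noise_low_false_positive_rate(self, rng):
        lfp = make_burst_lfp(rng, duration=100.0)
        events = detect_ripples(lfp)
        assert len(events) / 100.0 <= 0.05

    def test_single_burst_detected_with_duration(self, rng):
        lfp = make_burst_lfp(rng, duration=60.0, bursts=[(30.0, 80.0)])
        events = detect_ripples(lfp)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration_ms == pytest.approx(80.0, abs=15.0)
        assert ev.t_peak_s == pytest.approx(30.0, abs=0.01)
        assert RIPPLE_BAND.low_hz <= ev.peak_freq_hz <= RIPPLE_BAND.high_hz

    def test_nearby_bursts_merged(self, rng):
        # two 60-ms bursts 30 ms apart (edge to edge) merge into one event
        lfp = make_burst_lfp(rng, duration=60.0, bursts=[(30.0, 60.0), (30.09, 60.0)])
        events = detect_ripples(lfp)
        assert len(events) == 1

    def test_count_monotone_nonincreasing_in_threshold(self, rng):
        bursts = [(10.0 + 5 * k, 70.0) for k in range(8)]
        lfp = make_burst_lfp(rng, duration=60.0, bursts=bursts)
        counts = [
            len(detect_ripples(lfp, threshold_sd=thr)) for thr in (3.0, 5.0, 7.0, 9.0)
        ]
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))

    def test_recall_and_precision_on_synthetic_session(self):
        config = SessionConfig(duration_s=120.0, lfp_rate_hz=2000.0, seed=7,
                               ripple_rate_hz=0.2, ripple_snr_sd=8.0)
        speed, epochs = generate_speed_trace(config)
        lfp, truth = generate_lfp(epochs, config)
        seg = segment_states(speed)
        events = detect_ripples(lfp, segmentation=seg)
        det = np.array([e.t_peak_s for e in events])
        true = truth["t_center_s"].to_numpy()
        assert len(true) >= 5
        recall = np.mean([np.abs(det - t).min() < 0.05 for t in true])
        precision = np.mean([np.abs(true - t).min() < 0.05 for t in det])
        assert recall >= 0.95
        assert precision >= 0.95


class TestThetaRunEpochs:
    def test_one_epoch_per_locomotion_bout(self, small_session):
        seg = segment_states(small_session.speed)
        epochs = detect_theta_run_epochs(small_session.lfp, seg)
        loco = seg.by_state("locomotion")
        assert len(epochs) == len(loco)
        for ep, e in zip(epochs, loco):
            assert ep.t_onset_s == pytest.approx(e.t_start_s)
            assert ep.power_above_immobility

    def test_theta_peak_matches_configured_frequency(self, small_session):
        seg = segment_states(small_session.speed)
        epochs = detect_theta_run_epochs(small_session.lfp, seg)
        peaks = [e.theta_peak_hz for e in epochs if np.isfinite(e.theta_peak_hz)]
        assert len(peaks) > 0
        # per-epoch Welch resolution is coarse; pooled test is in acceptance
        assert np.median(peaks) == pytest.approx(7.1, abs=1.0)

    def test_no_locomotion_gives_empty_list(self):
        speed = RegularTimeSeries(np.zeros(2000), 100.0, units="cm/s")
        lfp = RegularTimeSeries(np.random.default_rng(0).standard_normal(40_000), 2000.0)
        seg = segment_states(speed)
        assert detect_theta_run_epochs(lfp, seg) == []


class TestEventTriggeredSegments:
    def test_constant_trace_gives_flat_mean(self):
        dff = RegularTimeSeries(np.full(3000, 12.0), 30.0, units="%dF/F")
        eta = event_triggered_segments(dff, np.array([30.0, 50.0]), window_s=(1, 2))
        assert eta.n_events == 2
        np.testing.assert_allclose(eta.mean_trace, 12.0)

    def test_planted_step_recovered_exactly(self):
        rate = 30.0
        data = np.zeros(3000)
        events = np.array([30.0, 50.0, 70.0])
        for t_ev in events:
            data[int(t_ev * rate) :] += 0.0  # keep baseline zero
            data[int(t_ev * rate) : int(t_ev * rate) + 60] = 5.0
        dff = RegularTimeSeries(data, rate, units="%dF/F")
        eta = event_triggered_segments(dff, events, window_s=(1.0, 3.0))
        post = eta.mean_trace[(eta.lags_s > 0.1) & (eta.lags_s < 1.9)]
        np.testing.assert_allclose(post, 5.0)
        pre = eta.mean_trace[eta.lags_s < -0.1]
        np.testing.assert_allclose(pre, 0.0)

    def test_mean_of_random_noise_shrinks_with_n(self, rng):
        rate = 30.0
        dff = RegularTimeSeries(rng.standard_normal(60_000), rate)
        few = event_triggered_segments(dff, rng.uniform(50, 1950, 5), window_s=(1, 1))
        many = event_triggered_segments(dff, rng.uniform(50, 1950, 200), window_s=(1, 1))
        assert np.abs(many.mean_trace).mean() < np.abs(few.mean_trace).mean()

    def test_edge_events_dropped_with_warning(self):
        dff = RegularTimeSeries(np.zeros(300), 30.0)
        with pytest.warns(UserWarning, match="dropped"):
            eta = event_triggered_segments(dff, np.array([0.5, 5.0]), window_s=(1, 2))
        assert eta.n_events == 1

    def test_no_usable_events_rejected(self):
        dff = RegularTimeSeries(np.zeros(90), 30.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                event_triggered_segments(dff, np.array([0.1]), window_s=(1, 3))


class TestStateModulation:
    def test_identical_samples_p_near_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = state_modulation_test(np.ones(10), np.ones(10))
        assert p == 1.0

    def test_disjoint_samples_minimal_p(self):
        a = np.arange(1, 11, dtype=float)
        b = np.arange(11, 21, dtype=float)
        u, p = state_modulation_test(a, b)
        assert u == 0.0
        # exact two-sided minimum for n=m=10: 2/C(20,10)
        assert p == pytest.approx(2.0 / 184_756, rel=1e-6)

    def test_planted_state_effect_detected(self, small_session):
        from thetaoff import compute_dff, detect_transients, state_peak_stats

        seg = segment_states(small_session.speed)
        trace = small_session.ca_traces[0]  # theta_off
        dff = compute_dff(trace)
        prof = state_peak_stats(dff, seg, detect_transients(dff))
        _, p = state_modulation_test(
            prof.states["immobility"].period_means,
            prof.states["locomotion"].period_means,
        )
        assert p < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            state_modulation_test(np.array([]), np.ones(3))
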