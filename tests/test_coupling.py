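"""Gap-junction coupling: CC, spikelets, synchrony, blocker effects."""

import dataclasses

import numpy as np
import pytest

from thetaoff import (
    blocker_effect,
    cc_regression,
    conditional_peak_by_presyn_spike,
    coupling_coefficient,
    spike_crosscorrelogram,
    spikelet_components,
    vm_crosscorrelation,
)
from thetaoff.core import RegularTimeSeries
from thetaoff.synth import CircuitSpec, generate_paired_recording
from thetaoff.synth.ephys import APInjectionProtocol, SinusoidProtocol, StepProtocol


@pytest.fixture(scope="module")
def circuit():
    return CircuitSpec()  # 200 MOhm cells, 1.62 GOhm junction


@pytest.fixture(scope="module")
def step_pair(circuit):
    return generate_paired_recording(circuit, StepProtocol())


class TestCouplingCoefficient:
    def test_matches_resistor_network_closed_form(self, circuit, step_pair):
        cc = coupling_coefficient(step_pair)
        want = circuit.r_in_2_mohm / (circuit.r_junction_mohm + circuit.r_in_2_mohm)
        assert cc == pytest.approx(want, rel=0.01)
        assert cc == pytest.approx(0.11, abs=0.005)

    def test_uncoupled_limit(self):
        circ = CircuitSpec(r_junction_mohm=np.inf)
        pair = generate_paired_recording(circ, StepProtocol())
        cc = coupling_coefficient(pair)
        assert abs(cc) < 0.01  # not coupled by the CC >= 0.01 rule

    def test_symmetric_circuit_symmetric_cc(self, circuit):
        pair_12 = generate_paired_recording(circuit, StepProtocol(target_cell=1))
        pair_21 = generate_paired_recording(circuit, StepProtocol(target_cell=2))
        cc_12 = coupling_coefficient(pair_12)
        # direction 2 -> 1: swap roles
        from thetaoff.coupling import PairedRecording

        swapped = PairedRecording(
            v1=pair_21.v2, v2=pair_21.v1, protocol=pair_21.protocol
        )
        # careful: v1 must be the stimulated cell
        cc_21 = coupling_coefficient(
            PairedRecording(v1=pair_21.v2, v2=pair_21.v1, protocol=pair_21.protocol)
        )
        assert cc_12 == pytest.approx(cc_21, rel=1e-6)

    def test_missing_step_protocol_rejected(self, step_pair):
        from thetaoff.coupling import PairedRecording

        bare = PairedRecording(v1=step_pair.v1, v2=step_pair.v2, protocol={})
        with pytest.raises(ValueError, match="step"):
            coupling_coefficient(bare)

    def test_integration_step_stability_guard(self):
        circ = CircuitSpec(tau_m_ms=0.2)  # dt/tau too coarse at 10 kHz
        with pytest.raises(ValueError, match="step too coarse"):
            generate_paired_recording(circ, StepProtocol())


class TestCcRegression:
    def test_linear_circuit_slope_equals_single_step_cc(self, circuit):
        dv1, dv2 = [], []
        for amp in (-180.0, -140.0, -100.0, -60.0):
            pair = generate_paired_recording(circuit, StepProtocol(amplitude_pa=amp))
            proto = pair.protocol
            from thetaoff.coupling import _step_delta

            dv1.append(_step_delta(pair.v1, proto["t_on_s"], proto["t_off_s"]))
            dv2.append(_step_delta(pair.v2, proto["t_on_s"], proto["t_off_s"]))
        slope, se = cc_regression(np.array(dv1), np.array(dv2))
        assert slope == pytest.approx(0.11, abs=0.005)
        assert se < 0.01

    def test_planted_noisy_slope_recovered(self, rng):
        dv1 = np.linspace(-30, -5, 8)
        dv2 = 0.11 * dv1 + 0.02 * rng.standard_normal(8)
        slope, se = cc_regression(dv1, dv2)
        assert slope == pytest.approx(0.11, abs=3 * se + 0.01)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            cc_regression(np.full(4, -10.0), np.linspace(0, 1, 4))
        with pytest.raises(ValueError):
            cc_regression(np.array([1.0, 2.0]), np.array([0.1, 0.2]))


class TestSpikelet:
    def test_slow_ahp_conducted_better_than_fast_spike(self, circuit):
        """Low-pass junction: |negative (AHP) component| > positive (spike)."""
        times = (0.4, 0.9, 1.4)
        pair = generate_paired_recording(
            circuit, APInjectionProtocol(spike_times_s=times, total_s=2.0)
        )
        pos, neg = spikelet_components(pair, np.array(times))
        # attenuation relative to source amplitude (80 mV spike, 8 mV AHP)
        assert abs(neg) / 8.0 > pos / 80.0
        assert pos > 0 and neg < 0

    def test_zero_ahp_template_gives_no_negative_component(self):
        circ = CircuitSpec(ahp_mv=0.0)
        times = (0.4, 0.9, 1.4)
        pair = generate_paired_recording(
            circ, APInjectionProtocol(spike_times_s=times, total_s=2.0)
        )
        pos, neg = spikelet_components(pair, np.array(times))
        assert abs(neg) < 0.05
        assert pos > 0

    def test_no_coupling_gives_flat_spikelet(self):
        circ = CircuitSpec(r_junction_mohm=np.inf)
        pair = generate_paired_recording(
            circ, APInjectionProtocol(spike_times_s=(0.4, 0.9, 1.3), total_s=2.0)
        )
        pos, neg = spikelet_components(pair, np.array([0.4, 0.9, 1.3]))
        assert abs(pos) < 1e-9 and abs(neg) < 1e-9

    def test_few_spikes_warns(self, circuit):
        pair = generate_paired_recording(
            circuit, APInjectionProtocol(spike_times_s=(0.4,), total_s=1.0)
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            spikelet_components(pair, np.array([0.4]))


class TestConditionalPeak:
    def test_ahp_on_spike_cycles_lowers_v2_peak(self, circuit):
        proto = SinusoidProtocol(
            freq_hz=5.0,
            amplitude_pa=80.0,
            t_on_s=0.5,
            duration_s=4.0,
            total_s=5.0,
            # spikes at the crest of every other cycle
            forced_spike_times_s=tuple(0.55 + 0.4 * k for k in range(10)),
        )
        pair = generate_paired_recording(circuit, proto)
        with_ap, without_ap = conditional_peak_by_presyn_spike(
            pair, 5.0, 0.5, 4.5, np.array(proto.forced_spike_times_s)
        )
        assert with_ap < without_ap

    def test_passive_drive_without_spikes(self, circuit):
        proto = SinusoidProtocol(
            freq_hz=5.0, amplitude_pa=80.0, t_on_s=0.5, duration_s=2.0, total_s=3.0
        )
        pair = generate_paired_recording(circuit, proto)
        with pytest.warns(UserWarning, match="no spike-containing"):
            with_ap, without_ap = conditional_peak_by_presyn_spike(
                pair, 5.0, 0.5, 2.5, np.array([])
            )
        assert np.isnan(with_ap)
        assert without_ap > 0

    def test_zero_coupling_both_near_zero(self):
        circ = CircuitSpec(r_junction_mohm=np.inf)
        proto = SinusoidProtocol(
            freq_hz=5.0,
            amplitude_pa=80.0,
            t_on_s=0.5,
            duration_s=2.0,
            total_s=3.0,
            forced_spike_times_s=(0.55, 0.95),
        )
        pair = generate_paired_recording(circ, proto)
        with_ap, without_ap = conditional_peak_by_presyn_spike(
            pair, 5.0, 0.5, 2.5, np.array(proto.forced_spike_times_s)
        )
        assert abs(with_ap) < 0.01 and abs(without_ap) < 0.01


class TestVmCrossCorrelation:
    def test_identical_traces_peak_one_at_zero_lag(self, rng):
        v = RegularTimeSeries(rng.standard_normal(20_000), 10_000.0)
        _, _, lag, peak = vm_crosscorrelation(v, v, max_lag_s=0.1)
        assert lag == 0.0
        assert peak == pytest.approx(1.0)

    def test_delayed_copy_peaks_at_delay(self, rng):
        x = rng.standard_normal(20_000)
        d = 57  # samples
        v1 = RegularTimeSeries(x, 10_000.0)
        v2 = RegularTimeSeries(np.roll(x, d), 10_000.0)
        _, _, lag, _ = vm_crosscorrelation(v1, v2, max_lag_s=0.05)
        assert lag == pytest.approx(d / 10_000.0, abs=1e-4)

    def test_independent_noise_uncorrelated(self, rng):
        v1 = RegularTimeSeries(rng.standard_normal(50_000), 10_000.0)
        v2 = RegularTimeSeries(rng.standard_normal(50_000), 10_000.0)
        _, _, _, peak = vm_crosscorrelation(v1, v2, max_lag_s=0.05)
        assert abs(peak) < 0.05

    def test_zero_variance_rejected(self):
        v = RegularTimeSeries(np.zeros(1000), 10_000.0)
        with pytest.raises(ValueError):
            vm_crosscorrelation(v, v)


class TestSpikeSynchrony:
    def test_identical_trains_all_mass_at_zero(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 100, 200))
        centers, counts, sync = spike_crosscorrelogram(t, t, duration_s=100.0)
        assert counts[np.argmin(np.abs(centers))] >= 200
        assert sync > 10

    def test_shifted_train_peaks_at_shift(self):
        t = np.sort(np.random.default_rng(1).uniform(1, 99, 150))
        centers, counts, _ = spike_crosscorrelogram(t, t + 0.02, duration_s=100.0)
        assert centers[np.argmax(counts)] == pytest.approx(0.02, abs=0.0051)

    def test_independent_poisson_trains_at_chance(self, rng):
        T, r1, r2 = 500.0, 4.0, 5.0
        t1 = np.sort(rng.uniform(0, T, int(r1 * T)))
        t2 = np.sort(rng.uniform(0, T, int(r2 * T)))
        centers, counts, sync = spike_crosscorrelogram(t1, t2, duration_s=T)
        # central bin coincidences ~ r1*r2*bin*T
        expect = r1 * r2 * 0.005 * T
        assert counts[np.argmin(np.abs(centers))] == pytest.approx(expect, rel=0.5)
        assert sync == pytest.approx(1.0, abs=0.5)

    def test_total_mass_conservation(self, rng):
        t1 = np.sort(rng.uniform(0, 50, 80))
        t2 = np.sort(rng.uniform(0, 50, 60))
        centers, counts, _ = spike_crosscorrelogram(
            t1, t2, bin_ms=5.0, max_lag_ms=200.0, duration_s=50.0
        )
        lim = 0.2 + 0.0025  # max lag + half bin
        n_pairs = int(np.sum(np.abs(t2[None, :] - t1[:, None]) <= lim))
        assert counts.sum() == n_pairs

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            spike_crosscorrelogram(np.array([]), np.array([1.0]))


class TestBlockerEffect:
    def test_unchanged_cc_is_100_percent(self):
        assert blocker_effect(0.11, 0.11) == pytest.approx(100.0)

    def test_full_block_is_zero(self):
        assert blocker_effect(0.11, 0.0) == 0.0

    def test_ninefold_junction_increase_matches_circuit_closed_form(self):
        before = CircuitSpec()
        after = CircuitSpec(r_junction_mohm=9 * before.r_junction_mohm)
        cc_b = coupling_coefficient(generate_paired_recording(before, StepProtocol()))
        cc_a = coupling_coefficient(generate_paired_recording(after, StepProtocol()))
        want = 100.0 * after.cc_12_closed_form / before.cc_12_closed_form
        assert blocker_effect(cc_b, cc_a) == pytest.approx(want, rel=0.02)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            blocker_effect(0.0, 0.05)
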