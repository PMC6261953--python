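"""dF/F, transient detection, state peak statistics and Otsu classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetaoff import (
    compute_dff,
    compute_f0,
    detect_transients,
    otsu_classify,
    otsu_threshold,
    segment_states,
    state_peak_stats,
)
from thetaoff.calcium import classification_feature
from thetaoff.core import RegularTimeSeries
from thetaoff.synth.session import gcamp_kernel


def series(data, rate=30.0):
    return RegularTimeSeries(np.asarray(data, float), rate, units="au")


def brute_force_f0(data, rate, window_s=1.0, n_windows=3):
    """Greedy exhaustive search over all start indices (the oracle)."""
    w = int(round(window_s * rate))
    means = np.array([data[i : i + w].mean() for i in range(len(data) - w + 1)])
    taken, starts = np.zeros(means.size, bool), []
    for _ in range(n_windows):
        order = np.argsort(means, kind="stable")
        best = next(i for i in order if not taken[i])
        starts.append(best)
        taken[max(best - w + 1, 0) : best + w] = True
    return np.concatenate([data[s : s + w] for s in starts]).mean()


class TestF0:
    def test_constant_trace(self):
        f0, windows = compute_f0(series(np.full(150, 7.0)))
        assert f0 == 7.0
        assert len(windows) == 3

    def test_three_planted_low_plateaus(self):
        data = np.full(600, 10.0)
        for start in (60, 240, 420):
            data[start : start + 30] = 5.0
        f0, windows = compute_f0(series(data))
        assert f0 == pytest.approx(5.0)
        assert f0 == pytest.approx(brute_force_f0(data, 30.0))

    def test_monotone_ramp_takes_first_three_seconds(self):
        data = np.linspace(1, 10, 300)
        f0, windows = compute_f0(series(data))
        starts = sorted(w[0] for w in windows)
        assert starts == pytest.approx([0.0, 1.0, 2.0])
        assert f0 == pytest.approx(brute_force_f0(data, 30.0))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_f0(series(np.ones(60)))


class TestDff:
    @pytest.mark.parametrize("factor,expected", [(1.0, 0.0), (2.0, 100.0), (1.5, 50.0)])
    def test_pointwise_formula(self, factor, expected):
        data = np.full(150, 4.0)
        out = compute_dff(series(data * factor), f0=4.0)
        assert out.dff.data == pytest.approx(np.full(150, expected))

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(series(np.ones(150)), f0=0.0)

    def test_scale_invariance(self, rng):
        raw = 50.0 + 10.0 * np.abs(rng.standard_normal(300))
        a = compute_dff(series(raw))
        b = compute_dff(series(raw * 3.7))
        np.testing.assert_allclose(a.dff.data, b.dff.data, atol=1e-9)


class TestTransients:
    def test_flat_trace_has_no_peaks(self):
        dff = compute_dff(series(np.full(300, 10.0) + 0.01 * np.sin(np.arange(300))))
        assert detect_transients(dff).size == 0

    def test_planted_kernel_peak_recovered(self):
        kern = gcamp_kernel(50, 400, 30.0)
        data = np.full(600, 100.0)
        i0 = 300
        data[i0 : i0 + kern.size] += 40.0 * kern[: 600 - i0]
        dff = compute_dff(series(data))
        peaks = detect_transients(dff)
        assert peaks.size == 1
        t_peak_true = (i0 + np.argmax(kern)) / 30.0
        assert abs(peaks[0] - t_peak_true) <= 1.5 / 30.0

    def test_separation_rule_keeps_single_peak(self):
        # two kernels 200 ms apart < 315-ms separation -> one retained
        kern = gcamp_kernel(20, 100, 30.0)
        data = np.full(600, 100.0)
        for i0 in (300, 306):
            data[i0 : i0 + kern.size] += 40.0 * kern[: 600 - i0]
        dff = compute_dff(series(data))
        assert detect_transients(dff).size == 1


class TestStatePeakStats:
    def _simple_segmentation(self, n, rate):
        speed = np.zeros(n)
        speed[: n // 2] = 10.0  # locomotion first half
        return segment_states(RegularTimeSeries(speed, rate, units="cm/s"))

    def test_single_transient_assigned_to_containing_state(self):
        rate = 30.0
        data = np.zeros(600)
        data[450] = 40.0  # second half: immobility
        dff_series = RegularTimeSeries(data, rate, units="%dF/F")
        from thetaoff.calcium import DffTrace

        dff = DffTrace(dff=dff_series, f0=100.0, f0_windows=[], noise_sd_dff=1.0)
        seg = self._simple_segmentation(600, rate)
        prof = state_peak_stats(dff, seg, np.array([450 / rate]))
        assert set(prof.states) == {"immobility"}
        st_ = prof.states["immobility"]
        assert st_.n_periods == 1 and st_.n_transients == 1
        # window mean of a single-sample impulse over the 315-ms window
        w = int(round(0.315 * rate / 2)) * 2 + 1
        assert st_.mean_peak_dff == pytest.approx(40.0 / 9, rel=0.3)

    def test_window_at_trace_edge_is_truncated_and_flagged(self):
        rate = 30.0
        data = np.zeros(600)
        data[598] = 40.0
        from thetaoff.calcium import DffTrace

        dff = DffTrace(
            dff=RegularTimeSeries(data, rate, units="%dF/F"),
            f0=100.0,
            f0_windows=[],
            noise_sd_dff=1.0,
        )
        seg = self._simple_segmentation(600, rate)
        prof = state_peak_stats(dff, seg, np.array([598 / rate]))
        assert prof.truncated_windows == 1

    def test_theta_off_cell_immobility_exceeds_locomotion(self, small_session):
        seg = segment_states(small_session.speed)
        trace = small_session.ca_traces[0]  # a theta_off cell
        dff = compute_dff(trace)
        prof = state_peak_stats(dff, seg, detect_transients(dff), cell_id=trace.name)
        assert prof.mean_peak("immobility") > prof.mean_peak("locomotion")


def brute_force_otsu(x):
    """Exhaustive scan over all midpoints of the sorted sample (the oracle)."""
    x = np.sort(np.asarray(x, float))
    mu, var_t = x.mean(), x.var()
    best = (-1.0, None)
    for i in range(1, x.size):
        t = 0.5 * (x[i - 1] + x[i])
        lo, hi = x[:i], x[i:]
        w1 = lo.size / x.size
        sb = w1 * (lo.mean() - mu) ** 2 + (1 - w1) * (hi.mean() - mu) ** 2
        if sb > best[0]:
            best = (sb, t)
    return best[1], best[0] / var_t


class TestOtsu:
    def test_example_split_matches_brute_force(self):
        feats = np.array([0.3, 0.33, 3.1, 3.3])
        cls = otsu_classify(feats)
        assert cls.labels == ["type_II", "type_II", "type_I", "type_I"]
        _, eta_oracle = brute_force_otsu(feats)
        assert cls.eta == pytest.approx(eta_oracle, abs=1e-3)

    def test_two_points_give_eta_one(self):
        t, eta = otsu_threshold(np.array([0.0, 1.0]))
        assert 0.0 < t < 1.0
        assert eta == pytest.approx(1.0)

    def test_degenerate_identical_features_rejected(self):
        with pytest.raises(ValueError, match="separability"):
            otsu_threshold(np.full(5, 2.0))

    def test_variance_decomposition_at_threshold(self, rng):
        x = np.concatenate([rng.normal(1, 0.2, 10), rng.normal(5, 0.4, 15)])
        t, eta = otsu_threshold(x)
        lo, hi = x[x <= t], x[x > t]
        w1 = lo.size / x.size
        sb = w1 * (lo.mean() - x.mean()) ** 2 + (1 - w1) * (hi.mean() - x.mean()) ** 2
        sw = w1 * lo.var() + (1 - w1) * hi.var()
        assert sb + sw == pytest.approx(x.var(), rel=1e-12)
        assert eta == pytest.approx(sb / x.var(), rel=1e-12)

    def test_planted_labels_recovered_at_ratio_5(self, rng):
        hi = np.exp(np.log(2.5) + 0.1 * rng.standard_normal(8))
        lo = np.exp(np.log(0.5) + 0.1 * rng.standard_normal(20))
        cls = otsu_classify(np.concatenate([hi, lo]))
        assert cls.labels == ["type_I"] * 8 + ["type_II"] * 20

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_binned_scan_matches_midpoint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 100))
        x = np.round(rng.normal(0, 1, n), 3)
        if np.ptp(x) == 0:
            return
        t_bin, eta_bin = otsu_threshold(x)
        t_oracle, eta_oracle = brute_force_otsu(x)
        bin_width = np.ptp(x) / 256
        assert abs(eta_bin - eta_oracle) <= 1e-3
        # same partition of the sample, up to one bin width of threshold slack
        assert abs(t_bin - t_oracle) <= bin_width + 0.5 * np.max(
            np.diff(np.sort(x))
        ) + 1e-12


def test_otsu_agrees_with_reference_implementation(rng):
    """Independent cross-check against scikit-image's Otsu threshold."""
    from skimage.filters import threshold_otsu

    x = np.concatenate([rng.normal(0.4, 0.1, 30), rng.normal(3.0, 0.5, 20)])
    t_ours, _ = otsu_threshold(x)
    t_ref = threshold_otsu(x, nbins=256)
    assert abs(t_ours - t_ref) <= np.ptp(x) / 256 + 1e-12


def test_classification_feature_modes():
    entry = {"immobility": 100.0, "locomotion": 25.0}
    assert classification_feature(entry, "ratio") == pytest.approx(4.0)
    assert classification_feature(entry, "difference") == pytest.approx(75.0)
    with pytest.raises(ValueError):
        classification_feature({"immobility": 1.0, "locomotion": 0.0}, "ratio")
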