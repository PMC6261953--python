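"""Gap-junction (electrical coupling) analysis of paired recordings.

The coupling coefficient CC is the steady-state voltage ratio between the
receiving and the stimulated cell during a hyperpolarizing step (-140 pA,
1000 ms by convention); pairs with CC >= 0.01 count as electrically coupled.
The junction acts as a low-pass filter, so a presynaptic AP appears in the
coupled cell as a "spikelet": a strongly attenuated fast positive deflection
followed by a better-conducted slow negative component inherited from the
AHP. This module also quantifies subthreshold Vm synchrony and spike-time
synchrony (cross-correlograms) and the effect of gap-junction blockers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .core import RegularTimeSeries


@dataclass
class PairedRecording:
    """Simultaneous two-cell recording with the applied current protocols."""

    v1: RegularTimeSeries
    v2: RegularTimeSeries
    i1: RegularTimeSeries | None = None
    i2: RegularTimeSeries | None = None
    protocol: dict | None = None

    def __post_init__(self) -> None:
        if self.v1.rate_hz != self.v2.rate_hz or len(self.v1) != len(self.v2):
            raise ValueError("paired traces must share clock and length")


@dataclass
class CouplingStats:
    cc: float
    cc_slope: float = float("nan")
    cc_slope_se: float = float("nan")
    spikelet_pos_mv: float = float("nan")
    spikelet_neg_mv: float = float("nan")
    percent_of_control: float = float("nan")

    @property
    def is_coupled(self) -> bool:
        return self.cc >= 0.01


COUPLED_CC = 0.01


def _step_delta(
    v: RegularTimeSeries,
    t_on: float,
    t_off: float,
    steady_window_s: float = 0.2,
    baseline_window_s: float = 0.2,
) -> float:
    """Steady-state voltage deflection: mean(late step) - mean(pre-step)."""
    pre = v.slice_time(max(t_on - baseline_window_s, v.t0), t_on)
    late = v.slice_time(t_off - steady_window_s, t_off)
    if len(pre) == 0 or len(late) == 0:
        raise ValueError("step windows fall outside the trace")
    return float(late.data.mean() - pre.data.mean())


def coupling_coefficient(
    pair: PairedRecording,
    step_window_s: tuple[float, float] | None = None,
    steady_window_s: float = 0.2,
) -> float:
    """CC (direction 1 -> 2) from a current step applied to cell 1.

    CC = dV2 / dV1 with dV the steady-state deflection, taken over the last
    ``steady_window_s`` of the step against the pre-step baseline.
    """
    if step_window_s is None:
        proto = pair.protocol or {}
        if "t_on_s" not in proto or "t_off_s" not in proto:
            raise ValueError("no step protocol window available")
        step_window_s = (proto["t_on_s"], proto["t_off_s"])
    t_on, t_off = step_window_s
    dv1 = _step_delta(pair.v1, t_on, t_off, steady_window_s)
    dv2 = _step_delta(pair.v2, t_on, t_off, steady_window_s)
    if dv1 == 0:
        raise ValueError("no voltage deflection in the stimulated cell")
    return float(dv2 / dv1)


def cc_regression(dv1: np.ndarray, dv2: np.ndarray) -> tuple[float, float]:
    """CC as the slope (+/- SE) of dV2 on dV1 across step amplitudes."""
    dv1 = np.asarray(dv1, dtype=float)
    dv2 = np.asarray(dv2, dtype=float)
    if dv1.size < 3:
        raise ValueError("need at least 3 step amplitudes for the regression")
    if np.ptp(dv1) == 0:
        raise ValueError("degenerate regression: all dV1 identical")
    res = stats.linregress(dv1, dv2)
    return float(res.slope), float(res.stderr)


def spikelet_components(
    pair: PairedRecording,
    presyn_spike_times_s: np.ndarray,
    window_s: tuple[float, float] = (0.01, 0.1),
    pos_window_s: float = 0.01,
    neg_window_s: tuple[float, float] = (0.005, 0.1),
) -> tuple[float, float]:
    """Positive and negative spikelet components in the coupled cell.

    Spike-triggered average of v2 over ``[-window[0], +window[1]]`` around
    the presynaptic spike peaks; the positive component is the maximum in the
    first ``pos_window_s`` after the spike minus the pre-event baseline, the
    negative component the minimum over ``neg_window_s`` (both signed, mV).
    """
    times = np.atleast_1d(np.asarray(presyn_spike_times_s, dtype=float))
    if times.size == 0:
        raise ValueError("no presynaptic spikes supplied")
    if times.size < 3:
        warnings.warn("fewer than 3 presynaptic spikes; single-event values", stacklevel=2)
    v2 = pair.v2
    pre, post = window_s
    lags = np.arange(-pre, post, v2.dt)
    rows = [
        v2.interp(t + lags)
        for t in times
        if t - pre >= v2.t0 and t + post <= v2.t0 + v2.duration
    ]
    if not rows:
        raise ValueError("no spikes with a full window inside the trace")
    sta = np.mean(rows, axis=0)
    baseline = sta[lags < 0].mean()
    pos_sel = (lags >= 0) & (lags <= pos_window_s)
    neg_sel = (lags >= neg_window_s[0]) & (lags <= neg_window_s[1])
    pos = float(sta[pos_sel].max() - baseline)
    neg = float(sta[neg_sel].min() - baseline)
    return pos, neg


def conditional_peak_by_presyn_spike(
    pair: PairedRecording,
    sinusoid_freq_hz: float,
    t_start_s: float,
    t_end_s: float,
    presyn_spike_times_s: np.ndarray,
) -> tuple[float, float]:
    """Per-cycle v2 peak depolarization, split by presence of a cell-1 spike.

    The drive interval ``[t_start, t_end]`` is cut into sinusoid cycles; each
    cycle's peak v2 depolarization (relative to the pre-drive baseline) is
    averaged separately over cycles with and without a presynaptic spike.
    Returns ``(peak_with_ap, peak_without_ap)``; an empty class yields NaN.
    """
    v2 = pair.v2
    period = 1.0 / sinusoid_freq_hz
    baseline = float(v2.slice_time(max(v2.t0, t_start_s - 0.2), t_start_s).data.mean())
    spike_times = np.atleast_1d(np.asarray(presyn_spike_times_s, dtype=float))
    with_ap, without_ap = [], []
    t = t_start_s
    while t + period <= t_end_s + 1e-9:
        seg = v2.slice_time(t, t + period)
        if len(seg) == 0:
            break
        peak = float(seg.data.max() - baseline)
        has_spike = bool(np.any((spike_times >= t) & (spike_times < t + period)))
        (with_ap if has_spike else without_ap).append(peak)
        t += period
    if not with_ap:
        warnings.warn("no spike-containing cycles", stacklevel=2)
    if not without_ap:
        warnings.warn("no spike-free cycles", stacklevel=2)
    mean = lambda v: float(np.mean(v)) if v else float("nan")  # noqa: E731
    return mean(with_ap), mean(without_ap)


def vm_crosscorrelation(
    v1: RegularTimeSeries, v2: RegularTimeSeries, max_lag_s: float = 0.5
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalized cross-correlation of two mean-removed voltage traces.

    Returns ``(lags_s, correlation, peak_lag_s, peak_value)``. A positive
    peak lag means v2 follows v1.
    """
    if v1.rate_hz != v2.rate_hz or len(v1) != len(v2):
        raise ValueError("traces must share rate and length")
    a = v1.data - v1.data.mean()
    b = v2.data - v2.data.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("zero-variance input")
    cc = signal.correlate(b, a, mode="full") / denom
    lags = signal.correlation_lags(b.size, a.size, mode="full") / v1.rate_hz
    sel = np.abs(lags) <= max_lag_s
    lags, cc = lags[sel], cc[sel]
    k = int(np.argmax(np.abs(cc)))
    return lags, cc, float(lags[k]), float(cc[k])


def detect_spike_starts(
    vm: RegularTimeSeries,
    highpass_hz: float = 125.0,
    k_sd: float = 6.0,
    min_separation_ms: float = 2.0,
) -> np.ndarray:
    """Spike start times detected on the high-pass filtered voltage trace."""
    sos = signal.butter(4, highpass_hz, btype="high", fs=vm.rate_hz, output="sos")
    hp = signal.sosfiltfilt(sos, vm.data)
    sd = 1.4826 * np.median(np.abs(hp - np.median(hp)))
    if sd == 0:
        return np.empty(0)
    distance = max(int(round(min_separation_ms / 1000.0 * vm.rate_hz)), 1)
    peaks, _ = signal.find_peaks(hp, height=k_sd * sd, distance=distance)
    return vm.t0 + peaks / vm.rate_hz


def spike_crosscorrelogram(
    times1_s: np.ndarray,
    times2_s: np.ndarray,
    bin_ms: float = 5.0,
    max_lag_ms: float = 200.0,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cross-correlogram of two spike trains and a chance-normalized
    synchrony index.

    Counts spike-time differences ``t2 - t1`` within ``+/- max_lag_ms`` in
    ``bin_ms`` bins. The synchrony index is the central-bin coincidence count
    divided by the chance level ``n1 * n2 * bin / T`` for independent trains.
    """
    t1 = np.sort(np.atleast_1d(np.asarray(times1_s, dtype=float)))
    t2 = np.sort(np.atleast_1d(np.asarray(times2_s, dtype=float)))
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both spike trains must be non-empty")
    max_lag = max_lag_ms / 1000.0
    bin_s = bin_ms / 1000.0
    n_bins = 2 * int(round(max_lag / bin_s)) + 1  # odd: central bin at lag 0
    edges = (np.arange(n_bins + 1) - n_bins / 2.0) * bin_s
    diffs = (t2[None, :] - t1[:, None]).ravel()
    diffs = diffs[np.abs(diffs) <= max_lag + bin_s / 2]
    counts, _ = np.histogram(diffs, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if duration_s is None:
        duration_s = max(t1[-1], t2[-1]) - min(t1[0], t2[0])
    chance = t1.size * t2.size * bin_s / max(duration_s, bin_s)
    sync = float(counts[n_bins // 2] / chance) if chance > 0 else float("nan")
    return centers, counts, sync


def spike_synchrony(
    pair: PairedRecording,
    highpass_hz: float = 125.0,
    bin_ms: float = 5.0,
    max_lag_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Spike cross-correlogram of a pair, spikes taken from the high-pass
    filtered voltage traces."""
    t1 = detect_spike_starts(pair.v1, highpass_hz=highpass_hz)
    t2 = detect_spike_starts(pair.v2, highpass_hz=highpass_hz)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both cells must spike for synchrony analysis")
    return spike_crosscorrelogram(
        t1, t2, bin_ms=bin_ms, max_lag_ms=max_lag_ms, duration_s=pair.v1.duration
    )


def blocker_effect(cc_before: float, cc_after: float) -> float:
    """Residual coupling after a gap-junction blocker, in percent of control."""
    if cc_before <= 0:
        raise ValueError("cc_before must be positive")
    return 100.0 * cc_after / cc_before
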