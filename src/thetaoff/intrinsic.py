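"""Intrinsic membrane properties from current-step families.

Action potential (AP) features are measured on the first AP elicited within
50 ms of pulse onset by a +40 to +60 pA step: amplitude from threshold to
peak, latency from pulse onset to the threshold crossing, half-width at half
amplitude, and fast AHP depth from threshold to the post-spike trough. The
h-current signature is the membrane-potential sag on the hyperpolarizing
sweep whose steady state sits near -100 mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RegularTimeSeries


@dataclass
class SweepFamily:
    """Voltage responses to a family of current steps.

    ``sweeps`` maps injected current (pA) to the voltage trace (mV);
    ``pulse_window`` is the (t_on, t_off) of the step in seconds, common to
    all sweeps.
    """

    sweeps: dict[float, RegularTimeSeries]
    pulse_window: tuple[float, float]

    def __post_init__(self) -> None:
        rates = {ts.rate_hz for ts in self.sweeps.values()}
        if len(rates) > 1:
            raise ValueError("all sweeps must share a sampling rate")
        t_on, t_off = self.pulse_window
        for i_pa, ts in self.sweeps.items():
            if not (ts.t0 <= t_on < t_off <= ts.t0 + ts.duration):
                raise ValueError(f"pulse window outside sweep at {i_pa} pA")


@dataclass
class NoQualifyingAP:
    """Returned when no sweep in the +40..+60 pA range spikes within 50 ms."""

    reason: str


@dataclass
class IntrinsicProperties:
    ap_amplitude_mv: float
    ap_latency_ms: float
    ap_halfwidth_ms: float
    fahp_amplitude_mv: float
    v_rest_mv: float
    sweep_current_pa: float


def detect_spikes(
    vm: RegularTimeSeries, dvdt_threshold: float = 20.0, min_separation_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Spike peak times and per-spike threshold times on a voltage trace.

    A spike's threshold point is the first sample in the rising phase before
    the peak where dV/dt exceeds ``dvdt_threshold`` (mV/ms); peaks must be
    separated by at least ``min_separation_ms``.
    """
    if vm.rate_hz < 10_000:
        raise ValueError("spike detection requires >= 10 kHz sampling")
    v = vm.data
    dvdt = np.gradient(v) * vm.rate_hz / 1000.0  # mV/ms
    fast = dvdt > dvdt_threshold
    if not fast.any():
        return np.empty(0), np.empty(0)

    min_sep = max(int(round(min_separation_ms / 1000.0 * vm.rate_hz)), 1)
    peak_idx, thr_idx = [], []
    i = 0
    n = v.size
    while i < n:
        if not fast[i]:
            i += 1
            continue
        # rising phase starts here; peak = local max after upstroke ends
        j = i
        while j + 1 < n and v[j + 1] >= v[j]:
            j += 1
        if not peak_idx or j - peak_idx[-1] >= min_sep:
            peak_idx.append(j)
            thr_idx.append(i)
        i = j + 1
    times = vm.t0 + np.asarray(peak_idx) / vm.rate_hz
    thr_times = vm.t0 + np.asarray(thr_idx) / vm.rate_hz
    return times, thr_times


def _halfwidth_ms(v: np.ndarray, rate_hz: float, thr_i: int, peak_i: int) -> float:
    """Width at half amplitude with linear interpolation at the crossings."""
    half = v[thr_i] + 0.5 * (v[peak_i] - v[thr_i])
    i = peak_i
    while i > thr_i and v[i - 1] > half:
        i -= 1
    if i == thr_i:
        t_rise = float(i)
    else:
        t_rise = i - 1 + (half - v[i - 1]) / (v[i] - v[i - 1])
    j = peak_i
    while j + 1 < v.size and v[j + 1] > half:
        j += 1
    if j + 1 >= v.size:
        t_fall = float(j)
    else:
        t_fall = j + (v[j] - half) / (v[j] - v[j + 1])
    return (t_fall - t_rise) / rate_hz * 1000.0


def first_ap_features(
    family: SweepFamily,
    current_range_pa: tuple[float, float] = (40.0, 60.0),
    latency_window_ms: float = 50.0,
    dvdt_threshold: float = 20.0,
    fahp_window_ms: float = 10.0,
) -> IntrinsicProperties | NoQualifyingAP:
    """AP features of the first spike within 50 ms of a +40..+60 pA pulse.

    When several sweeps qualify, the lowest current is used. Returns
    :class:`NoQualifyingAP` (never silent zeros) if no sweep qualifies.
    """
    t_on, _ = family.pulse_window
    for i_pa in sorted(family.sweeps):
        if not (current_range_pa[0] <= i_pa <= current_range_pa[1]):
            continue
        vm = family.sweeps[i_pa]
        peaks, thrs = detect_spikes(vm, dvdt_threshold=dvdt_threshold)
        in_window = (thrs >= t_on) & (thrs <= t_on + latency_window_ms / 1000.0)
        if not in_window.any():
            continue
        k = int(np.argmax(in_window))
        peak_i = vm.index_at(peaks[k])
        thr_i = vm.index_at(thrs[k])
        v = vm.data
        v_thr, v_peak = v[thr_i], v[peak_i]
        fahp_i1 = min(peak_i + int(fahp_window_ms / 1000.0 * vm.rate_hz), v.size)
        trough = float(v[peak_i:fahp_i1].min())
        baseline_i = vm.index_at(t_on)
        return IntrinsicProperties(
            ap_amplitude_mv=float(v_peak - v_thr),
            ap_latency_ms=float((thrs[k] - t_on) * 1000.0),
            ap_halfwidth_ms=_halfwidth_ms(v, vm.rate_hz, thr_i, peak_i),
            fahp_amplitude_mv=float(v_thr - trough),
            v_rest_mv=float(v[: max(baseline_i, 1)].mean()),
            sweep_current_pa=float(i_pa),
        )
    return NoQualifyingAP(
        reason=f"no AP within {latency_window_ms} ms of pulse onset in "
        f"{current_range_pa[0]}..{current_range_pa[1]} pA sweeps"
    )


def sag_amplitude(
    family: SweepFamily,
    target_mv: float = -100.0,
    tolerance_mv: float = 3.0,
    steady_window_ms: float = 100.0,
) -> float:
    """Sag on the hyperpolarizing sweep whose steady state is near ``target_mv``.

    Sag = V_steady - V_peak (a positive number): the depolarizing relaxation
    from the early hyperpolarization peak back to the plateau. The steady
    state is the mean over the final ``steady_window_ms`` of the pulse. When
    no sweep lands within ``tolerance_mv`` of the target, the sag is linearly
    interpolated between the two bracketing sweeps.
    """
    t_on, t_off = family.pulse_window

    def measure(vm: RegularTimeSeries) -> tuple[float, float]:
        i_on, i_off = vm.index_at(t_on), vm.index_at(t_off)
        i_sw = vm.index_at(t_off - steady_window_ms / 1000.0)
        steady = float(vm.data[i_sw:i_off].mean())
        peak = float(vm.data[i_on:i_off].min())
        return steady, steady - peak

    hyper = {
        i_pa: measure(vm)
        for i_pa, vm in family.sweeps.items()
        if i_pa < 0
    }
    if not hyper:
        raise ValueError("no hyperpolarizing sweeps in the family")
    # nearest steady state to the target
    items = sorted(hyper.items(), key=lambda kv: abs(kv[1][0] - target_mv))
    (i_best, (v_best, sag_best)) = items[0]
    if abs(v_best - target_mv) <= tolerance_mv:
        return float(max(sag_best, 0.0))
    # interpolate between the sweeps bracketing the target steady state
    pts = sorted((v, s) for v, s in hyper.values())
    vs = np.array([p[0] for p in pts])
    ss = np.array([p[1] for p in pts])
    if not (vs.min() <= target_mv <= vs.max()):
        raise ValueError(
            f"no sweep near {target_mv} mV (closest steady state {v_best:.1f} mV) "
            "and interpolation impossible"
        )
    return float(max(np.interp(target_mv, vs, ss), 0.0))
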