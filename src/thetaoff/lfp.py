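"""LFP band analysis: theta and ripple events, and event-triggered Ca2+ averages.

Theta (5-10 Hz) accompanies locomotion; ripples (125-250 Hz) occur during
quiet immobility. Both are extracted from the LFP with zero-phase Butterworth
band-pass filters. Ripples are detected on the rectified, smoothed envelope of
the band-passed signal against the immobility background; theta-run epochs are
anchored to locomotion onsets. Somatic dF/F traces are segmented around event
onsets and averaged to quantify event-locked modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .behavior import IMMOBILITY, LOCOMOTION, BehaviorSegmentation
from .core import RegularTimeSeries


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("band edges must satisfy 0 < low < high")


THETA_BAND = BandSpec("theta", 5.0, 10.0)
RIPPLE_BAND = BandSpec("ripple", 125.0, 250.0)


@dataclass
class RippleEvent:
    t_start_s: float
    t_end_s: float
    t_peak_s: float
    duration_ms: float
    peak_freq_hz: float
    peak_amplitude_sd: float


@dataclass
class ThetaRunEpoch:
    t_onset_s: float
    t_end_s: float
    theta_power: float
    theta_peak_hz: float
    power_above_immobility: bool = True


@dataclass
class EventTriggeredAverage:
    """Event x time matrix of dF/F segments aligned on event onset."""

    window_s: tuple[float, float]
    lags_s: np.ndarray
    aligned_traces: np.ndarray
    n_events: int
    before_means: np.ndarray | None = None
    after_means: np.ndarray | None = None

    @property
    def mean_trace(self) -> np.ndarray:
        return self.aligned_traces.mean(axis=0)


# ---------------------------------------------------------------------------


def bandpass(ts: RegularTimeSeries, band: BandSpec, order: int = 4) -> RegularTimeSeries:
    """Zero-phase (forward-backward) Butterworth band-pass; length preserved."""
    nyq = ts.rate_hz / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band edge {band.high_hz} Hz at or above Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="band", fs=ts.rate_hz, output="sos")
    return ts.copy_with(signal.sosfiltfilt(sos, ts.data), name=f"{ts.name}:{band.name}")


def spectral_peak(
    ts: RegularTimeSeries,
    band: BandSpec,
    nperseg_s: float | None = None,
    min_cycles: float = 10.0,
) -> tuple[float, bool]:
    """Welch spectral peak frequency within a band.

    Returns ``(peak_hz, confident)``; ``confident`` is False when the peak
    prominence is below 3x the in-band median power (no clear oscillation).
    Raises when the segment is shorter than ``min_cycles`` cycles of the band
    low edge.
    """
    if ts.duration < min_cycles / band.low_hz:
        raise ValueError(
            f"segment of {ts.duration:.2f}s too short for a {band.low_hz}-Hz band peak"
        )
    if nperseg_s is None:
        nperseg_s = min(ts.duration, max(4.0 / band.low_hz, 0.5))
    nperseg = min(int(nperseg_s * ts.rate_hz), len(ts))
    f, p = signal.welch(ts.data, fs=ts.rate_hz, nperseg=nperseg)
    sel = (f >= band.low_hz) & (f <= band.high_hz)
    if not sel.any():
        raise ValueError("no spectral bins inside the band; segment too short")
    fb, pb = f[sel], p[sel]
    k = int(np.argmax(pb))
    confident = bool(pb[k] >= 3.0 * np.median(pb))
    return float(fb[k]), confident


def _event_peak_freq(seg: np.ndarray, rate_hz: float, band: BandSpec) -> float:
    """Spectral peak of a short event segment (zero-padded periodogram)."""
    nfft = max(4096, 4 * seg.size)
    f, p = signal.periodogram(seg, fs=rate_hz, nfft=nfft)
    sel = (f >= band.low_hz) & (f <= band.high_hz)
    return float(f[sel][np.argmax(p[sel])])


def envelope(ts: RegularTimeSeries, smooth_ms: float = 10.0) -> np.ndarray:
    """Rectified band-passed signal smoothed with a moving average."""
    k = max(int(round(smooth_ms / 1000.0 * ts.rate_hz)), 1)
    return np.convolve(np.abs(ts.data), np.ones(k) / k, mode="same")


def detect_ripples(
    lfp: RegularTimeSeries,
    band: BandSpec = RIPPLE_BAND,
    threshold_sd: float = 5.0,
    min_duration_ms: float = 50.0,
    min_gap_ms: float = 50.0,
    boundary_sd: float = 1.0,
    segmentation: BehaviorSegmentation | None = None,
    smooth_ms: float = 10.0,
) -> list[RippleEvent]:
    """Detect ripple events on the band-passed LFP envelope.

    The envelope (rectified band-passed signal, ``smooth_ms`` moving average)
    is compared to the background statistics computed over immobility samples
    (or the whole trace when no segmentation is given). An event must reach
    ``threshold_sd`` SDs above the background mean at its peak; its extent is
    taken where the envelope stays above ``boundary_sd`` SDs. Events closer
    than ``min_gap_ms`` are merged, events shorter than ``min_duration_ms``
    or whose spectral peak falls outside the band are discarded. The
    background is re-estimated once with the initial detections excluded.
    """
    if lfp.rate_hz < 1000:
        raise ValueError("ripple detection requires LFP sampled at >= 1 kHz")
    bp = bandpass(lfp, band)
    env = envelope(bp, smooth_ms=smooth_ms)
    fs = lfp.rate_hz

    if segmentation is not None:
        bg_mask = np.zeros(env.size, dtype=bool)
        for e in segmentation.by_state(IMMOBILITY):
            bg_mask[lfp.index_at(e.t_start_s) : lfp.index_at(e.t_end_s)] = True
        if not bg_mask.any():
            bg_mask = np.ones(env.size, dtype=bool)
    else:
        bg_mask = np.ones(env.size, dtype=bool)

    def _detect(mask: np.ndarray) -> tuple[list[tuple[int, int, int]], float, float]:
        mu, sd = float(env[mask].mean()), float(env[mask].std())
        if sd == 0:
            sd = np.finfo(float).eps
        high = env >= mu + threshold_sd * sd
        low = env >= mu + boundary_sd * sd
        events = []
        for i0, i1 in _bool_runs(low):
            seg = env[i0:i1]
            if not high[i0:i1].any():
                continue
            events.append((i0, i1, i0 + int(np.argmax(seg))))
        # merge events separated by less than min_gap
        gap = int(round(min_gap_ms / 1000.0 * fs))
        merged: list[tuple[int, int, int]] = []
        for ev in events:
            if merged and ev[0] - merged[-1][1] < gap:
                p0, p1, pk = merged[-1]
                pk = pk if env[pk] >= env[ev[2]] else ev[2]
                merged[-1] = (p0, ev[1], pk)
            else:
                merged.append(ev)
        return merged, mu, sd

    events, mu, sd = _detect(bg_mask)
    # one background re-estimation with detections excluded
    mask2 = bg_mask.copy()
    for i0, i1, _ in events:
        mask2[i0:i1] = False
    if mask2.any():
        events, mu, sd = _detect(mask2)

    out: list[RippleEvent] = []
    min_dur = min_duration_ms / 1000.0
    for i0, i1, pk in events:
        dur = (i1 - i0) / fs
        if dur < min_dur:
            continue
        peak_freq = _event_peak_freq(bp.data[i0:i1], fs, band)
        if not (band.low_hz <= peak_freq <= band.high_hz):
            continue
        out.append(
            RippleEvent(
                t_start_s=lfp.t0 + i0 / fs,
                t_end_s=lfp.t0 + i1 / fs,
                t_peak_s=lfp.t0 + pk / fs,
                duration_ms=dur * 1000.0,
                peak_freq_hz=peak_freq,
                peak_amplitude_sd=float((env[pk] - mu) / sd),
            )
        )
    return out


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def detect_theta_run_epochs(
    lfp: RegularTimeSeries,
    segmentation: BehaviorSegmentation,
    band: BandSpec = THETA_BAND,
) -> list[ThetaRunEpoch]:
    """One theta-run epoch per locomotion epoch, onset at locomotion onset.

    Theta power is the variance of the band-passed LFP over the epoch; epochs
    whose power does not exceed the median power over immobility epochs are
    flagged (``power_above_immobility = False``). The spectral peak is NaN
    for epochs too short for a reliable in-band estimate.
    """
    bp = bandpass(lfp, band)

    def epoch_power(t0: float, t1: float) -> float:
        seg = bp.slice_time(t0, t1)
        return float(np.var(seg.data)) if len(seg) else 0.0

    immob_powers = [
        epoch_power(e.t_start_s, e.t_end_s) for e in segmentation.by_state(IMMOBILITY)
    ]
    ref = float(np.median(immob_powers)) if immob_powers else 0.0

    epochs = []
    for e in segmentation.by_state(LOCOMOTION):
        power = epoch_power(e.t_start_s, e.t_end_s)
        seg = lfp.slice_time(e.t_start_s, e.t_end_s)
        try:
            peak_hz, _ = spectral_peak(seg, band)
        except ValueError:
            peak_hz = float("nan")
        epochs.append(
            ThetaRunEpoch(
                t_onset_s=e.t_start_s,
                t_end_s=e.t_end_s,
                theta_power=power,
                theta_peak_hz=peak_hz,
                power_above_immobility=power > ref,
            )
        )
    return epochs


def theta_peak_over_epochs(
    lfp: RegularTimeSeries,
    segmentation: BehaviorSegmentation,
    band: BandSpec = THETA_BAND,
    nperseg_s: float = 10.0,
) -> float:
    """Welch spectral peak over the concatenated locomotion epochs.

    Pooling the locomotion segments gives a much finer frequency resolution
    than any single epoch allows; segment-boundary discontinuities only add
    broadband leakage and do not move the narrowband peak.
    """
    segs = [
        lfp.slice_time(e.t_start_s, e.t_end_s).data
        for e in segmentation.by_state(LOCOMOTION)
    ]
    if not segs:
        raise ValueError("no locomotion epochs to pool")
    pooled = RegularTimeSeries(np.concatenate(segs), lfp.rate_hz, units=lfp.units)
    peak, _ = spectral_peak(pooled, band, nperseg_s=min(nperseg_s, pooled.duration))
    return peak


def event_triggered_segments(
    dff: RegularTimeSeries,
    event_times_s: np.ndarray,
    window_s: tuple[float, float] = (2.0, 5.0),
    modulation_window_s: float = 0.5,
    event_end_times_s: np.ndarray | None = None,
) -> EventTriggeredAverage:
    """Segment a dF/F trace around event onsets and average.

    Rows are aligned on event time on a lag grid at the imaging rate; the
    trace is linearly interpolated at each requested time so that imaging and
    LFP clocks need not share sample edges. Events whose window extends past
    the trace are dropped with a warning. ``before_means`` / ``after_means``
    are mean dF/F over ``modulation_window_s`` immediately before the onset
    and after the event end (onset when no end times are given), for
    before-vs-after modulation tests.
    """
    event_times_s = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    pre, post = window_s
    lags = np.arange(-pre, post + dff.dt / 2, dff.dt)
    t_lo, t_hi = dff.t0, dff.t0 + dff.duration - dff.dt
    ends = (
        np.atleast_1d(np.asarray(event_end_times_s, dtype=float))
        if event_end_times_s is not None
        else event_times_s
    )

    keep, rows, before, after = [], [], [], []
    for t_ev, t_end in zip(event_times_s, ends):
        if t_ev - pre < t_lo or max(t_ev + post, t_end + modulation_window_s) > t_hi:
            continue
        keep.append(t_ev)
        rows.append(dff.interp(t_ev + lags))
        tb = np.arange(t_ev - modulation_window_s, t_ev, dff.dt)
        ta = np.arange(t_end, t_end + modulation_window_s, dff.dt)
        before.append(float(dff.interp(tb).mean()))
        after.append(float(dff.interp(ta).mean()))
    n_dropped = event_times_s.size - len(keep)
    if n_dropped:
        warnings.warn(f"{n_dropped} event(s) dropped: window outside trace", stacklevel=2)
    if not rows:
        raise ValueError("no events with a full window inside the trace")
    return EventTriggeredAverage(
        window_s=window_s,
        lags_s=lags,
        aligned_traces=np.vstack(rows),
        n_events=len(rows),
        before_means=np.array(before),
        after_means=np.array(after),
    )


def state_modulation_test(
    peaks_state_a: np.ndarray, peaks_state_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank test between per-period peak signals."""
    a = np.asarray(peaks_state_a, dtype=float)
    b = np.asarray(peaks_state_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("degenerate all-tied samples; p = 1", stacklevel=2)
        return 0.0, 1.0
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
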