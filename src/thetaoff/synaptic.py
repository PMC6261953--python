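"""Unitary/evoked IPSC analysis from paired voltage-clamp recordings.

Sweeps hold the postsynaptic current (pA, holding 0 mV, inhibitory events
appear as positive outward deflections) evoked by presynaptic APs. Release is
probabilistic: each AP either produces an IPSC or a failure. Failures are
called per sweep from the response-window mean against the baseline noise,
with a latency-consistency check — small unitary events near the noise floor
are distinguished from noise by their constant latency. Potency is the peak
of the success-average trace; kinetics (20-80% rise, monoexponential decay
tau) are measured on the same average. During trains the amplitude of each
pulse is extrapolated from the fitted decay of the preceding response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from statsmodels.stats.proportion import proportion_confint


@dataclass
class SweepSet:
    """Postsynaptic current sweeps with a common presynaptic AP schedule.

    ``sweeps`` is (n_sweeps, n_samples) in pA; ``ap_peak_times_ms`` are the
    presynaptic AP peak times from sweep start, identical across sweeps;
    ``baseline_window_ms`` is a pre-stimulus interval free of evoked events.
    """

    sweeps: np.ndarray
    rate_hz: float
    ap_peak_times_ms: np.ndarray
    baseline_window_ms: tuple[float, float] = (0.0, 90.0)

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.ap_peak_times_ms = np.atleast_1d(
            np.asarray(self.ap_peak_times_ms, dtype=float)
        )
        b0, b1 = self.baseline_window_ms
        if b1 <= b0:
            raise ValueError("baseline window must have positive length")
        if b1 > self.ap_peak_times_ms.min():
            raise ValueError("baseline window must precede the first presynaptic AP")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def idx(self, t_ms: float) -> int:
        return int(round(t_ms / 1000.0 * self.rate_hz))


@dataclass
class FailureCallResult:
    success: np.ndarray           # (n_sweeps, n_aps) bool
    excluded: np.ndarray          # (n_sweeps,) bool, spontaneous activity
    onset_latency_ms: np.ndarray  # (n_sweeps, n_aps), NaN where not estimable
    median_latency_ms: float
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray


@dataclass
class UIPSCStats:
    n_total: int
    n_failures: int
    failure_rate: float
    potency_pa: float
    latency_ms: float
    rise_20_80_ms: float
    tau_decay_ms: float
    ppr: float


@dataclass
class TrainStats:
    frequency_hz: float
    amplitudes_pa: np.ndarray
    corrections_pa: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def normalized(self) -> np.ndarray:
        return self.amplitudes_pa / self.amplitudes_pa[0]


# ---------------------------------------------------------------------------


def _robust_sd(x: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def call_failures(
    sweep_set: SweepSet,
    expected_latency_ms: float = 2.0,
    window_ms: float = 15.0,
    k_sd: float = 2.0,
    latency_tolerance_ms: float = 1.0,
    spontaneous_k_sd: float = 4.0,
) -> FailureCallResult:
    """Per-sweep, per-AP success/failure calls.

    A sweep is a success for a given AP when (a) the mean current over
    ``[AP + latency, AP + latency + window]`` exceeds the baseline mean by
    ``k_sd`` baseline SDs, and (b) its onset latency lies within
    ``latency_tolerance_ms`` of the connection's median latency (estimated
    from the amplitude-passing sweeps). Sweeps with baseline excursions
    beyond ``spontaneous_k_sd`` SDs are flagged spontaneous and excluded.
    """
    s = sweep_set
    b0, b1 = s.idx(s.baseline_window_ms[0]), s.idx(s.baseline_window_ms[1])
    if b1 - b0 < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    base = s.sweeps[:, b0:b1]
    b_mu = base.mean(axis=1)
    b_sd = np.array([_robust_sd(row) for row in base])
    b_sd = np.where(b_sd > 0, b_sd, base.std(axis=1))

    # spontaneous events are multi-sample; judge excursions on a 1-ms-smoothed
    # baseline so single-sample noise spikes do not disqualify sweeps
    k_sm = max(int(round(1e-3 * s.rate_hz)), 1)
    kern_sm = np.ones(k_sm) / k_sm
    base_sm = np.apply_along_axis(
        lambda r: np.convolve(r, kern_sm, mode="same"), 1, base
    )
    excluded = np.array(
        [
            bool(np.any(np.abs(row - mu) > spontaneous_k_sd * sd)) if sd > 0 else False
            for row, mu, sd in zip(base_sm, b_mu, b_sd)
        ]
    )

    n_aps = s.ap_peak_times_ms.size
    amp_pass = np.zeros((s.n_sweeps, n_aps), dtype=bool)
    onset = np.full((s.n_sweeps, n_aps), np.nan)
    for j, t_ap in enumerate(s.ap_peak_times_ms):
        r0 = s.idx(t_ap + expected_latency_ms)
        r1 = s.idx(t_ap + expected_latency_ms + window_ms)
        resp = s.sweeps[:, r0:r1].mean(axis=1) - b_mu
        thresh = np.where(b_sd > 0, k_sd * b_sd, 0.0)
        amp_pass[:, j] = resp > thresh
        # onset: first crossing of a 3-SD level on the 1-ms-smoothed sweep
        # (smoothing suppresses false early crossings)
        o0, o1 = s.idx(t_ap), s.idx(t_ap + expected_latency_ms + window_ms)
        for i in range(s.n_sweeps):
            if not amp_pass[i, j]:
                continue
            sm = np.convolve(s.sweeps[i, o0:o1], kern_sm, mode="same")
            level = b_mu[i] + 3.0 * b_sd[i] / np.sqrt(k_sm)
            above = np.flatnonzero(sm > level)
            if above.size:
                onset[i, j] = (o0 + above[0]) / s.rate_hz * 1000.0 - t_ap

    provisional = amp_pass & ~excluded[:, None]
    lat = onset[provisional]
    lat = lat[np.isfinite(lat)]
    if lat.size:
        med_lat = float(np.median(lat))
        consistent = np.abs(onset - med_lat) <= latency_tolerance_ms
        success = amp_pass & np.where(np.isfinite(onset), consistent, False)
    else:
        med_lat = float("nan")
        success = np.zeros_like(amp_pass)
    success &= ~excluded[:, None]
    return FailureCallResult(
        success=success,
        excluded=excluded,
        onset_latency_ms=onset,
        median_latency_ms=med_lat,
        baseline_mean=b_mu,
        baseline_sd=b_sd,
    )


def _fit_decay(
    t_ms: np.ndarray, y: np.ndarray, tau0_ms: float = 10.0
) -> tuple[float, float]:
    """Least-squares monoexponential ``A exp(-t/tau)``; returns (A, tau_ms)."""
    a0 = max(float(y[0]), 1e-9)
    popt, _ = curve_fit(
        lambda t, a, tau: a * np.exp(-t / tau),
        t_ms - t_ms[0],
        y,
        p0=(a0, tau0_ms),
        maxfev=5000,
    )
    return float(popt[0]), float(popt[1])


def uipsc_stats(
    sweep_set: SweepSet,
    calls: FailureCallResult,
    response_window_ms: float = 25.0,
    smooth_ms: float = 0.5,
) -> UIPSCStats:
    """Summary statistics of a unitary connection from called sweeps.

    Failure rate uses the first AP of each (non-excluded) sweep. Potency,
    latency and kinetics are measured on the success-average trace: onset at
    the 10%-of-peak crossing, rise between the 20% and 80% crossings, decay
    tau from a monoexponential fit over the peak-to-30% segment. PPR is
    computed on the all-sweep average (failures included), with the second
    response measured against the extrapolated decay of the first.
    """
    s = sweep_set
    keep = ~calls.excluded
    n_total = int(keep.sum())
    if n_total == 0:
        raise ValueError("all sweeps excluded as spontaneous")
    succ0 = calls.success[:, 0] & keep
    n_failures = n_total - int(succ0.sum())
    failure_rate = n_failures / n_total

    t_ap = s.ap_peak_times_ms[0]
    r0, r1 = s.idx(t_ap), s.idx(t_ap + response_window_ms)
    k = max(int(round(smooth_ms / 1000.0 * s.rate_hz)), 1)
    kern = np.ones(k) / k

    potency = latency = rise = tau = float("nan")
    if succ0.any():
        avg = s.sweeps[succ0].mean(axis=0)
        avg = avg - avg[s.idx(s.baseline_window_ms[0]) : s.idx(s.baseline_window_ms[1])].mean()
        avg_s = np.convolve(avg, kern, mode="same")
        seg = avg_s[r0:r1]
        pk = int(np.argmax(seg))
        potency = float(seg[pk])
        t_ms = (np.arange(r0, r1) / s.rate_hz) * 1000.0

        def crossing(level: float, upto: int) -> float:
            above = np.flatnonzero(seg[: upto + 1] >= level)
            if above.size == 0:
                return float("nan")
            i = above[0]
            if i == 0 or seg[i] == seg[i - 1]:
                return t_ms[i]
            frac = (level - seg[i - 1]) / (seg[i] - seg[i - 1])
            return t_ms[i - 1] + frac * (t_ms[i] - t_ms[i - 1])

        latency = crossing(0.1 * potency, pk) - t_ap
        rise = crossing(0.8 * potency, pk) - crossing(0.2 * potency, pk)
        # decay fit over the 90% -> 30% falling segment; starting slightly
        # below the peak avoids contamination by the rising exponential
        decay = seg[pk:]
        start_c = np.flatnonzero(decay <= 0.9 * potency)
        start = start_c[0] if start_c.size else 0
        below = np.flatnonzero(decay <= 0.3 * potency)
        end = below[0] if below.size else decay.size
        if end - start >= 3:
            try:
                _, tau = _fit_decay(t_ms[pk + start : pk + end], decay[start:end])
            except RuntimeError:
                warnings.warn("decay fit did not converge", stacklevel=2)

    ppr = float("nan")
    if s.ap_peak_times_ms.size >= 2:
        all_avg = s.sweeps[keep].mean(axis=0)
        all_avg = all_avg - all_avg[
            s.idx(s.baseline_window_ms[0]) : s.idx(s.baseline_window_ms[1])
        ].mean()
        isi = s.ap_peak_times_ms[1] - s.ap_peak_times_ms[0]
        train = train_amplitudes(
            all_avg,
            s.rate_hz,
            s.ap_peak_times_ms[:2],
            frequency_hz=1000.0 / isi,
            response_window_ms=min(response_window_ms, isi),
        )
        if train.amplitudes_pa[0] > 0:
            ppr = float(train.amplitudes_pa[1] / train.amplitudes_pa[0])

    return UIPSCStats(
        n_total=n_total,
        n_failures=n_failures,
        failure_rate=failure_rate,
        potency_pa=potency,
        latency_ms=latency,
        rise_20_80_ms=rise,
        tau_decay_ms=tau,
        ppr=ppr,
    )


def train_amplitudes(
    avg_trace: np.ndarray,
    rate_hz: float,
    ap_times_ms: np.ndarray,
    frequency_hz: float,
    response_window_ms: float = 25.0,
    latency_ms: float = 2.0,
) -> TrainStats:
    """Per-pulse IPSC amplitudes during a train, corrected for summation.

    For pulse i >= 2 the decay of the preceding response is fitted with a
    monoexponential on the average trace and extrapolated under pulse i; the
    amplitude is the raw peak minus the extrapolated baseline. When the fit
    fails the last pre-pulse sample is used instead (with a warning).
    """
    ap_times_ms = np.atleast_1d(np.asarray(ap_times_ms, dtype=float))
    y = np.asarray(avg_trace, dtype=float)

    def idx(t_ms: float) -> int:
        return int(round(t_ms / 1000.0 * rate_hz))

    isi = 1000.0 / frequency_hz
    amps, corrections = [], []
    prev_fit: tuple[float, float, float] | None = None  # (t_peak_ms, A, tau)
    for i, t_ap in enumerate(ap_times_ms):
        w0 = idx(t_ap + latency_ms / 2)
        w1 = idx(t_ap + min(response_window_ms, isi))
        seg = y[w0:w1]
        pk = int(np.argmax(seg))
        t_peak_ms = (w0 + pk) / rate_hz * 1000.0
        raw_peak = float(seg[pk])
        if i == 0:
            corr = 0.0
        elif prev_fit is not None:
            tp, a, tau = prev_fit
            corr = float(a * np.exp(-(t_peak_ms - tp) / tau))
        else:
            corr = float(y[idx(t_ap) - 1])
        amps.append(raw_peak - corr)
        corrections.append(corr)
        # fit this response's decay for the next pulse
        next_t = ap_times_ms[i + 1] if i + 1 < ap_times_ms.size else t_ap + isi
        d0 = w0 + pk
        d1 = idx(next_t)
        # skip the rise-contaminated shoulder just after the peak
        fall = np.flatnonzero(y[d0:d1] <= 0.9 * raw_peak)
        if fall.size:
            d0 += fall[0]
        prev_fit = None
        if d1 - d0 >= 4:
            t_ms = np.arange(d0, d1) / rate_hz * 1000.0
            try:
                a, tau = _fit_decay(t_ms, y[d0:d1])
                prev_fit = (t_ms[0], a, tau)
            except (RuntimeError, ValueError):
                warnings.warn(
                    f"decay fit failed after pulse {i}; using last-sample baseline",
                    stacklevel=2,
                )
    return TrainStats(
        frequency_hz=frequency_hz,
        amplitudes_pa=np.array(amps),
        corrections_pa=np.array(corrections),
    )


def connection_ratio(
    n_connected: int, n_tested: int, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Connection probability with its Wilson score interval."""
    if n_tested < 1:
        raise ValueError("n_tested must be at least 1")
    if not (0 <= n_connected <= n_tested):
        raise ValueError("need 0 <= n_connected <= n_tested")
    p = n_connected / n_tested
    lo, hi = proportion_confint(n_connected, n_tested, alpha=alpha, method="wilson")
    return p, (min(float(lo), p), max(float(hi), p))
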