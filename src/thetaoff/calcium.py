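"""Somatic Ca2+ analysis: dF/F, transient peaks, state statistics, Otsu classes.

The raw fluorescence trace of each cell is converted to %dF/F against a
baseline F0 taken as the mean over the three 1-s windows with the lowest
fluorescence. Ca2+ transients are detected as threshold-crossing local maxima;
each transient's "peak signal" is the mean dF/F in a 315-ms window centred on
the peak. Peak signals are averaged per behavioural period and then per state
(locomotion vs immobility), giving the average peak Ca2+ transient per state
for each cell. The per-cell immobility/locomotion ratio is the scalar feature
on which Otsu's method splits the population into two activity classes, with
separability quantified by the discrimination criterion eta = sigma_B^2 /
sigma_T^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .behavior import FLICKERING, BehaviorSegmentation
from .core import RegularTimeSeries


@dataclass
class DffTrace:
    """%dF/F series with the baseline it was computed against."""

    dff: RegularTimeSeries
    f0: float
    f0_windows: list[tuple[float, float]]
    noise_sd_dff: float = float("nan")


@dataclass
class StateStats:
    mean_peak_dff: float
    n_periods: int
    n_transients: int
    period_means: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class CellStateProfile:
    """Per-state average peak Ca2+ transient amplitudes for one cell."""

    cell_id: str
    states: dict[str, StateStats]
    truncated_windows: int = 0

    def mean_peak(self, state: str) -> float:
        if state not in self.states:
            raise KeyError(f"state '{state}' has no periods for cell {self.cell_id}")
        return self.states[state].mean_peak_dff


@dataclass
class CellClassification:
    cell_ids: list[str]
    features: np.ndarray
    threshold: float
    eta: float
    labels: list[str]  # "type_I" (feature > threshold) or "type_II"


# ---------------------------------------------------------------------------
# baseline and dF/F


def compute_f0(
    trace: RegularTimeSeries, window_s: float = 1.0, n_windows: int = 3
) -> tuple[float, list[tuple[float, float]]]:
    """Baseline F0: mean over the ``n_windows`` non-overlapping ``window_s``
    intervals with the lowest mean fluorescence, chosen greedily."""
    w = int(round(window_s * trace.rate_hz))
    if len(trace) < n_windows * w:
        raise ValueError(
            f"trace of {trace.duration:.2f}s too short for {n_windows} x {window_s}s windows"
        )
    means = np.convolve(trace.data, np.ones(w) / w, mode="valid")  # every start index
    available = np.ones(means.size, dtype=bool)
    starts: list[int] = []
    for _ in range(n_windows):
        idx = np.flatnonzero(available)
        best = idx[np.argmin(means[idx])]
        starts.append(int(best))
        lo, hi = max(best - w + 1, 0), min(best + w, means.size)
        available[lo:hi] = False
        if not available.any() and len(starts) < n_windows:
            raise ValueError("could not place non-overlapping baseline windows")
    samples = np.concatenate([trace.data[s : s + w] for s in starts])
    windows = [
        (trace.t0 + s / trace.rate_hz, trace.t0 + (s + w) / trace.rate_hz)
        for s in sorted(starts)
    ]
    return float(samples.mean()), windows


def compute_dff(
    trace: RegularTimeSeries,
    f0: float | None = None,
    window_s: float = 1.0,
    n_windows: int = 3,
) -> DffTrace:
    """%dF/F = (F - F0)/F0 x 100, with F0 estimated when not supplied.

    The noise SD (in %dF/F) is estimated as the SD of the raw fluorescence
    inside the baseline windows, scaled by 100/F0.
    """
    if f0 is None:
        f0, windows = compute_f0(trace, window_s=window_s, n_windows=n_windows)
    else:
        try:
            _, windows = compute_f0(trace, window_s=window_s, n_windows=n_windows)
        except ValueError:
            windows = []
    if f0 <= 0:
        raise ValueError(f"F0 must be positive, got {f0}")
    dff = (trace.data - f0) / f0 * 100.0
    if windows:
        w_samples = np.concatenate(
            [
                trace.data[trace.index_at(t0) : trace.index_at(t1)]
                for t0, t1 in windows
            ]
        )
        noise_sd = float(w_samples.std()) / f0 * 100.0
    else:
        noise_sd = float("nan")
    series = trace.copy_with(dff, units="%dF/F")
    return DffTrace(dff=series, f0=float(f0), f0_windows=windows, noise_sd_dff=noise_sd)


# ---------------------------------------------------------------------------
# transients and state statistics


def detect_transients(
    dff: DffTrace, k_sd: float = 3.0, min_separation_ms: float = 315.0
) -> np.ndarray:
    """Transient peak times: local maxima above ``k_sd`` x noise SD with a
    minimum inter-peak separation (taller peak wins)."""
    noise_sd = dff.noise_sd_dff
    if not np.isfinite(noise_sd):
        raise ValueError("noise SD unavailable; compute dF/F with baseline windows")
    # noise-free traces: any positive local maximum is a transient
    noise_sd = max(noise_sd, 1e-6)
    series = dff.dff
    distance = max(int(round(min_separation_ms / 1000.0 * series.rate_hz)), 1)
    peaks, _ = find_peaks(series.data, height=k_sd * noise_sd, distance=distance)
    return series.t0 + peaks / series.rate_hz


def state_peak_stats(
    dff: DffTrace,
    segmentation: BehaviorSegmentation,
    transient_times_s: np.ndarray,
    window_ms: float = 315.0,
    cell_id: str = "",
) -> CellStateProfile:
    """Average peak Ca2+ transient per behavioural state.

    Each transient is assigned to the epoch containing its peak (flickering
    epochs are excluded); its peak signal is the mean dF/F over the centred
    ``window_ms`` window (truncated and counted when it crosses the trace
    edge). Peak signals are averaged within each period, and period averages
    are averaged per state. States with no transient-containing period are
    simply absent from the result.
    """
    series = dff.dff
    half = window_ms / 2000.0
    t_lo, t_hi = series.t0, series.t0 + series.duration
    per_period: dict[tuple[str, int], list[float]] = {}
    truncated = 0

    for t_pk in np.atleast_1d(transient_times_s):
        epoch = None
        for k, e in enumerate(segmentation.epochs):
            if e.t_start_s <= t_pk < e.t_end_s:
                epoch = (k, e)
                break
        if epoch is None or epoch[1].state == FLICKERING:
            continue
        w0, w1 = t_pk - half, t_pk + half
        if w0 < t_lo or w1 > t_hi:
            truncated += 1
            w0, w1 = max(w0, t_lo), min(w1, t_hi)
        seg = series.slice_time(w0, w1)
        if len(seg) == 0:
            continue
        per_period.setdefault((epoch[1].state, epoch[0]), []).append(
            float(seg.data.mean())
        )

    states: dict[str, StateStats] = {}
    for state in sorted({s for s, _ in per_period}):
        period_means = np.array(
            [np.mean(v) for (s, _), v in sorted(per_period.items()) if s == state]
        )
        n_tr = sum(len(v) for (s, _), v in per_period.items() if s == state)
        states[state] = StateStats(
            mean_peak_dff=float(period_means.mean()),
            n_periods=period_means.size,
            n_transients=n_tr,
            period_means=period_means,
        )
    return CellStateProfile(cell_id=cell_id, states=states, truncated_windows=truncated)


def classification_feature(
    profile_avg: dict[str, float], mode: str = "ratio"
) -> float:
    """Scalar classification feature from a cell's AVG per-state peaks.

    ``ratio`` (default): immobility / locomotion mean peak (scale-free across
    cells); ``difference``: immobility - locomotion.
    """
    imm, loc = profile_avg["immobility"], profile_avg["locomotion"]
    if mode == "ratio":
        if loc <= 0:
            raise ValueError("locomotion mean peak must be positive for the ratio")
        return imm / loc
    if mode == "difference":
        return imm - loc
    raise ValueError(f"unknown feature mode '{mode}'")


# ---------------------------------------------------------------------------
# Otsu classification


def otsu_threshold(features: np.ndarray, n_bins: int = 256) -> tuple[float, float]:
    """Otsu's threshold on a 1-D feature sample.

    The threshold is scanned over the internal edges of an ``n_bins``-bin
    histogram spanning the data range, maximizing the between-class variance
    sigma_B^2 = w1 (mu1 - mu)^2 + w2 (mu2 - mu)^2 computed on the actual
    sample values; ties break toward the lower threshold. Returns
    ``(threshold, eta)`` with eta = sigma_B^2 / sigma_T^2.
    """
    x = np.asarray(features, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 feature values")
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate: no separability, all features identical")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    mu, var_t = x.mean(), x.var()
    best_sb, best_t = -np.inf, edges[1]
    for t in edges[1:-1]:
        lo = x[x <= t]
        hi = x[x > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w1 = lo.size / x.size
        sb = w1 * (lo.mean() - mu) ** 2 + (1 - w1) * (hi.mean() - mu) ** 2
        if sb > best_sb:  # strict: ties keep the lower threshold
            best_sb, best_t = sb, float(t)
    return best_t, float(best_sb / var_t)


def otsu_classify(
    features: np.ndarray, cell_ids: list[str] | None = None, n_bins: int = 256
) -> CellClassification:
    """Segregate cells into two activity classes by Otsu's criterion.

    Cells whose feature exceeds the threshold are labelled ``type_I``
    (immobility-dominant when the feature is the immobility/locomotion
    ratio), the rest ``type_II``.
    """
    x = np.asarray(features, dtype=float)
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(x.size)]
    threshold, eta = otsu_threshold(x, n_bins=n_bins)
    labels = ["type_I" if v > threshold else "type_II" for v in x]
    if len(set(labels)) == 1:
        warnings.warn("Otsu threshold left a single class", stacklevel=2)
    return CellClassification(
        cell_ids=list(cell_ids), features=x, threshold=threshold, eta=eta, labels=labels
    )
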