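"""Synthetic in vivo sessions: wheel speed, LFP and GCaMP6f somatic traces.

The generator emulates the statistical structure of head-fixed treadmill
recordings: spontaneous alternation between locomotion, immobility and brief
"flickering" bouts; an LFP with locomotion-gated theta (~7 Hz) and immobility
ripples (125-250 Hz band) riding on a white + 1/f noise floor; and per-cell
somatic Ca2+ fluorescence produced by a spikes -> kernel forward model with
state-dependent firing rates. Every generated quantity is recorded in ground
truth tables so downstream detectors can be scored against a known answer.

Locomotion speed is drawn so that the *marginal* distribution of locomotion
samples matches the configured median and interquartile range exactly: a
latent AR(1) Gaussian process (correlation time 200 ms) is mapped through the
normal CDF and then through a piecewise log-linear quantile function anchored
at the configured quartiles. Temporal smoothness therefore never distorts the
realized speed quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from ..core import RegularTimeSeries, states_to_epochs

LOCOMOTION = "locomotion"
IMMOBILITY = "immobility"
FLICKERING = "flickering"


@dataclass
class SessionConfig:
    """Parameters of a synthetic treadmill session.

    Defaults reproduce the recording conditions the pipeline was designed
    around: 5-min sessions, 10-kHz LFP, 30-Hz imaging, locomotion speed with
    median 8.8 cm/s and IQR 5-30 cm/s, 7.1-Hz theta during locomotion and
    144.5-Hz ripples during immobility.
    """

    duration_s: float = 300.0
    speed_rate_hz: float = 100.0
    lfp_rate_hz: float = 10_000.0
    imaging_rate_hz: float = 30.0
    # behaviour
    locomotion_speed_median_cm_s: float = 8.8
    locomotion_speed_iqr: tuple[float, float] = (5.0, 30.0)
    locomotion_bout_median_s: float = 6.0
    immobility_bout_median_s: float = 8.0
    bout_log_sd: float = 0.4
    flicker_prob: float = 0.3
    speed_corr_time_s: float = 0.2
    # LFP
    theta_freq_hz: float = 7.1
    theta_amp_mv: float = 0.15
    ripple_freq_hz: float = 144.5
    ripple_rate_hz: float = 0.1
    ripple_duration_ms: float = 70.0
    ripple_snr_sd: float = 8.0
    ripple_amp_mv: float | None = None  # absolute fallback when noise is off
    ripple_min_gap_s: float = 0.1
    noise_sd_mv: float = 0.05
    noise_pink_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "speed_rate_hz", "lfp_rate_hz", "imaging_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (5.0 <= self.theta_freq_hz <= 10.0):
            raise ValueError("theta_freq_hz must lie in the 5-10 Hz theta band")
        if not (125.0 <= self.ripple_freq_hz <= 250.0):
            raise ValueError("ripple_freq_hz must lie in the 125-250 Hz ripple band")
        if self.ripple_duration_ms < 50.0:
            raise ValueError("ripple_duration_ms must be >= 50 ms")
        if not (0.0 <= self.flicker_prob <= 1.0):
            raise ValueError("flicker_prob must be a probability")
        q1, q3 = self.locomotion_speed_iqr
        if not (2.0 < q1 < self.locomotion_speed_median_cm_s < q3):
            raise ValueError("need 2 < Q1 < median < Q3 for the locomotion speed law")

    def substream(self, label: str) -> np.random.Generator:
        """Named child RNG so each stage can be regenerated independently."""
        order = {"behavior": 0, "lfp": 1, "ca": 2, "ephys": 3}
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(children[order[label]])


@dataclass
class CellSpec:
    """Forward model of one imaged cell.

    ``theta_off`` cells fire more during immobility, ``theta_on`` cells more
    during locomotion; fluorescence is the spike train convolved with a
    difference-of-exponentials GCaMP6f kernel (default rise 50 ms, decay
    400 ms), expressed in % dF/F and added to a constant baseline.
    """

    cell_class: str = "theta_off"
    rate_locomotion_hz: float = 0.05
    rate_immobility_hz: float = 0.4
    kernel_rise_ms: float = 50.0
    kernel_decay_ms: float = 400.0
    unit_amplitude_dff: float = 80.0
    baseline_f: float = 100.0
    noise_sd_dff: float = 2.0
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        if self.cell_class not in ("theta_off", "theta_on"):
            raise ValueError("cell_class must be 'theta_off' or 'theta_on'")
        if self.rate_locomotion_hz < 0 or self.rate_immobility_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.cell_class == "theta_off" and not (
            self.rate_immobility_hz > self.rate_locomotion_hz
        ):
            raise ValueError("theta_off requires rate_immobility > rate_locomotion")
        if self.cell_class == "theta_on" and not (
            self.rate_locomotion_hz > self.rate_immobility_hz
        ):
            raise ValueError("theta_on requires rate_locomotion > rate_immobility")
        if self.kernel_rise_ms <= 0 or self.kernel_decay_ms <= self.kernel_rise_ms:
            raise ValueError("kernel times must satisfy 0 < rise < decay")

    def state_rate(self, state: str) -> float:
        if state == LOCOMOTION:
            return self.rate_locomotion_hz
        if state == IMMOBILITY:
            return self.rate_immobility_hz
        return 0.5 * (self.rate_locomotion_hz + self.rate_immobility_hz)


@dataclass
class SyntheticSession:
    """One generated session: signals plus ground truth."""

    speed: RegularTimeSeries
    lfp: RegularTimeSeries
    ca_traces: list[RegularTimeSeries]
    truth: dict = field(default_factory=dict)
    config: SessionConfig | None = None


# ---------------------------------------------------------------------------
# speed


def _speed_quantile_fn(config: SessionConfig):
    """Piecewise log-linear quantile function for locomotion speed."""
    q1, q3 = config.locomotion_speed_iqr
    med = config.locomotion_speed_median_cm_s
    p_anchor = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    v_anchor = np.log([max(2.2, 0.5 * q1), q1, med, q3, 1.5 * q3])

    def q(p: np.ndarray) -> np.ndarray:
        return np.exp(np.interp(p, p_anchor, v_anchor))

    return q


def _draw_bouts(config: SessionConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Alternating bout plan as (state, n_samples), exactly tiling the trace."""
    fs = config.speed_rate_hz
    n_total = int(round(config.duration_s * fs))
    min_loco = int(round(1.5 * fs))

    def dur_samples(median_s: float) -> int:
        d = median_s * np.exp(config.bout_log_sd * rng.standard_normal())
        return max(int(round(d * fs)), 1)

    bouts: list[tuple[str, int]] = []
    state = IMMOBILITY
    used = 0
    while used < n_total:
        if state == IMMOBILITY:
            n = dur_samples(config.immobility_bout_median_s)
        else:
            n = max(dur_samples(config.locomotion_bout_median_s), min_loco)
        n = min(n, n_total - used)
        if state == LOCOMOTION and n < min_loco:
            state = IMMOBILITY  # tail too short for a locomotion bout
            continue
        bouts.append((state, n))
        used += n
        if used >= n_total:
            break
        nxt = LOCOMOTION if state == IMMOBILITY else IMMOBILITY
        if (
            state == IMMOBILITY
            and config.flicker_prob > 0
            and rng.random() < config.flicker_prob
        ):
            nf = min(int(round(rng.uniform(0.3, 0.9) * fs)), n_total - used)
            if nf > 0:
                bouts.append((FLICKERING, nf))
                used += nf
        state = nxt

    seen = {s for s, _ in bouts}
    if LOCOMOTION not in seen or IMMOBILITY not in seen:
        raise ValueError(
            "session duration too short to place at least one locomotion "
            "and one immobility bout"
        )
    return bouts


def generate_speed_trace(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> tuple[RegularTimeSeries, pd.DataFrame]:
    """Generate the wheel-speed trace and its ground-truth state epochs.

    Returns the speed series (cm/s) and a DataFrame with columns
    ``state, t_start_s, t_end_s`` whose epochs tile ``[0, duration]``.
    """
    rng = config.substream("behavior") if rng is None else rng
    fs = config.speed_rate_hz
    bouts = _draw_bouts(config, rng)
    qfn = _speed_quantile_fn(config)
    rho = float(np.exp(-1.0 / (fs * config.speed_corr_time_s)))

    chunks = []
    for state, n in bouts:
        if state == IMMOBILITY:
            chunks.append(np.zeros(n))
        elif state == FLICKERING:
            chunks.append(np.full(n, rng.uniform(0.3, 1.8)))
        else:
            z = np.empty(n)
            z[0] = rng.standard_normal()
            eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
            for i in range(1, n):  # latent AR(1), unit marginal variance
                z[i] = rho * z[i - 1] + np.sqrt(1 - rho**2) * eps[i - 1]
            u = special.ndtr(z)
            chunks.append(qfn(u))

    speed = RegularTimeSeries(np.concatenate(chunks), fs, units="cm/s", name="speed")
    rows = []
    t = 0.0
    for state, n in bouts:
        rows.append({"state": state, "t_start_s": t, "t_end_s": t + n / fs})
        t += n / fs
    return speed, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LFP


def _colored_noise(n: int, pink_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD white + 1/f mixture."""
    white = rng.standard_normal(n)
    if pink_fraction <= 0:
        return white
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * scale, n)
    pink /= pink.std()
    out = np.sqrt(1 - pink_fraction) * white + np.sqrt(pink_fraction) * pink
    return out / out.std()


def _state_mask(epochs: pd.DataFrame, state: str, n: int, fs: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for _, row in epochs[epochs["state"] == state].iterrows():
        i0 = int(round(row["t_start_s"] * fs))
        i1 = int(round(row["t_end_s"] * fs))
        mask[i0:i1] = True
    return mask


def generate_lfp(
    truth_epochs: pd.DataFrame,
    config: SessionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[RegularTimeSeries, pd.DataFrame]:
    """Generate the LFP and a ripple ground-truth table.

    Theta (a ``theta_freq_hz`` sinusoid with a 100-ms amplitude ramp) is
    present only during locomotion epochs. Ripples are Gaussian-envelope
    bursts at ``ripple_freq_hz``, placed at Poisson times restricted to
    immobility with at least ``ripple_min_gap_s`` between envelope edges; the
    burst peak amplitude is ``ripple_snr_sd`` times the SD of the band-passed
    (125-250 Hz) noise floor.
    """
    from ..lfp import RIPPLE_BAND, bandpass  # local import: lfp is pure DSP

    rng = config.substream("lfp") if rng is None else rng
    fs = config.lfp_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    noise = (
        config.noise_sd_mv * _colored_noise(n, config.noise_pink_fraction, rng)
        if config.noise_sd_mv > 0
        else np.zeros(n)
    )

    loco = _state_mask(truth_epochs, LOCOMOTION, n, fs).astype(float)
    ramp = int(round(0.1 * fs))
    if ramp > 1:
        win = np.hanning(2 * ramp + 1)
        loco = np.convolve(loco, win / win.sum(), mode="same")
    phase = rng.uniform(0, 2 * np.pi)
    theta = config.theta_amp_mv * np.sin(2 * np.pi * config.theta_freq_hz * t + phase) * loco

    # amplitude calibration against the band-passed noise floor
    if config.noise_sd_mv > 0:
        bg = bandpass(RegularTimeSeries(noise, fs, units="mV"), RIPPLE_BAND)
        immob = _state_mask(truth_epochs, IMMOBILITY, n, fs)
        base = bg.data[immob] if immob.any() else bg.data
        amp = config.ripple_snr_sd * float(base.std())
    else:
        amp = config.ripple_amp_mv if config.ripple_amp_mv is not None else 0.1

    dur_s = config.ripple_duration_ms / 1000.0
    sigma = dur_s / 4.0
    gap = config.ripple_min_gap_s
    lfp = noise + theta
    rows = []
    if config.ripple_rate_hz > 0:
        if config.ripple_rate_hz * (gap + dur_s) > 0.8:
            raise ValueError(
                "ripple_rate_hz too high to honour the minimum event separation"
            )
        margin = dur_s / 2 + gap / 2
        last_end = -np.inf
        for _, row in truth_epochs[truth_epochs["state"] == IMMOBILITY].iterrows():
            lo, hi = row["t_start_s"] + margin, row["t_end_s"] - margin
            if hi <= lo:
                continue
            k = rng.poisson(config.ripple_rate_hz * (hi - lo))
            centers = np.sort(rng.uniform(lo, hi, size=k))
            for tc in centers:
                if tc - dur_s / 2 < last_end + gap:
                    continue
                phase_r = rng.uniform(0, 2 * np.pi)
                i0 = max(int((tc - 2 * dur_s) * fs), 0)
                i1 = min(int((tc + 2 * dur_s) * fs), n)
                tt = t[i0:i1] - tc
                burst = amp * np.exp(-(tt**2) / (2 * sigma**2)) * np.sin(
                    2 * np.pi * config.ripple_freq_hz * tt + phase_r
                )
                lfp[i0:i1] += burst
                rows.append(
                    {
                        "t_center_s": tc,
                        "t_start_s": tc - dur_s / 2,
                        "t_end_s": tc + dur_s / 2,
                        "duration_ms": config.ripple_duration_ms,
                        "freq_hz": config.ripple_freq_hz,
                        "amplitude_mv": amp,
                    }
                )
                last_end = tc + dur_s / 2

    ripple_truth = pd.DataFrame(
        rows,
        columns=[
            "t_center_s",
            "t_start_s",
            "t_end_s",
            "duration_ms",
            "freq_hz",
            "amplitude_mv",
        ],
    )
    return RegularTimeSeries(lfp, fs, units="mV", name="lfp"), ripple_truth


# ---------------------------------------------------------------------------
# calcium


def gcamp_kernel(
    rise_ms: float, decay_ms: float, rate_hz: float, n_decay: float = 8.0
) -> np.ndarray:
    """Difference-of-exponentials kernel sampled at ``rate_hz``, peak = 1."""
    tau_r, tau_d = rise_ms / 1000.0, decay_ms / 1000.0
    t = np.arange(0, n_decay * tau_d, 1.0 / rate_hz)
    h = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    # normalize on the sampled grid so one spike peaks exactly at 1
    return h / h.max()


def generate_ca_traces(
    truth_epochs: pd.DataFrame,
    cell_specs: Sequence[CellSpec],
    config: SessionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RegularTimeSeries], dict]:
    """Generate raw somatic fluorescence traces and the spike/label truth.

    Spikes are inhomogeneous Poisson with per-state rates; fluorescence is
    ``baseline_f * (1 + (dff + noise)/100)`` with dff the kernel-convolved
    spike train scaled by ``unit_amplitude_dff``.
    """
    rng = config.substream("ca") if rng is None else rng
    fs = config.imaging_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    state_per_sample = np.full(n, IMMOBILITY, dtype=object)
    for state in (LOCOMOTION, FLICKERING):
        state_per_sample[_state_mask(truth_epochs, state, n, fs)] = state

    traces, spikes, labels = [], {}, {}
    for spec in cell_specs:
        rate = np.array([spec.state_rate(s) for s in state_per_sample])
        counts = rng.poisson(rate / fs)
        kern = gcamp_kernel(spec.kernel_rise_ms, spec.kernel_decay_ms, fs)
        dff = spec.unit_amplitude_dff * np.convolve(counts, kern)[:n]
        if spec.noise_sd_dff > 0:
            dff = dff + spec.noise_sd_dff * rng.standard_normal(n)
        f = spec.baseline_f * (1.0 + dff / 100.0)
        traces.append(RegularTimeSeries(f, fs, units="au", name=spec.cell_id))
        spikes[spec.cell_id] = np.repeat(t, counts)
        labels[spec.cell_id] = spec.cell_class
    return traces, {"spikes": spikes, "labels": labels}


def simulate_session(
    config: SessionConfig, cell_specs: Sequence[CellSpec] = ()
) -> SyntheticSession:
    """Generate a full session (speed + LFP + Ca traces) from one seed.

    Randomness flows through named substreams (behavior / lfp / ca) of the
    session seed, so each stage is individually reproducible.
    """
    speed, epochs = generate_speed_trace(config)
    lfp, ripples = generate_lfp(epochs, config)
    ca, ca_truth = generate_ca_traces(epochs, cell_specs, config)
    truth = {"epochs": epochs, "ripples": ripples, **ca_truth}
    return SyntheticSession(speed=speed, lfp=lfp, ca_traces=ca, truth=truth, config=config)
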