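"""Synthetic intracellular protocols: uIPSC sweep sets, coupled pairs, steps.

Unit conventions follow patch-clamp practice: voltages in mV, currents in pA
(converted to nA internally so that nA x MOhm = mV), resistances in MOhm,
times in s unless a name says otherwise. The paired-cell model is two passive
isopotential compartments joined by a junctional resistance; its steady-state
voltage division has the closed form dV2/dV1 = R2 / (Rj + R2), which the
integrator must reproduce and tests verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import RegularTimeSeries
from ..coupling import PairedRecording
from ..intrinsic import SweepFamily
from ..synaptic import SweepSet


@dataclass
class SynapseSpec:
    """Generative model of a unitary connection with probabilistic release.

    Defaults mirror the connection statistics the analysis is designed to
    recover: ~60% failures (p_release 0.4), 16.3 pA potency near a 2.5 pA
    noise floor, 2 ms latency, 20-Hz paired pulses over 100 sweeps.
    """

    p_release: float = 0.4
    potency_pa: float = 16.3
    amplitude_cv: float = 0.15
    latency_ms: float = 2.0
    rise_ms: float = 1.0
    decay_ms: float = 10.0
    noise_sd_pa: float = 2.5
    n_sweeps: int = 100
    ap_times_ms: tuple[float, ...] = (100.0, 150.0)
    sweep_duration_ms: float = 300.0
    rate_hz: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_release <= 1.0):
            raise ValueError("p_release must be a probability")
        if self.rise_ms <= 0 or self.decay_ms <= self.rise_ms:
            raise ValueError("kinetics must satisfy 0 < rise < decay")
        if self.n_sweeps < 1:
            raise ValueError("need at least one sweep")


def _psc_kernel(rise_ms: float, decay_ms: float, rate_hz: float) -> np.ndarray:
    """Difference-of-exponentials current kernel, peak normalized to 1."""
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    t_peak = np.log(td / tr) * tr * td / (td - tr)
    t = np.arange(0.0, 8 * td, 1.0 / rate_hz)
    h = np.exp(-t / td) - np.exp(-t / tr)
    return h / (np.exp(-t_peak / td) - np.exp(-t_peak / tr))


def generate_uipsc_sweeps(
    spec: SynapseSpec, rng: np.random.Generator | None = None
) -> tuple[SweepSet, pd.DataFrame]:
    """Generate a uIPSC sweep set with per-AP release truth.

    Each presynaptic AP releases independently with ``p_release``; a success
    adds a difference-of-exponentials outward current of amplitude
    ``potency_pa * (1 + CV * N(0,1))`` at the fixed latency. Gaussian baseline
    noise is added throughout.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_samp = int(round(spec.sweep_duration_ms / 1000.0 * spec.rate_hz))
    kern = _psc_kernel(spec.rise_ms, spec.decay_ms, spec.rate_hz)
    sweeps = (
        spec.noise_sd_pa * rng.standard_normal((spec.n_sweeps, n_samp))
        if spec.noise_sd_pa > 0
        else np.zeros((spec.n_sweeps, n_samp))
    )
    rows = []
    for i in range(spec.n_sweeps):
        for j, t_ap in enumerate(spec.ap_times_ms):
            success = bool(rng.random() < spec.p_release)
            amp = 0.0
            if success:
                amp = spec.potency_pa * max(
                    1.0 + spec.amplitude_cv * rng.standard_normal(), 0.0
                )
                i0 = int(round((t_ap + spec.latency_ms) / 1000.0 * spec.rate_hz))
                i1 = min(i0 + kern.size, n_samp)
                sweeps[i, i0:i1] += amp * kern[: i1 - i0]
            rows.append(
                {
                    "sweep": i,
                    "ap_index": j,
                    "success": success,
                    "amplitude_pa": amp,
                    "latency_ms": spec.latency_ms,
                }
            )
    sweep_set = SweepSet(
        sweeps=sweeps,
        rate_hz=spec.rate_hz,
        ap_peak_times_ms=np.asarray(spec.ap_times_ms, dtype=float),
        baseline_window_ms=(0.0, 0.9 * min(spec.ap_times_ms)),
    )
    return sweep_set, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coupled pair


def ap_template(
    rate_hz: float,
    amp_mv: float = 80.0,
    width_ms: float = 1.0,
    ahp_mv: float = 8.0,
    ahp_tau_ms: float = 50.0,
) -> np.ndarray:
    """Stereotyped spike waveform: triangular fast spike + exponential AHP.

    Starts at 0, rises linearly to ``amp_mv`` at ``width_ms/2``, returns to 0
    at ``width_ms``, then relaxes from ``-ahp_mv`` with time constant
    ``ahp_tau_ms``.
    """
    dt_ms = 1000.0 / rate_hz
    t_spike = np.arange(0.0, width_ms, dt_ms)
    spike = amp_mv * (1.0 - np.abs(t_spike - width_ms / 2) / (width_ms / 2))
    t_ahp = np.arange(0.0, 6 * ahp_tau_ms, dt_ms)
    ahp = -ahp_mv * np.exp(-t_ahp / ahp_tau_ms)
    return np.concatenate([spike, ahp])


@dataclass
class CircuitSpec:
    """Two passive isopotential cells joined by a junctional resistance.

    The implied steady-state coupling coefficient is
    ``r_in_2 / (r_junction + r_in_2)`` (about 0.11 with the defaults).
    """

    r_in_1_mohm: float = 200.0
    r_in_2_mohm: float = 200.0
    r_junction_mohm: float = 1620.0
    tau_m_ms: float = 20.0
    v_rest_mv: float = -65.0
    ap_amp_mv: float = 80.0
    ap_width_ms: float = 1.0
    ahp_mv: float = 8.0
    ahp_tau_ms: float = 50.0
    noise_sd_mv: float = 0.0
    rate_hz: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_in_1_mohm <= 0 or self.r_in_2_mohm <= 0:
            raise ValueError("input resistances must be positive")
        if self.r_junction_mohm <= 0:
            raise ValueError("junctional resistance must be positive")

    @property
    def cc_12_closed_form(self) -> float:
        if np.isinf(self.r_junction_mohm):
            return 0.0
        return self.r_in_2_mohm / (self.r_junction_mohm + self.r_in_2_mohm)


@dataclass
class StepProtocol:
    amplitude_pa: float = -140.0
    duration_s: float = 1.0
    t_on_s: float = 0.3
    total_s: float = 1.8
    target_cell: int = 1


@dataclass
class APInjectionProtocol:
    spike_times_s: tuple[float, ...] = (0.5,)
    total_s: float = 1.5


@dataclass
class SinusoidProtocol:
    freq_hz: float = 5.0
    amplitude_pa: float = 60.0
    t_on_s: float = 0.5
    duration_s: float = 2.0
    total_s: float = 3.5
    targets: tuple[int, ...] = (1,)
    bias2_pa: float = 0.0
    forced_spike_times_s: tuple[float, ...] = ()
    spike_threshold_mv: float | None = None
    refractory_s: float = 0.05


def generate_paired_recording(
    circuit: CircuitSpec,
    protocol: StepProtocol | APInjectionProtocol | SinusoidProtocol,
    rng: np.random.Generator | None = None,
) -> PairedRecording:
    """Simulate a paired recording from the two-cell resistive circuit.

    Forward-Euler integration of the coupled passive membranes; AP templates
    are imposed on cell 1's voltage (the imposed excursion drives junctional
    current into cell 2 but does not alter cell 1's own state, mimicking a
    stereotyped regenerative event). Raises when the time step is too coarse
    for a stable integration.
    """
    rng = np.random.default_rng(circuit.seed) if rng is None else rng
    fs = circuit.rate_hz
    dt_ms = 1000.0 / fs
    if dt_ms > circuit.tau_m_ms / 5.0:
        raise ValueError("integration step too coarse for the membrane time constant")
    n = int(round(protocol.total_s * fs))
    t = np.arange(n) / fs

    i1 = np.zeros(n)  # nA
    i2 = np.zeros(n)
    spike_times: list[float] = []
    threshold = None
    if isinstance(protocol, StepProtocol):
        on = int(protocol.t_on_s * fs)
        off = int((protocol.t_on_s + protocol.duration_s) * fs)
        target = i1 if protocol.target_cell == 1 else i2
        target[on:off] = protocol.amplitude_pa / 1000.0
    elif isinstance(protocol, APInjectionProtocol):
        spike_times = list(protocol.spike_times_s)
    else:
        on = int(protocol.t_on_s * fs)
        off = int((protocol.t_on_s + protocol.duration_s) * fs)
        wave = protocol.amplitude_pa / 1000.0 * np.sin(
            2 * np.pi * protocol.freq_hz * (t[on:off] - t[on])
        )
        if 1 in protocol.targets:
            i1[on:off] += wave
        if 2 in protocol.targets:
            i2[on:off] += wave
        i2 += protocol.bias2_pa / 1000.0
        spike_times = list(protocol.forced_spike_times_s)
        threshold = protocol.spike_threshold_mv

    tmpl = ap_template(
        fs, circuit.ap_amp_mv, circuit.ap_width_ms, circuit.ahp_mv, circuit.ahp_tau_ms
    )
    tmpl_wave = np.zeros(n)
    for ts_ in spike_times:
        k0 = int(round(ts_ * fs))
        k1 = min(k0 + tmpl.size, n)
        if 0 <= k0 < n:
            tmpl_wave[k0:k1] += tmpl[: k1 - k0]

    e = circuit.v_rest_mv
    r1, r2, rj = circuit.r_in_1_mohm, circuit.r_in_2_mohm, circuit.r_junction_mohm
    g_j = 0.0 if np.isinf(rj) else 1.0 / rj
    c1 = circuit.tau_m_ms / r1  # nF
    c2 = circuit.tau_m_ms / r2
    v1 = np.empty(n)
    v2 = np.empty(n)
    v1_state, v2_state = e, e
    last_spike = -np.inf
    for k in range(n):
        v1_eff = v1_state + tmpl_wave[k]
        if (
            threshold is not None
            and v1_eff >= threshold
            and t[k] - last_spike > getattr(protocol, "refractory_s", 0.05)
        ):
            last_spike = t[k]
            k1 = min(k + tmpl.size, n)
            tmpl_wave[k:k1] += tmpl[: k1 - k]
            v1_eff = v1_state + tmpl_wave[k]
        v1[k], v2[k] = v1_eff, v2_state
        dv1 = (-(v1_state - e) / r1 + g_j * (v2_state - v1_eff) + i1[k]) / c1
        dv2 = (-(v2_state - e) / r2 + g_j * (v1_eff - v2_state) + i2[k]) / c2
        v1_state += dv1 * dt_ms
        v2_state += dv2 * dt_ms

    if circuit.noise_sd_mv > 0:
        v1 = v1 + circuit.noise_sd_mv * rng.standard_normal(n)
        v2 = v2 + circuit.noise_sd_mv * rng.standard_normal(n)

    proto_meta: dict = {"kind": type(protocol).__name__}
    if isinstance(protocol, StepProtocol):
        proto_meta.update(
            t_on_s=protocol.t_on_s,
            t_off_s=protocol.t_on_s + protocol.duration_s,
            amplitude_pa=protocol.amplitude_pa,
            target_cell=protocol.target_cell,
        )
    elif isinstance(protocol, SinusoidProtocol):
        proto_meta.update(
            freq_hz=protocol.freq_hz,
            t_on_s=protocol.t_on_s,
            t_off_s=protocol.t_on_s + protocol.duration_s,
        )
    proto_meta["spike_times_s"] = list(spike_times)
    return PairedRecording(
        v1=RegularTimeSeries(v1, fs, units="mV", name="cell1"),
        v2=RegularTimeSeries(v2, fs, units="mV", name="cell2"),
        i1=RegularTimeSeries(i1 * 1000.0, fs, units="pA", name="i1"),
        i2=RegularTimeSeries(i2 * 1000.0, fs, units="pA", name="i2"),
        protocol=proto_meta,
    )


# ---------------------------------------------------------------------------
# current-step families


@dataclass
class CellParams:
    """Phenomenological single-cell model for current-step sweep synthesis.

    Hyperpolarizing steps show an Ih-like sag: the response is a double
    exponential ``I R [(1 - e^{-t/tau}) - a (1 - e^{-t/tau_sag})]`` whose
    plateau is depolarized back by the sag fraction ``a``. Suprathreshold
    steps clip at threshold and emit stereotyped AP templates.
    """

    r_in_mohm: float = 200.0
    tau_m_ms: float = 20.0
    v_rest_mv: float = -65.0
    spike_threshold_mv: float = -58.0
    sag_fraction: float = 0.15
    sag_tau_ms: float = 150.0
    f0_hz: float = 5.0
    firing_gain_hz_per_pa: float = 0.2
    ap_amp_mv: float = 80.0
    ap_width_ms: float = 1.0
    ahp_mv: float = 8.0
    ahp_tau_ms: float = 50.0
    noise_sd_mv: float = 0.0
    rate_hz: float = 20_000.0
    seed: int = 0


def sag_closed_form(params: CellParams, i_pa: float) -> tuple[float, float]:
    """Analytic (peak, plateau) deflection of the double-exponential sag
    response, in mV relative to rest; valid for hyperpolarizing ``i_pa``."""
    ir = i_pa / 1000.0 * params.r_in_mohm  # mV
    a, tau, taus = params.sag_fraction, params.tau_m_ms, params.sag_tau_ms
    t = np.linspace(0, 10 * taus, 20001)
    u = ir * ((1 - np.exp(-t / tau)) - a * (1 - np.exp(-t / taus)))
    return float(u.min()), float(ir * (1 - a))


def generate_current_steps(
    params: CellParams,
    amplitudes_pa: np.ndarray | None = None,
    t_on_s: float = 0.2,
    pulse_s: float = 1.0,
    post_s: float = 0.3,
    rng: np.random.Generator | None = None,
) -> SweepFamily:
    """Family of voltage sweeps for steps from -240 to +280 pA (40-pA grid)."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if amplitudes_pa is None:
        amplitudes_pa = np.arange(-240.0, 281.0, 40.0)
    fs = params.rate_hz
    total = t_on_s + pulse_s + post_s
    n = int(round(total * fs))
    t = np.arange(n) / fs
    on, off = int(t_on_s * fs), int((t_on_s + pulse_s) * fs)
    tau = params.tau_m_ms / 1000.0
    taus = params.sag_tau_ms / 1000.0
    u_th = params.spike_threshold_mv - params.v_rest_mv
    tmpl = ap_template(
        fs, params.ap_amp_mv, params.ap_width_ms, params.ahp_mv, params.ahp_tau_ms
    )

    sweeps: dict[float, RegularTimeSeries] = {}
    for i_pa in amplitudes_pa:
        ir = i_pa / 1000.0 * params.r_in_mohm  # mV plateau without sag
        v = np.full(n, params.v_rest_mv)
        tp = t[on:off] - t_on_s
        u = ir * (1 - np.exp(-tp / tau))
        if i_pa < 0 and params.sag_fraction > 0:
            u = u - ir * params.sag_fraction * (1 - np.exp(-tp / taus))
        if ir > u_th > 0:
            # threshold crossing; clip and emit template APs
            t_star = -tau * np.log(1 - u_th / ir)
            u = np.minimum(u, u_th)
            rate = params.f0_hz + params.firing_gain_hz_per_pa * max(
                i_pa - u_th / params.r_in_mohm * 1000.0, 0.0
            )
            isi = 1.0 / rate
            t_spk = t_star
            while t_spk < pulse_s:
                k0 = on + int(round(t_spk * fs))
                k1 = min(k0 + tmpl.size, n)
                u_pad = np.zeros(n)
                u_pad[k0:k1] = tmpl[: k1 - k0]
                v += u_pad
                t_spk += isi
        v[on:off] += u
        u_end = u[-1] if off > on else 0.0
        v[off:] += u_end * np.exp(-(t[off:] - t[off - 1]) / tau)
        if params.noise_sd_mv > 0:
            v = v + params.noise_sd_mv * rng.standard_normal(n)
        sweeps[float(i_pa)] = RegularTimeSeries(v, fs, units="mV", name=f"{i_pa:+.0f}pA")
    return SweepFamily(sweeps=sweeps, pulse_window=(t_on_s, t_on_s + pulse_s))
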