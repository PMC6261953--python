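"""Gap-junction metrics on a simulated electrically coupled pair.

The junction divides steady-state voltage (coupling coefficient CC) and
low-pass filters transients: a presynaptic AP arrives in the coupled cell as
a tiny fast spikelet followed by a relatively larger slow AHP component.
"""

import numpy as np

from thetaoff import (
    CircuitSpec,
    blocker_effect,
    cc_regression,
    coupling_coefficient,
    generate_paired_recording,
    spikelet_components,
)
from thetaoff.coupling import _step_delta
from thetaoff.synth.ephys import APInjectionProtocol, StepProtocol

circuit = CircuitSpec()  # 200-MOhm cells, 1.62-GOhm junction
pair = generate_paired_recording(circuit, StepProtocol(amplitude_pa=-140.0))
cc = coupling_coefficient(pair)
print(f"coupling coefficient (-140 pA step): {cc:.3f} "
      f"(closed form {circuit.cc_12_closed_form:.3f}; coupled if >= 0.01)")

dv1, dv2 = [], []
for amp in (-180.0, -140.0, -100.0, -60.0):
    p = generate_paired_recording(circuit, StepProtocol(amplitude_pa=amp))
    dv1.append(_step_delta(p.v1, p.protocol["t_on_s"], p.protocol["t_off_s"]))
    dv2.append(_step_delta(p.v2, p.protocol["t_on_s"], p.protocol["t_off_s"]))
slope, se = cc_regression(np.array(dv1), np.array(dv2))
print(f"CC as regression slope across steps: {slope:.3f} +/- {se:.4f}")

times = (0.4, 0.9, 1.4)
ap_pair = generate_paired_recording(
    circuit, APInjectionProtocol(spike_times_s=times, total_s=2.0)
)
pos, neg = spikelet_components(ap_pair, np.array(times))
print(f"spikelet: +{pos:.2f} mV fast component, {neg:.2f} mV slow (AHP) component")
print(f"  relative conduction: spike {pos / circuit.ap_amp_mv:.1%} "
      f"vs AHP {abs(neg) / circuit.ahp_mv:.1%} -> slow components pass better")

blocked = CircuitSpec(r_junction_mohm=9 * circuit.r_junction_mohm)
cc_after = coupling_coefficient(generate_paired_recording(blocked, StepProtocol()))
print(f"after 9x junctional resistance (blocker): CC {cc_after:.4f}, "
      f"{blocker_effect(cc, cc_after):.0f}% of control")
print("-> weak coupling (~0.11) that low-pass filters spikes explains why "
      "these pairs rarely fire synchronously.")
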