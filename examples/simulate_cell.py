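"""Simulate one synthetic motoneuron: a voltage-clamp and a current-clamp
triangular ramp, with the model's closed-form ground truth printed next
to them.

The voltage-clamp ramp (-80 to -40 mV at 5 mV/s) evokes the N-shaped
leak-subtracted current whose downward deflection is the persistent
inward current (PIC); the current-clamp ramp evokes repetitive firing.
"""

from picquant import RampSpec, SimCellParams, simulate_cclamp_ramp, simulate_vclamp_ramp
from picquant.synth import pic_ground_truth, rheobase

params = SimCellParams(seed=1)
truth = pic_ground_truth(params)

vc = simulate_vclamp_ramp(params, RampSpec(-80, -40, 5.0, baseline_duration=1.0))
rb = rheobase(params)
cc = simulate_cclamp_ramp(params, RampSpec(0.0, rb + 4.0, (rb + 4.0) / 4.0, baseline_duration=1.0))

print(f"voltage-clamp sweep: {len(vc)} samples at {vc.sampling_rate:.0f} Hz")
print(f"current-clamp sweep: {len(cc)} samples, {len(cc.meta['spike_times'])} spikes")
print(f"true input conductance : {truth['g_in_true']:.3f} uS")
print(f"true PIC amplitude     : {truth['amplitude_true']:.2f} nA "
      f"(peak at {truth['peak_voltage_true']:.1f} mV)")
print(f"quasi-static rheobase  : {rb:.2f} nA")
# The PIC amplitude is the largest downward deflection of the
# leak-subtracted I-V curve; the rheobase is the ramp current at which
# the subthreshold equilibrium disappears and firing must start.
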