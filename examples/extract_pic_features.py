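"""Voltage-clamp measurement chain on a simulated ramp: split the sweep
at the apex, fit the leak line over -80..-65 mV, subtract it, and read
off the PIC features -- then compare with the generator's ground truth.
"""

from picquant import RampSpec, SimCellParams, extract_vclamp, simulate_vclamp_ramp
from picquant.synth import pic_ground_truth

params = SimCellParams(seed=4, V_half_pic=-50.0)
sweep = simulate_vclamp_ramp(params, RampSpec(-80, -40, 5.0, baseline_duration=1.0))
measure = extract_vclamp(sweep)
truth = pic_ground_truth(params)

print(f"input conductance : {measure.leak_fit.slope:.3f} uS   (true {truth['g_in_true']:.3f})")
print(f"PIC amplitude asc : {measure.amplitude_asc:.2f} nA    (closed form {truth['amplitude_leakfit']:.2f})")
print(f"PIC amplitude desc: {measure.amplitude_desc:.2f} nA")
print(f"peak voltage asc  : {measure.peak_voltage_asc:.1f} mV  (closed form {truth['peak_voltage_leakfit']:.1f})")
print(f"onset voltage     : {measure.onset_voltage:.1f} mV")
print(f"end voltage       : {measure.end_voltage:.1f} mV")
# Onset (ascending) and end (descending) are where the leak-subtracted
# current clears a noise-scaled detection threshold; the small asc/desc
# differences reflect the PIC's activation time constant (hysteresis).
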