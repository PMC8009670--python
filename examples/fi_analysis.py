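"""Current-clamp chain on a simulated triangular current ramp: spike
detection by the 10 mV/ms criterion, recruitment/de-recruitment,
instantaneous F-I curves, subprimary/primary range segmentation and the
primary-range gains.
"""

from picquant import (
    RampSpec,
    SimCellParams,
    detect_spikes,
    fi_gain,
    instantaneous_fi,
    recruitment_measures,
    segment_spr_pr,
    simulate_cclamp_ramp,
)
from picquant.synth import rheobase

params = SimCellParams(seed=3)
rb = rheobase(params)
ramp = RampSpec(0.0, rb + 4.0, (rb + 4.0) / 4.0, baseline_duration=1.0)
sweep = simulate_cclamp_ramp(params, ramp)

train = detect_spikes(sweep)
rec = recruitment_measures(sweep, train)
fi_asc, fi_desc = instantaneous_fi(sweep, train)
pr_asc = segment_spr_pr(fi_asc)
pr_desc = segment_spr_pr(fi_desc)

print(f"spikes                : {len(train)}")
print(f"voltage threshold     : {rec['v_threshold']:.1f} mV")
print(f"recruitment current   : {rec['recruitment_current']:.2f} nA  (rheobase {rb:.2f})")
print(f"de-recruitment current: {rec['derecruitment_current']:.2f} nA  (delta I {rec['delta_i']:.2f})")
if pr_asc is not None:
    print(f"SPR/PR transition     : {pr_asc.transition_current:.2f} nA at "
          f"{pr_asc.transition_frequency:.1f} Hz")
print(f"gain ascending PR     : {fi_gain(fi_asc, pr_asc):.1f} Hz/nA")
print(f"gain descending PR    : {fi_gain(fi_desc, pr_desc):.1f} Hz/nA")
# The subprimary range is the steep, variable firing just after
# recruitment; the gain is the slope of the linear fit over the primary
# range only, computed per limb (descending gains run steeper).
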