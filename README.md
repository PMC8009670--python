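# picquant

Quantitative analysis of motoneuron excitability from intracellular
triangular-ramp recordings, plus a synthetic motoneuron that makes the
whole chain testable end to end.

In studies of spinal motoneuron physiology — in particular of the
SOD1(G93A) mouse model of ALS — two ramp protocols carry most of the
information: a slow triangular **voltage-clamp** ramp (−80 → −40 mV at
5 mV/s), whose leak-subtracted current-voltage relation exposes the
persistent inward current (PIC) as a downward deflection, and a
triangular **current-clamp** ramp, whose instantaneous frequency-current
(F-I) relation splits into a steep, variable subprimary range followed
by a linear primary range. `picquant` is for electrophysiologists and
computational neuroscientists who want those measurements, and the
estimation statistics built on them, as reproducible code rather than
as manual cursor placements.

The package implements:

* **Voltage clamp** — limb splitting, OLS leak fit over −80..−65 mV
  (slope = input conductance G_in, in µS = nA/mV), leak subtraction, and
  PIC amplitude / peak voltage / onset / end voltage per limb.
* **Current clamp** — spike detection by the 10 mV/ms dV/dt criterion,
  voltage threshold, recruitment and de-recruitment currents (ΔI, ΔF),
  instantaneous F-I curves, a deterministic subprimary/primary-range
  changepoint rule, and per-limb F-I gains.
* **Cohort pipeline** — RMP-based quality control, age grouping,
  assembly of the canonical 21-feature table, genotype comparisons,
  age regressions, PIC-vs-conductance ANCOVA, firing vs non-firing
  comparisons and PCA.
* **Estimation statistics** — Hedges' g

      g = J(df) · (m₂ − m₁) / s_pooled,
      s_pooled = √(((n₁−1)s₁² + (n₂−1)s₂²)/df),  df = n₁ + n₂ − 2,

  with the exact gamma-ratio correction J and 95% bias-corrected and
  accelerated (BCa) bootstrap intervals (5000 resamples), Welch's t
  alongside.
* **Synthetic motoneuron** — a conductance-based model (leak + lumped
  Boltzmann PIC + opposing outward current, integrate-and-fire with
  inserted action-potential waveforms and two adaptation currents) and
  cohort factories whose group distributions emulate published
  SOD1(G93A)/wild-type summaries, with closed-form ground truth attached
  to every cell.

## Worked example

```python
from picquant import RampSpec, SimCellParams, extract_vclamp, simulate_vclamp_ramp
from picquant.synth import pic_ground_truth

params = SimCellParams(seed=4, V_half_pic=-50.0)
sweep = simulate_vclamp_ramp(params, RampSpec(-80, -40, 5.0, baseline_duration=1.0))
m = extract_vclamp(sweep)
print(m.leak_fit.slope, m.amplitude_asc, m.onset_voltage)
```

prints (values from `examples/extract_pic_features.py`):

```
input conductance : 0.419 uS   (true 0.420)
PIC amplitude asc : 2.40 nA    (closed form 2.58)
PIC amplitude desc: 2.67 nA
peak voltage asc  : -42.7 mV  (closed form -44.2)
onset voltage     : -55.3 mV
end voltage       : -57.9 mV
```

The fitted leak slope recovers the model's true input conductance to
well under 1%; the measured amplitude sits slightly below the
closed-form value because the PIC activates with a 0.25 s time constant
and lags the 5 mV/s ramp — the same kinetic hysteresis that separates
the ascending and descending limbs of real recordings.

The other `examples/` scripts each exercise one capability: single-cell
simulation, F-I analysis, effect sizes, and a full cohort report. A thin
CLI wraps the same calls:

```
picquant simulate --seed 1 --out cohort/
picquant extract cohort/* --mode both --out features.json
picquant report --seed 1 --out report/
```

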