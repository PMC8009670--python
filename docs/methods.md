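# Methods

`picquant` reimplements, as a tested library, the analysis chain used in
in vivo intracellular studies of spinal motoneuron excitability in the
SOD1(G93A) mouse model of ALS: quantification of persistent inward
currents (PICs) from slow triangular voltage-clamp ramps, of
frequency–current (F-I) properties from triangular current-clamp ramps,
assembly of a canonical 21-feature per-cell table, and an
estimation-statistics layer (Hedges' *g* with BCa bootstrap intervals,
Welch's *t*, regressions against age, ANCOVA, PCA). A conductance-based
synthetic motoneuron provides ground truth for every stage, so the whole
chain is testable without any recorded data.

Units everywhere: mV, nA, µS, nF, s, Hz. With these units conductance is
nA/mV, so the slope of the leak fit *is* the input conductance.

## Voltage-clamp measurement chain

A triangular voltage command (−80 → −40 → −80 mV at 5 mV/s) is split at
its apex into an ascending and a descending limb (median-filtered
command; baseline and any apex plateau belong to neither limb). On each
limb the passive leak is an OLS line through the subthreshold window of
the I–V relation, by default −80 to −65 mV; its slope is the input
conductance G_in and its intercept absorbs the constant capacitive
current ±C·dV/dt of that limb. After subtracting the line:

* **PIC amplitude** — magnitude of the minimum of the subtracted current,
  smoothed by a moving average spanning 0.5 mV of command (a 5 mV/s ramp
  sampled at 10 kHz has 2000 samples per mV; a raw argmin would chase
  noise). Ties resolve to the earliest ascending / latest descending
  sample.
* **PIC peak voltage** — commanded voltage at that minimum, per limb.
* **Onset / end voltage** — the published definition is visual ("where
  the trace visibly deviates downward"), operationalised as the first
  ascending voltage where the smoothed subtracted current stays below
  −max(k·σ, floor) over a 1 mV stretch (defaults k = 3, floor = 0.05 nA);
  the end voltage applies the mirrored rule on the descending limb. σ is
  a high-frequency noise estimate (SD of first differences over the fit
  window divided by √2) rather than the OLS residual SD: active current
  reaching into the window inflates the residuals with smooth curvature
  that has nothing to do with recording noise and would push the
  detected onset systematically late.

A known property of this (standard) method: any PIC activation that
extends into the leak window biases the fitted slope and is partially
absorbed into the "leak". The closed-form ground truth therefore reports
two amplitudes — the true minimum of the non-leak current, and the
minimum after subtracting an exactly-fitted window line
(`amplitude_leakfit`). The latter is what a perfect noiseless analysis
of a trace recovers; the difference is the method's own bias, about
0.01 nA for the default cell and growing for PICs that activate close
to the window.

## Current-clamp measurement chain

Spikes are upward crossings of dV/dt through 10 mV/ms (smoothed first
difference over 0.2 ms) confirmed by a voltage peak ≥ 20 mV above the
crossing within 2 ms, with a 2 ms refractory period; sampling below
5 kHz is rejected as too coarse for the criterion. The crossing voltage
of the first spike is the voltage threshold. Recruitment and
de-recruitment currents are the injected currents at the first and last
spike; ΔI is their difference, and ΔF the difference between the
instantaneous frequency of the last and first interspike interval
(undefined below 3 spikes).

Instantaneous frequency (1/ISI) is plotted against the current at the
interspike midpoint — the midpoint minimises the bias a ramping command
would otherwise introduce — separately per limb (limb assignment by the
command apex time).

Mouse motoneurons fire in a steep, variable subprimary range (SPR)
before settling into a linear primary range (PR). The published PR
identification is visual (walk from the ramp apex backward until the
relation stops being linear); the deterministic surrogate grows a window
from the apex outward while (a) the residual SD of a running linear fit
stays below max(c1·σ_apex, c2) and (b) the local slope over the newest
few points stays within a factor c3 of the apex-window slope (defaults
c1 = 2, c2 = 3 Hz, c3 = 2, apex window 6 points, local window 4). The
transition is reported at the last accepted point — the PR boundary — so
a perfectly linear series yields a PR covering the whole limb with the
transition at its lowest-current point. The F-I gain is the OLS slope
over the PR points only, per limb.

A cell is **non-firing** when its ramp evokes at most 4 spikes while a
current step (when recorded) still evokes at least one; such cells keep
their voltage-clamp features but all F-I features are missing.

RMP is the mean voltage over the pre-ramp baseline (≥ 0.5 s); "unstable
RMP" is operationalised as a peak-to-peak excursion of the 50 ms-smoothed
baseline above 2 mV. QC excludes cells with RMP more depolarized than
−50 mV (a cell at exactly −50.0 mV is kept). Age groups are half-open:
<60 d (P30–P60), 60–89 d (P60–P90), ≥90 d (P90–P120).

## Estimation statistics

Hedges' *g* is the pooled-SD standardized mean difference of group 2
minus group 1 times the exact gamma-ratio small-sample correction
J(df) = Γ(df/2)/(√(df/2)·Γ((df−1)/2)); the familiar 1 − 3/(4·df − 1)
approximation is available and agrees to 3 decimals for df ≥ 10. The
95% CI is a bias-corrected and accelerated (BCa) bootstrap over
independent per-group resampling, 5000 resamples by default
(`scipy.stats.bootstrap` is the engine; a Monte-Carlo coverage test over
500 replicate experiments at n = (19, 15) checks 93–97% empirical
coverage). Welch's *t* is reported as (mean1 − mean2)/SE with both the
Welch–Satterthwaite df and the pooled df n1 + n2 − 2; reference reports
label the statistic with the pooled df, so both are emitted.

Regressions against age use OLS with age in weeks and a t-based 95% CI
on the slope. The ANCOVA fits `PIC amplitude ~ conductance * genotype`
with the covariate mean-centred; when the interaction is not significant
at α = 0.05 the additive model is refit and the genotype effect (group
difference at fixed conductance) reported with its CI. Centring matters
only in the rare runs where the interaction is kept: it makes the
genotype coefficient the group difference at the mean conductance rather
than an extrapolation to zero conductance, which restores nominal CI
coverage of a planted offset.

PCA standardizes the 21 features (ddof 1), keeps complete-case rows
(dropped count logged), retains 5 components and reports per-feature ×
component Pearson correlations as loadings; explained-variance ratios
are taken over the total variance of all features, so they sum to 1 only
when all components are retained.

## Synthetic motoneuron

The model's steady-state current is

    I(V) = g_leak (V − E_rest) + g_pic·m∞(V)(V − E_pic) + g_out·n∞(V)(V − E_out)

with logistic (Boltzmann) activations m∞ and n∞. The single lumped
inward conductance stands in for the Na/Ca PIC components (only their
summed deflection is ever measured); the opposing outward conductance
(V_half −35 mV, k 5 mV, E −85 mV) creates the interior negative peak of
the leak-subtracted I–V between roughly −55 and −40 mV. PIC activation
follows first-order kinetics with τ_pic (default 0.25 s; 0 =
instantaneous), producing ascending/descending hysteresis under the
5 mV/s ramp. Defaults for the PIC activation are V_half −48 mV and
k 2.75 mV: the slope is chosen steep enough that the activation tail is
genuinely closed below −65 mV, keeping the default cell's leak-window
contamination inside the tolerances quoted above (a broader slope of
~4 mV biases the fitted conductance by >1% and the measured amplitude by
~0.16 nA, which would conflate method bias with extraction error).

Voltage-clamp responses are the closed form plus the capacitive ramp
current and white Gaussian current noise (default SD 0.1 nA);
noiseless instantaneous simulation reproduces the closed form to
machine precision, which is the root oracle of the test suite.

Current clamp integrates an exponential-Euler integrate-and-fire riding
on the same currents. At threshold a stereotyped action potential
(half-cosine rise to +50 mV overshoot in 0.4 ms, fall to the reset in
0.6 ms) is inserted into the trace so the downstream dV/dt detector
operates exactly as on real recordings; the PIC keeps activating during
the waveform, which drives the firing hysteresis (ΔI < 0 for strong
slow PICs). Two spike-triggered adaptation components shape the F-I
relation: a fast one (1.0 nA, τ 50 ms) that sets the primary-range gain
and keeps the approach to threshold steep (and spike timing regular),
and a slow one (0.015 nA, τ 4 s) that accumulates over the ascending
limb and is quasi-frozen on the descending limb — which is what makes
descending gains steeper than ascending ones, as observed. Membrane
noise is an OU-like voltage perturbation with stationary SD 0.1 mV; its
jitter is amplified near recruitment (shallow approach to threshold)
and small near the apex, which is precisely the subprimary/primary
variability contrast. The quasi-static rheobase — the maximum of the
steady-state I(V) between rest and threshold, found by brute force on a
0.01 mV grid — is the oracle for recruitment.

### Cohort sampling

Cohorts are drawn per genotype × age group from truncated-normal
marginals with a Gaussian copula correlating input conductance and PIC
amplitude (default ρ = 0.74, which reproduces the published
PIC-vs-conductance coupling of r² ≈ 0.55 in young adults). The factory
in `picquant.reference` is parameterised directly by the published group
summaries (conductance, PIC amplitude, RMP, spiking threshold *relative
to RMP*, PIC onset). Because the analysis chain itself has method
biases, per-cell parameters are found by inverting the chain rather than
set naively: g_pic and V_half are calibrated by brute-force closed-form
search so the *measured* amplitude and onset hit the drawn targets;
g_leak is corrected for the leak-window contamination so the *measured*
conductance is centred on the draw; E_rest is shifted so the
zero-current resting equilibrium (the measured RMP) lands on the draw.
The current ramp is sized per cell as rheobase + 4 nA, the way an
experimenter sizes it at the rig; planted non-firing cells get a barely
suprathreshold ramp (1.03 × rheobase), a near-zero PIC and an additional
suprathreshold step sweep. Everything is reproducible bit-for-bit from
one seed.

### What the generator does and does not emulate

It reproduces: the linear leak, the N-shaped leak-subtracted I–V with
hysteresis, ramp-evoked firing with an SPR/PR structure and plausible
gains, asc/desc concordances strictly between 0 and 1, cohort-level
means of conductance, PIC amplitude, RMP, threshold and SPR/PR
transition frequency close to the published group values, and the
published direction of every group contrast. It does **not** model PIC
inactivation, mixed-mode oscillations, dendritic compartments or
electrode artifacts. Two fidelity limits follow from the
non-inactivating Boltzmann PIC and are worth knowing when reading
simulated cohorts: onset targets much deeper than ≈ −64 mV compress
toward that value (a midpoint sunk into the leak-fit window is absorbed
by the leak line, so the calibration refuses to go there), and simulated
recruitment currents run somewhat above the published means for the
strong-PIC mutant groups. Passing cohort tests therefore demonstrate
that the *extraction chain* recovers what the model generates and that
group contrasts keep their published sign and rough size — not that the
model is a complete biophysical account of the recorded cells.

## Problem sizes and numerical choices

Parameter-recovery studies use 200 voltage-clamp-only cells with
instantaneous PIC kinetics (the recovery oracle is the steady state) and
onsets drawn in [−61, −54] mV so the activation is closed below the
leak window by construction, with amplitudes truncated at 0.5 nA so
relative errors are meaningful. Bootstrap calibration uses 500 replicate
experiments at the published young-adult group sizes (19, 15) with 5000
resamples each. End-to-end pipeline tests run 5–8 cells per genotype
with a few hundred resamples. Brute-force searches use a 0.01 mV grid;
voltage-clamp simulation defaults to 10 kHz and current clamp to 5 kHz
in cohorts (10 kHz for single-cell studies). The tolerance for the
"symmetric noiseless cell de-recruits where it recruited" property is
one F-I sample — ramp speed × interspike interval — because an
integrate-and-fire neuron near rheobase necessarily overshoots
de-recruitment by the current traversed during the final interval; no
continuous-time neuron model can satisfy a one-ADC-sample version of
that identity.

## Known limitations

* The recorded-data dialects are generic (CSV + JSON sidecar, HDF5);
  vendor formats are out of scope.
* The optional re-analysis of the original deposited dataset (age
  regressions, PCA variance fractions, ANCOVA statistics, asc/desc r²)
  is supported through the same feature-table API but requires that
  download; no network access is assumed anywhere in the package.
* Effect-size comparisons across many features are reported without
  multiple-testing correction, matching the estimation-statistics
  reporting style the package follows.
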