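"""Published reference summaries for in vivo mouse spinal motoneuron
cohorts (SOD1(G93A) mutants vs wild-type littermates) and cohort
factories that emulate them.

These group summary statistics (mean, SD, n) are inputs to two things:

* the anchored effect-size computations (Hedges' g from printed group
  moments), and
* the synthetic cohort generator, whose per-group parameter
  distributions are matched to the corresponding cohort so that
  extracted feature tables resemble the reference study's Table-style
  summaries.

Age groups: P30-P60 (young adult, presymptomatic), P60-P90 (substantial
denervation, no overt symptoms), P90-P120 (symptomatic).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

from .synth import GroupSpec, SimCohortSpec

__all__ = [
    "GROUP_SUMMARIES",
    "ANCHOR_COMPARISONS",
    "reference_cohort_spec",
    "recovery_cohort_spec",
]

# (mean, sd, n) per feature, genotype and age group
GROUP_SUMMARIES: Dict[str, Dict[Tuple[str, str], Tuple[float, float, int]]] = {
    "input_conductance": {  # uS
        ("WT", "P30-P60"): (0.42, 0.16, 19),
        ("mSOD1", "P30-P60"): (0.72, 0.18, 15),
        ("WT", "P60-P90"): (0.46, 0.16, 16),
        ("mSOD1", "P60-P90"): (0.42, 0.15, 24),
        ("WT", "P90-P120"): (0.60, 0.15, 15),
        ("mSOD1", "P90-P120"): (0.33, 0.13, 14),
    },
    "pic_amplitude_asc": {  # nA
        ("WT", "P30-P60"): (2.30, 2.17, 19),
        ("mSOD1", "P30-P60"): (6.73, 3.28, 15),
        ("WT", "P60-P90"): (2.47, 1.69, 16),
        ("mSOD1", "P60-P90"): (2.75, 2.40, 24),
        ("WT", "P90-P120"): (4.12, 3.69, 15),
        ("mSOD1", "P90-P120"): (1.90, 1.78, 14),
    },
    "rmp": {  # mV
        ("WT", "P30-P60"): (-62.38, 5.52, 19),
        ("mSOD1", "P30-P60"): (-71.45, 8.78, 15),
        ("WT", "P60-P90"): (-60.98, 5.35, 16),
        ("mSOD1", "P60-P90"): (-66.18, 5.63, 24),
        ("WT", "P90-P120"): (-64.71, 7.42, 15),
        ("mSOD1", "P90-P120"): (-61.99, 5.43, 14),
    },
    "vthreshold": {  # mV
        ("WT", "P30-P60"): (-45.35, 5.48, 19),
        ("mSOD1", "P30-P60"): (-54.86, 5.15, 14),
        ("WT", "P60-P90"): (-45.39, 7.04, 16),
        ("mSOD1", "P60-P90"): (-47.53, 5.85, 24),
        ("WT", "P90-P120"): (-47.61, 5.00, 15),
        ("mSOD1", "P90-P120"): (-48.20, 5.41, 14),
    },
    "vthreshold_rel_rmp": {  # mV
        ("WT", "P30-P60"): (17.03, 6.37, 19),
        ("mSOD1", "P30-P60"): (18.09, 5.21, 15),
        ("WT", "P60-P90"): (15.59, 5.54, 16),
        ("mSOD1", "P60-P90"): (19.26, 6.29, 24),
        ("WT", "P90-P120"): (17.10, 5.54, 15),
        ("mSOD1", "P90-P120"): (13.79, 3.62, 14),
    },
    "pic_onset_voltage": {  # mV
        ("WT", "P30-P60"): (-58.03, 6.35, 19),
        ("mSOD1", "P30-P60"): (-69.41, 5.71, 15),
        ("WT", "P60-P90"): (-59.22, 4.88, 16),
        ("mSOD1", "P60-P90"): (-59.66, 6.39, 24),
        ("WT", "P90-P120"): (-63.15, 6.31, 15),
        ("mSOD1", "P90-P120"): (-60.12, 7.25, 14),
    },
    "recruitment_current": {  # nA
        ("WT", "P30-P60"): (4.73, 3.14, 19),
        ("mSOD1", "P30-P60"): (6.21, 2.51, 14),
        ("WT", "P60-P90"): (5.28, 2.64, 16),
        ("mSOD1", "P60-P90"): (4.53, 3.38, 20),
        ("WT", "P90-P120"): (5.43, 3.07, 15),
        ("mSOD1", "P90-P120"): (2.19, 1.56, 13),
    },
}

#: anchored two-group comparisons: (mean1, sd1, n1, mean2, sd2, n2);
#: group order matches the published convention (g standardizes
#: mean2 - mean1).
ANCHOR_COMPARISONS: Dict[str, Tuple[float, float, int, float, float, int]] = {
    # WT vs mSOD1, P30-P60
    "pic_amplitude_p30_p60": (2.30, 2.17, 19, 6.73, 3.28, 15),
    "input_conductance_p30_p60": (0.42, 0.16, 19, 0.72, 0.18, 15),
    "vthreshold_p30_p60": (-45.35, 5.48, 19, -54.86, 5.15, 14),
    "rmp_p30_p60": (-62.38, 5.52, 19, -71.45, 8.78, 15),
    "pic_onset_voltage_p30_p60": (-58.03, 6.35, 19, -69.41, 5.71, 15),
    # WT vs mSOD1, P90-P120
    "recruitment_current_p90_p120": (5.43, 3.07, 15, 2.19, 1.56, 13),
    "rmp_p90_p120": (-64.71, 7.42, 15, -61.99, 5.43, 13),
    # repetitively-firing vs non-firing motoneurons (all ages)
    "nonfiring_pic_amplitude": (4.04, 3.18, 47, 0.60, 0.49, 6),
}

_AGE_RANGES = {"P30-P60": (31, 59), "P60-P90": (60, 89), "P90-P120": (90, 123)}


def reference_cohort_spec(
    age_groups: Tuple[str, ...] = ("P30-P60",),
    n_per_group: Optional[int] = None,
    n_nonfiring: int = 0,
    rho: float = 0.74,
    seed: int = 0,
    include_cc: bool = True,
) -> SimCohortSpec:
    """Cohort spec whose per-group distributions match the reference
    study: conductance, PIC amplitude, RMP, spiking threshold and PIC
    onset are drawn around the published group means/SDs.

    ``n_per_group`` overrides the published cell counts (e.g. to scale a
    simulation down); ``rho`` is the conductance-PIC copula correlation,
    defaulting to the value that reproduces the published
    PIC-vs-conductance coupling (r^2 about 0.55 in the young group).
    """
    groups = {}
    for age_group in age_groups:
        for genotype in ("WT", "mSOD1"):
            key = (genotype, age_group)
            g_mean, g_sd, n = GROUP_SUMMARIES["input_conductance"][key]
            a_mean, a_sd, _ = GROUP_SUMMARIES["pic_amplitude_asc"][key]
            r_mean, r_sd, _ = GROUP_SUMMARIES["rmp"][key]
            t_mean, t_sd, _ = GROUP_SUMMARIES["vthreshold_rel_rmp"][key]
            o_mean, o_sd, _ = GROUP_SUMMARIES["pic_onset_voltage"][key]
            groups[key] = GroupSpec(
                n=n_per_group if n_per_group is not None else n,
                g_leak=(g_mean, g_sd),
                pic_amplitude=(a_mean, a_sd),
                rmp=(r_mean, r_sd),
                v_threshold_rel=(t_mean, t_sd),
                pic_onset=(o_mean, o_sd),
                rho=rho,
                n_nonfiring=n_nonfiring,
                age_range=_AGE_RANGES[age_group],
            )
    return SimCohortSpec(groups=groups, seed=seed, include_cc=include_cc)


def recovery_cohort_spec(
    n: int = 200, noise_sd_vc: float = 0.0, seed: int = 0
) -> SimCohortSpec:
    """Voltage-clamp-only cohort for parameter-recovery studies.

    Wild-type-like parameter ranges with the PIC activation kept clear of
    the leak-fit window, and amplitudes truncated away from zero so that
    relative errors are meaningful.  ``noise_sd_vc`` sets the recording
    noise (nA); 0 gives the noiseless recovery conditions.
    """
    group = GroupSpec(
        n=n,
        g_leak=(0.45, 0.12),
        pic_amplitude=(2.5, 1.5),
        rmp=(-62.0, 4.0),
        v_threshold_rel=(17.0, 3.0),
        pic_onset=(-58.0, 2.0),
        rho=0.74,
        age_range=(31, 59),
        pic_amplitude_min=0.5,
        pic_onset_min=-61.0,
        pic_onset_max=-54.0,
    )
    return SimCohortSpec(
        groups={("WT", "P30-P60"): group},
        include_cc=False,
        noise_sd_vc=noise_sd_vc,
        tau_pic=0.0,
        seed=seed,
    )
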