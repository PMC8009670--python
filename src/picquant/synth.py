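"""Conductance-based synthetic motoneuron: ramp responses with ground truth.

The model lumps the persistent inward current (PIC) into a single
Boltzmann-activated inward conductance and opposes it with a
Boltzmann-activated outward conductance, so that the leak-subtracted
current-voltage relation is N-shaped with an interior negative peak
between roughly -55 and -40 mV, as seen in slow-voltage-ramp recordings
of spinal motoneurons.  Repetitive firing under current ramps is produced
by integrate-and-fire dynamics riding on the same currents, with a
spike-triggered adaptation current and a stereotyped action-potential
waveform inserted at each spike so that downstream dV/dt-based detection
operates exactly as on real traces.

Steady-state total current (also the quasi-static current-clamp balance)::

    I(V) = g_leak (V - E_rest) + g_pic m_inf(V) (V - E_pic)
                               + g_out n_inf(V) (V - E_out)

with ``m_inf``/``n_inf`` logistic (Boltzmann) activation curves.  Units:
mV, nA, uS, nF, s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal, stats

from .types import CC, VC, CellRecord, RampSpec, StepSpec, TraceSweep, ValidationError

__all__ = [
    "SimCellParams",
    "GroupSpec",
    "SimCohortSpec",
    "steady_state_current",
    "nonleak_current",
    "pic_ground_truth",
    "rheobase",
    "simulate_vclamp_ramp",
    "simulate_cclamp_ramp",
    "simulate_cclamp_step",
    "sample_cohort",
    "calibrate_pic",
]

# voltage grid used for all brute-force ground-truth searches (mV)
_GRID_LO, _GRID_HI, _GRID_STEP = -80.0, -40.0, 0.01

# default leak-fit window; must match the analysis default
_LEAK_WINDOW = (-80.0, -65.0)

# stereotyped action potential: rise/fall duration and overshoot height
_AP_RISE_S = 0.4e-3
_AP_FALL_S = 0.6e-3
_AP_HEIGHT_MV = 50.0


@dataclass(frozen=True)
class SimCellParams:
    """Biophysical parameters of one synthetic motoneuron.

    Conductances in uS, voltages in mV, capacitance in nF, times in s.
    ``tau_pic = 0`` makes PIC activation instantaneous.  ``noise_sd_vc``
    is a current noise (nA) added to voltage-clamp responses;
    ``noise_sd_cc`` is the stationary SD (mV) of membrane-voltage noise
    in current clamp.
    """

    g_leak: float = 0.42
    E_rest: float = -62.0
    C: float = 1.7
    g_pic: float = 0.045
    V_half_pic: float = -48.0
    k_pic: float = 2.75
    E_pic: float = 30.0
    tau_pic: float = 0.25
    g_out: float = 0.0675
    V_half_out: float = -35.0
    k_out: float = 5.0
    E_out: float = -85.0
    spike_threshold: float = -45.0
    V_reset: float = -55.0
    adapt_increment: float = 1.0
    tau_adapt: float = 0.05
    adapt_slow_increment: float = 0.015
    tau_adapt_slow: float = 4.0
    noise_sd_vc: float = 0.1
    noise_sd_cc: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("g_leak", "g_pic", "g_out"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.k_pic <= 0 or self.k_out <= 0:
            raise ValidationError("activation slopes k_pic, k_out must be > 0")
        if not (self.E_pic > self.spike_threshold > self.E_rest > self.E_out):
            raise ValidationError(
                "require E_pic > spike_threshold > E_rest > E_out "
                f"(got {self.E_pic}, {self.spike_threshold}, {self.E_rest}, {self.E_out})"
            )
        if self.C <= 0:
            raise ValidationError("C must be > 0")


def _boltzmann(V, v_half, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - v_half) / k))


def nonleak_current(params: SimCellParams, V):
    """Active (non-leak) part of the steady-state current, in nA."""
    V = np.asarray(V, dtype=float)
    m = _boltzmann(V, params.V_half_pic, params.k_pic)
    n = _boltzmann(V, params.V_half_out, params.k_out)
    return params.g_pic * m * (V - params.E_pic) + params.g_out * n * (V - params.E_out)


def steady_state_current(params: SimCellParams, V):
    """Closed-form steady-state clamp current at voltage ``V`` (nA).

    This is the deterministic ground truth for every voltage-clamp
    measurement; its non-leak part is the true leak-subtracted current.
    """
    V = np.asarray(V, dtype=float)
    out = params.g_leak * (V - params.E_rest) + nonleak_current(params, V)
    return float(out) if out.ndim == 0 else out


def _grid() -> np.ndarray:
    n = int(round((_GRID_HI - _GRID_LO) / _GRID_STEP)) + 1
    return np.linspace(_GRID_LO, _GRID_HI, n)


def pic_ground_truth(params: SimCellParams, leak_window: Tuple[float, float] = _LEAK_WINDOW) -> Dict[str, float]:
    """Brute-force PIC features of the closed-form model on a 0.01 mV grid.

    Two amplitude definitions are reported:

    ``amplitude_true``
        magnitude of the minimum of the non-leak current itself;

    ``amplitude_leakfit``
        magnitude of the minimum after subtracting an OLS line fitted to
        the *total* steady-state current over ``leak_window`` -- i.e. the
        exact measurement definition applied to the closed form.  The two
        differ by the (small) contamination of the leak window by active
        currents; the second is what a perfect, noiseless analysis of a
        trace recovers.
    """
    V = _grid()
    active = nonleak_current(params, V)
    i_min = int(np.argmin(active))
    mask = (V >= leak_window[0]) & (V <= leak_window[1])
    total = params.g_leak * (V - params.E_rest) + active
    slope, intercept = np.polyfit(V[mask], total[mask], 1)
    sub = total - (slope * V + intercept)
    j_min = int(np.argmin(sub))
    return {
        "amplitude_true": max(0.0, -float(active[i_min])),
        "peak_voltage_true": float(V[i_min]),
        "amplitude_leakfit": max(0.0, -float(sub[j_min])),
        "peak_voltage_leakfit": float(V[j_min]),
        "leakfit_slope": float(slope),
        "g_in_true": params.g_leak,
        "rheobase": rheobase(params),
    }


def resting_potential(params: SimCellParams) -> float:
    """Zero-current resting equilibrium: the most hyperpolarized root of
    I(V) = 0 below spike threshold (brute force).  With active currents
    present at rest this sits slightly above E_rest."""
    n = int(round((params.spike_threshold - params.E_rest + 10.0) / 0.01)) + 1
    V = np.linspace(params.E_rest - 10.0, params.spike_threshold, max(n, 2))
    I = steady_state_current(params, V)
    sign_change = np.flatnonzero((I[:-1] <= 0) & (I[1:] > 0))
    if sign_change.size == 0:
        return params.E_rest
    i = int(sign_change[0])
    # linear interpolation of the crossing
    f = I[i] / (I[i] - I[i + 1])
    return float(V[i] + f * (V[i + 1] - V[i]))


def rheobase(params: SimCellParams) -> float:
    """Smallest ramp current that forces V past spike threshold.

    Under a slow ramp the membrane tracks the stable quasi-static
    equilibrium, which disappears once the injected current exceeds the
    maximum of the steady-state I(V) over [E_rest, spike_threshold];
    evaluated by brute force on a 0.01 mV grid.
    """
    n = int(round((params.spike_threshold - params.E_rest) / 0.01)) + 1
    V = np.linspace(params.E_rest, params.spike_threshold, max(n, 2))
    return float(np.max(steady_state_current(params, V)))


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def triangular_command(ramp: RampSpec, sampling_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    """Time base and triangular command for ``ramp`` at ``sampling_rate``."""
    dt = 1.0 / sampling_rate
    n = int(round(ramp.total_duration * sampling_rate)) + 1
    t = np.arange(n) * dt
    cmd = np.full(n, ramp.start_level, dtype=float)
    t0 = ramp.baseline_duration
    t1 = t0 + ramp.ramp_duration
    up = (t >= t0) & (t < t1)
    down = t >= t1
    cmd[up] = ramp.start_level + ramp.speed * (t[up] - t0)
    cmd[down] = np.maximum(
        ramp.peak_level - ramp.speed * (t[down] - t1), ramp.start_level
    )
    return t, cmd


def step_command(step: StepSpec, sampling_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / sampling_rate
    total = step.baseline_duration + step.duration + 0.2
    n = int(round(total * sampling_rate)) + 1
    t = np.arange(n) * dt
    cmd = np.full(n, step.start_level, dtype=float)
    on = (t >= step.baseline_duration) & (t < step.baseline_duration + step.duration)
    cmd[on] = step.start_level + step.amplitude
    return t, cmd


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def simulate_vclamp_ramp(
    params: SimCellParams,
    ramp: RampSpec,
    sampling_rate: float = 10000.0,
    rng: Optional[np.random.Generator] = None,
) -> TraceSweep:
    """Clamp current in response to a triangular voltage ramp.

    With ``tau_pic > 0`` the PIC activation follows first-order kinetics
    toward its Boltzmann steady state, producing hysteresis between the
    ascending and descending limbs.  A capacitive current C dV/dt rides
    on the ramp (constant, opposite sign per limb), as in real ramps; the
    per-limb leak fit absorbs it into the intercept.
    """
    if sampling_rate < 100:
        raise ValidationError("voltage-clamp simulation needs sampling_rate >= 100 Hz")
    t, V = triangular_command(ramp, sampling_rate)
    dt = 1.0 / sampling_rate
    m_inf = _boltzmann(V, params.V_half_pic, params.k_pic)
    if params.tau_pic > 0:
        a = math.exp(-dt / params.tau_pic)
        m, _ = signal.lfilter([1.0 - a], [1.0, -a], m_inf, zi=[a * m_inf[0]])
    else:
        m = m_inf
    n_act = _boltzmann(V, params.V_half_out, params.k_out)
    I = (
        params.g_leak * (V - params.E_rest)
        + params.g_pic * m * (V - params.E_pic)
        + params.g_out * n_act * (V - params.E_out)
        + params.C * np.gradient(V, dt) / 1000.0
    )
    if params.noise_sd_vc > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        I = I + rng.normal(0.0, params.noise_sd_vc, I.size)
    return TraceSweep(
        time=t, command=V, response=I, mode=VC,
        sampling_rate=sampling_rate, protocol=ramp,
    )


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------

def _ap_waveform(v_start: float, v_reset: float, sampling_rate: float) -> np.ndarray:
    """Stereotyped spike: half-cosine rise to overshoot, fall to reset."""
    n_rise = max(2, int(round(_AP_RISE_S * sampling_rate)))
    n_fall = max(2, int(round(_AP_FALL_S * sampling_rate)))
    peak = v_start + _AP_HEIGHT_MV
    up = v_start + (peak - v_start) * 0.5 * (1 - np.cos(np.pi * np.arange(1, n_rise + 1) / n_rise))
    down = v_reset + (peak - v_reset) * 0.5 * (1 + np.cos(np.pi * np.arange(1, n_fall + 1) / n_fall))
    return np.concatenate([up, down])


def _integrate_cc(
    params: SimCellParams,
    t: np.ndarray,
    inj: np.ndarray,
    sampling_rate: float,
    rng: Optional[np.random.Generator],
) -> Tuple[np.ndarray, list]:
    """Exponential-Euler integrate-and-fire with AP insertion.

    Returns the voltage trace and the list of spike (threshold-crossing)
    times.  Conductances are frozen within each step, which makes the
    subthreshold update exact for piecewise-constant inputs.
    """
    dt = 1.0 / sampling_rate
    n = t.size
    V = np.empty(n)
    exp = math.exp
    v = resting_potential(params)
    V[0] = v
    m = 1.0 / (1.0 + exp(-(v - params.V_half_pic) / params.k_pic))
    alpha_pic = 1.0 - exp(-dt / params.tau_pic) if params.tau_pic > 0 else 1.0
    decay_w = exp(-dt / params.tau_adapt) if params.tau_adapt > 0 else 0.0
    decay_ws = exp(-dt / params.tau_adapt_slow) if params.tau_adapt_slow > 0 else 0.0
    w = 0.0
    ws = 0.0
    noise = None
    if params.noise_sd_cc > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        tau_m = params.C / params.g_leak / 1000.0  # s
        sigma_step = params.noise_sd_cc * math.sqrt(2.0 * dt / tau_m)
        noise = rng.normal(0.0, sigma_step, n)
    spike_times: list = []
    g_leak, E_rest = params.g_leak, params.E_rest
    g_pic, E_pic = params.g_pic, params.E_pic
    g_out, E_out = params.g_out, params.E_out
    vh_p, k_p = params.V_half_pic, params.k_pic
    vh_o, k_o = params.V_half_out, params.k_out
    C = params.C
    thr, v_reset = params.spike_threshold, params.V_reset
    i = 1
    while i < n:
        m_inf = 1.0 / (1.0 + exp(-(v - vh_p) / k_p))
        m += (m_inf - m) * alpha_pic
        n_inf = 1.0 / (1.0 + exp(-(v - vh_o) / k_o))
        g_tot = g_leak + g_pic * m + g_out * n_inf
        E_eff = (
            g_leak * E_rest + g_pic * m * E_pic + g_out * n_inf * E_out
            + inj[i] - w - ws
        ) / g_tot
        v = E_eff + (v - E_eff) * exp(-dt * 1000.0 * g_tot / C)
        if noise is not None:
            v += noise[i]
        w *= decay_w
        ws *= decay_ws
        if v >= thr:
            spike_times.append(t[i])
            wave = _ap_waveform(thr, v_reset, sampling_rate)
            j_end = min(n, i + 1 + wave.size)
            V[i] = thr
            V[i + 1 : j_end] = wave[: j_end - i - 1]
            # PIC keeps activating during the spike; adaptation steps up
            for vv in wave[: j_end - i - 1]:
                m_inf = 1.0 / (1.0 + exp(-(vv - vh_p) / k_p))
                m += (m_inf - m) * alpha_pic
                w *= decay_w
                ws *= decay_ws
            w += params.adapt_increment
            ws += params.adapt_slow_increment
            v = v_reset
            i = j_end
            continue
        V[i] = v
        i += 1
    return V, spike_times


def simulate_cclamp_ramp(
    params: SimCellParams,
    ramp: RampSpec,
    sampling_rate: float = 10000.0,
    rng: Optional[np.random.Generator] = None,
) -> TraceSweep:
    """Membrane voltage in response to a triangular current ramp.

    Raises on sampling rates below 5 kHz: the inserted AP waveform would
    be too coarse for dV/dt-based spike detection downstream.
    """
    if sampling_rate < 5000:
        raise ValidationError(
            "current-clamp simulation needs sampling_rate >= 5 kHz "
            "(AP waveform and dV/dt criterion unreliable below that)"
        )
    t, inj = triangular_command(ramp, sampling_rate)
    V, spike_times = _integrate_cc(params, t, inj, sampling_rate, rng)
    return TraceSweep(
        time=t, command=inj, response=V, mode=CC,
        sampling_rate=sampling_rate, protocol=ramp,
        meta={"spike_times": spike_times, "effective_threshold": params.spike_threshold},
    )


def simulate_cclamp_step(
    params: SimCellParams,
    step: StepSpec,
    sampling_rate: float = 10000.0,
    rng: Optional[np.random.Generator] = None,
) -> TraceSweep:
    """Membrane voltage in response to a square current pulse."""
    if sampling_rate < 5000:
        raise ValidationError("current-clamp simulation needs sampling_rate >= 5 kHz")
    t, inj = step_command(step, sampling_rate)
    V, spike_times = _integrate_cc(params, t, inj, sampling_rate, rng)
    return TraceSweep(
        time=t, command=inj, response=V, mode=CC,
        sampling_rate=sampling_rate, protocol=step,
        meta={"spike_times": spike_times, "effective_threshold": params.spike_threshold},
    )


# ---------------------------------------------------------------------------
# PIC calibration and cohort sampling
# ---------------------------------------------------------------------------

_GOUT_RATIO = 1.5  # g_out/g_pic, fixed so the N-shape scales with the PIC

def _unit_amplitude(base: SimCellParams, v_half: float) -> float:
    """Leak-fit-subtracted amplitude per unit g_pic (g_out co-scaled)."""
    probe = replace(base, g_pic=1.0, g_out=_GOUT_RATIO, V_half_pic=v_half)
    return pic_ground_truth(probe)["amplitude_leakfit"]


def _chain_onset(
    base: SimCellParams, g_pic: float, v_half: float, floor: float,
    leak_window: Tuple[float, float] = _LEAK_WINDOW,
) -> float:
    """Onset voltage the measurement chain reports for the closed form:
    first grid voltage where the line-subtracted active current stays
    below ``-floor`` over 1 mV.  The leak line partially absorbs active
    current reaching into the fit window, so this sits above a naive
    activation-tail estimate.  NaN when the criterion is never met."""
    probe = replace(base, g_pic=g_pic, g_out=_GOUT_RATIO * g_pic, V_half_pic=v_half)
    V = _grid()
    active = nonleak_current(probe, V)
    mask = (V >= leak_window[0]) & (V <= leak_window[1])
    slope, intercept = np.polyfit(V[mask], active[mask], 1)
    sub = active - (slope * V + intercept)
    below = sub < -floor
    n_w = max(1, int(round(1.0 / _GRID_STEP)))
    csum = np.concatenate([[0], np.cumsum(below.astype(np.int64))])
    wsum = csum[n_w:] - csum[:-n_w]
    idx = np.flatnonzero(wsum == n_w)
    if idx.size == 0:
        return float("nan")
    return float(V[idx[0]])


def calibrate_pic(
    base: SimCellParams,
    target_amplitude: float,
    target_onset: float,
    onset_floor: float = 0.05,
) -> Tuple[float, float]:
    """Invert (g_pic, V_half_pic) from a target PIC amplitude and onset.

    The amplitude target is the leak-fit-subtracted amplitude a noiseless
    analysis measures; since the active currents scale linearly with
    g_pic (g_out held at a fixed ratio), the inversion of g_pic is a
    division.  V_half is then placed so the subtracted current reaches
    the onset-detection floor at ``target_onset``; the two equations are
    iterated to a joint fixed point.
    """
    if target_amplitude < 0.02:
        return 0.0, target_onset + 12.0
    # v_half is confined: above -42 the deflection peak leaves the ramp
    # range; below -64 the activation is swallowed by the leak-fit window
    # and the calibration degenerates.  Onset targets outside the
    # attainable range compress to its edge; the amplitude target wins.
    v_lo, v_hi = -64.0, -42.0
    v_half = min(max(target_onset + 10.0, v_lo), v_hi)
    g_pic = target_amplitude / _unit_amplitude(base, v_half)
    for _ in range(3):
        # bisect v_half so the chain-measured onset hits the target
        lo, hi = v_lo, v_hi
        ons_lo = _chain_onset(base, g_pic, lo, onset_floor)
        ons_hi = _chain_onset(base, g_pic, hi, onset_floor)
        if math.isnan(ons_lo) or ons_lo >= target_onset:
            # target deeper than attainable: for a large PIC the deep edge
            # compresses least badly, but for a small PIC sinking the
            # midpoint into the leak window buys nothing -- compare a
            # neutral midpoint and keep whichever onset lands closer
            neutral = min(max(target_onset + 8.0, lo), hi)
            ons_n = _chain_onset(base, g_pic, neutral, onset_floor)
            d_lo = abs(ons_lo - target_onset) if not math.isnan(ons_lo) else math.inf
            d_n = abs(ons_n - target_onset) if not math.isnan(ons_n) else math.inf
            v_half = lo if d_lo < d_n else neutral
        elif math.isnan(ons_hi) or ons_hi <= target_onset:
            v_half = hi
        else:
            for _ in range(24):
                mid = 0.5 * (lo + hi)
                ons = _chain_onset(base, g_pic, mid, onset_floor)
                if math.isnan(ons) or ons > target_onset:
                    hi = mid
                else:
                    lo = mid
            v_half = 0.5 * (lo + hi)
        g_new = target_amplitude / _unit_amplitude(base, v_half)
        converged = abs(g_new - g_pic) < 1e-4
        g_pic = g_new
        if converged:
            break
    return min(g_pic, 1.0), v_half


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution of one genotype x age-group cell population.

    ``(mean, sd)`` pairs; conductance in uS, PIC amplitude in nA (the
    amplitude a noiseless analysis of the cell measures), voltages in mV.
    ``rho`` is the Gaussian-copula correlation between input conductance
    and PIC amplitude.  ``n_nonfiring`` of the ``n`` cells are planted as
    non-firing: near-zero PIC and a ramp that barely crosses rheobase,
    with an additional suprathreshold step sweep.
    """

    n: int
    g_leak: Tuple[float, float]
    pic_amplitude: Tuple[float, float]
    rmp: Tuple[float, float]
    v_threshold_rel: Tuple[float, float]
    pic_onset: Tuple[float, float]
    rho: float = 0.74
    n_nonfiring: int = 0
    age_range: Tuple[int, int] = (31, 59)
    #: lower truncation of the amplitude draw (nA); raise for recovery
    #: studies where near-zero PICs make relative errors meaningless
    pic_amplitude_min: float = 0.0
    #: truncation of the onset draw (mV): raise the lower bound to keep
    #: the PIC activation clear of the leak-fit window, lower the upper
    #: bound to keep the deflection peak well inside the ramp range
    pic_onset_min: float = -76.0
    pic_onset_max: float = -45.0

    def __post_init__(self) -> None:
        if self.n < 0 or self.n_nonfiring < 0 or self.n_nonfiring > self.n:
            raise ValidationError("need 0 <= n_nonfiring <= n")
        if abs(self.rho) > 1:
            raise ValidationError("|rho| must be <= 1")
        for nm in ("g_leak", "pic_amplitude", "rmp", "v_threshold_rel", "pic_onset"):
            if getattr(self, nm)[1] < 0:
                raise ValidationError(f"{nm} SD must be >= 0")


@dataclass
class SimCohortSpec:
    """Cohort layout: one GroupSpec per (genotype, age_group).

    ``vc_rate``/``cc_rate`` are the simulated sampling rates; current
    clamp may be disabled (``include_cc=False``) for voltage-clamp-only
    studies such as parameter-recovery experiments.
    """

    groups: Dict[Tuple[str, str], GroupSpec] = field(default_factory=dict)
    vc_rate: float = 10000.0
    cc_rate: float = 5000.0
    include_cc: bool = True
    noise_sd_vc: float = 0.1
    noise_sd_cc: float = 0.1
    tau_pic: float = 0.25
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "groups"}
        d["groups"] = [
            {"genotype": g, "age_group": a, **asdict(spec)}
            for (g, a), spec in self.groups.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimCohortSpec":
        d = dict(d)
        groups = {}
        for entry in d.pop("groups", []):
            entry = dict(entry)
            key = (entry.pop("genotype"), entry.pop("age_group"))
            for nm in ("g_leak", "pic_amplitude", "rmp", "v_threshold_rel", "pic_onset", "age_range"):
                if nm in entry:
                    entry[nm] = tuple(entry[nm])
            groups[key] = GroupSpec(**entry)
        return cls(groups=groups, **d)


def _trunc_ppf(u, mean, sd, lower=-np.inf, upper=np.inf):
    if sd == 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_cohort(spec: SimCohortSpec, seed: Optional[int] = None) -> list:
    """Draw a cohort of CellRecords, each with one VC ramp, one CC ramp
    (unless disabled) and a ground-truth sidecar.  Fully determined by
    the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cells = []
    vc_ramp = RampSpec(start_level=-80.0, peak_level=-40.0, speed=5.0, baseline_duration=1.0)
    for (genotype, age_group), g in sorted(spec.groups.items()):
        if g.n == 0:
            continue
        cov = np.array([[1.0, g.rho], [g.rho, 1.0]])
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"infeasible correlation rho={g.rho}") from exc
        z = rng.standard_normal((g.n, 2)) @ chol.T
        u = stats.norm.cdf(z)
        g_leaks = _trunc_ppf(u[:, 0], *g.g_leak, lower=0.05)
        amps = _trunc_ppf(u[:, 1], *g.pic_amplitude, lower=max(0.0, g.pic_amplitude_min))
        # RMP draws live between the outward reversal and the QC cutoff
        rmps = _trunc_ppf(rng.uniform(size=g.n), *g.rmp, lower=-80.0, upper=-51.0)
        vth_rels = _trunc_ppf(rng.uniform(size=g.n), *g.v_threshold_rel, lower=5.0)
        onsets = _trunc_ppf(
            rng.uniform(size=g.n), *g.pic_onset,
            lower=max(-76.0, g.pic_onset_min), upper=min(-45.0, g.pic_onset_max),
        )
        ages = rng.integers(g.age_range[0], g.age_range[1] + 1, size=g.n)
        nonfiring_idx = set(range(g.n - g.n_nonfiring, g.n))
        for i in range(g.n):
            cell_id = f"{genotype}_{age_group}_{i:03d}"
            animal_id = f"{genotype}_{age_group}_m{i // 3:02d}"
            nonfiring = i in nonfiring_idx
            e_rest = float(rmps[i])
            vth = e_rest + float(vth_rels[i])
            amp = 0.2 * float(amps[i]) if nonfiring else float(amps[i])
            base = SimCellParams(
                g_leak=float(g_leaks[i]),
                E_rest=e_rest,
                C=4.0 * float(g_leaks[i]),
                spike_threshold=vth,
                V_reset=vth - 10.0,
                tau_pic=spec.tau_pic,
                noise_sd_vc=spec.noise_sd_vc,
                noise_sd_cc=spec.noise_sd_cc,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            # the onset-detection threshold downstream scales with the
            # recording noise; calibrate against the same effective floor
            floor = max(3.0 * spec.noise_sd_vc, 0.05)
            g_pic, v_half = calibrate_pic(base, amp, float(onsets[i]), onset_floor=floor)
            params = replace(
                base, g_pic=g_pic, g_out=_GOUT_RATIO * g_pic, V_half_pic=v_half
            )
            # active currents reaching into the leak-fit window bias the
            # fitted slope; compensate g_leak so the *measured* input
            # conductance is centred on the drawn value
            bias = pic_ground_truth(params)["leakfit_slope"] - params.g_leak
            bias = float(np.clip(bias, -0.5 * params.g_leak, 0.5 * params.g_leak))
            g_adj = max(params.g_leak - bias, 0.05)
            params = replace(params, g_leak=g_adj, C=4.0 * g_adj)
            # active currents at rest pull the zero-current equilibrium off
            # E_rest; shift E_rest so the measured RMP lands on the draw
            for _ in range(8):
                delta = resting_potential(params) - e_rest
                if abs(delta) < 0.1:
                    break
                new_e = min(max(params.E_rest - delta, params.E_out + 5.0), vth - 5.0)
                params = replace(params, E_rest=new_e)
            # a cohort cell must not be spontaneously active at rest:
            # shift activation up, then shrink the PIC, until a positive
            # rheobase margin exists
            for _ in range(30):
                if rheobase(params) >= 0.3:
                    break
                if params.V_half_pic < -42.0:
                    params = replace(params, V_half_pic=params.V_half_pic + 1.0)
                else:
                    params = replace(
                        params,
                        g_pic=0.8 * params.g_pic,
                        g_out=0.8 * params.g_out,
                    )
            truth = pic_ground_truth(params)
            truth.update(
                target_amplitude=amp,
                target_onset=float(onsets[i]),
                nonfiring=nonfiring,
                params=asdict(params),
            )
            cell_rng = np.random.default_rng(params.seed)
            sweeps = [simulate_vclamp_ramp(params, vc_ramp, spec.vc_rate, rng=cell_rng)]
            if spec.include_cc:
                rheo = truth["rheobase"]
                # the ramp is sized per cell, as at the rig: far enough past
                # rheobase to develop a primary range, without driving small
                # cells to unphysiological rates
                peak = 1.03 * rheo if nonfiring else rheo + 4.0
                cc_ramp = RampSpec(
                    start_level=0.0, peak_level=peak, speed=peak / 4.0,
                    baseline_duration=1.0,
                )
                cc = simulate_cclamp_ramp(params, cc_ramp, spec.cc_rate, rng=cell_rng)
                truth["cc_spike_times"] = list(cc.meta["spike_times"])
                sweeps.append(cc)
                if nonfiring:
                    step = StepSpec(start_level=0.0, amplitude=1.3 * rheo, duration=0.5)
                    sweeps.append(
                        simulate_cclamp_step(params, step, spec.cc_rate, rng=cell_rng)
                    )
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    animal_id=animal_id,
                    genotype=genotype,
                    age_days=int(ages[i]),
                    sweeps=sweeps,
                    truth=truth,
                )
            )
    return cells
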