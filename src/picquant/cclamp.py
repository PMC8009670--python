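"""Current-clamp measurement chain: spike detection, voltage threshold,
recruitment/de-recruitment, instantaneous F-I curves, subprimary/primary
range segmentation, gains and firing classification.

Spikes are detected by an upward crossing of dV/dt through 10 mV/ms
(smoothed first difference), confirmed by a voltage peak at least 20 mV
above the crossing voltage within 2 ms.  The voltage at the dV/dt
crossing of the first spike is the voltage threshold for spiking.

The firing regime of mouse motoneurons splits into a subprimary range
(SPR: steep, highly variable firing just after recruitment) followed by
a linear primary range (PR).  The PR is identified deterministically by
walking from the ramp apex backward and growing a window while a running
linear fit stays tight and the local slope stays comparable to the
apex-window slope; the F-I gain is the OLS slope over the PR points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .types import CC, ProtocolError, TraceSweep, ValidationError

__all__ = [
    "SpikeTrain",
    "FIMeasure",
    "FISeries",
    "PRSegment",
    "SpikeConfig",
    "SprPrConfig",
    "detect_spikes",
    "recruitment_measures",
    "instantaneous_fi",
    "segment_spr_pr",
    "fi_gain",
    "classify_firing",
    "extract_cclamp",
    "REPETITIVE",
    "NON_FIRING",
]

log = logging.getLogger("picquant.cclamp")

REPETITIVE = "repetitive"
NON_FIRING = "non_firing"

# a ramp that evokes at most this many spikes marks a non-firing cell
NONFIRING_MAX_SPIKES = 4


@dataclass(frozen=True)
class SpikeConfig:
    dvdt_threshold: float = 10.0  # mV/ms
    dvdt_smooth_s: float = 0.2e-3
    peak_window_s: float = 2.0e-3
    min_peak_height: float = 20.0  # mV above crossing voltage
    refractory_s: float = 2.0e-3


@dataclass(frozen=True)
class SprPrConfig:
    """Constants of the deterministic SPR/PR changepoint rule.

    The PR window grows from the apex while the residual SD of a running
    linear fit stays below ``max(c1 * sd_apex, c2)`` (Hz) and the local
    slope over the ``local_points`` newest points stays within a factor
    ``c3`` of the apex-window slope.
    """

    c1: float = 2.0
    c2: float = 3.0  # Hz
    c3: float = 2.0
    apex_points: int = 6
    local_points: int = 4


@dataclass
class SpikeTrain:
    """Detected spikes of one sweep: threshold-crossing times (s),
    voltages at the crossing (mV) and AP peak voltages (mV)."""

    spike_times: np.ndarray
    threshold_crossing_voltages: np.ndarray
    peak_voltages: np.ndarray

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class FISeries:
    """Instantaneous frequency-current points of one ramp limb: one point
    per adjacent spike pair, current taken at the interspike midpoint."""

    current: np.ndarray
    frequency: np.ndarray
    limb: str


@dataclass
class PRSegment:
    transition_current: float
    transition_frequency: float
    pr_indices: np.ndarray  # indices into the FISeries, time order


@dataclass
class FIMeasure:
    """Frequency-current features of one cell.  All fields except
    ``firing_class`` are NaN for non-firing cells."""

    recruitment_current: float = float("nan")
    derecruitment_current: float = float("nan")
    delta_i: float = float("nan")
    v_threshold: float = float("nan")
    spr_pr_transition_current: float = float("nan")
    spr_pr_transition_frequency: float = float("nan")
    gain_asc: float = float("nan")
    gain_desc: float = float("nan")
    delta_f: float = float("nan")
    firing_class: str = REPETITIVE


def detect_spikes(sweep: TraceSweep, config: SpikeConfig = SpikeConfig()) -> SpikeTrain:
    """dV/dt-criterion spike detection on a CC sweep.

    A spike is an upward crossing of the smoothed dV/dt through the
    threshold, followed within 2 ms by a voltage peak at least 20 mV
    above the crossing voltage; crossings within the refractory period of
    an accepted spike are ignored.
    """
    if sweep.mode != CC:
        raise ProtocolError("detect_spikes requires a CC sweep")
    fs = sweep.sampling_rate
    if fs < 5000:
        raise ValidationError(
            "spike detection needs sampling_rate >= 5 kHz for a reliable dV/dt criterion"
        )
    V = sweep.response
    n_sm = max(1, int(round(config.dvdt_smooth_s * fs)))
    v_sm = uniform_filter1d(V, size=n_sm, mode="nearest") if n_sm > 1 else V
    dvdt = np.gradient(v_sm) * fs / 1000.0  # mV/ms
    thr = config.dvdt_threshold
    crossings = np.flatnonzero((dvdt[:-1] < thr) & (dvdt[1:] >= thr))
    n_peak = max(1, int(round(config.peak_window_s * fs)))
    n_refr = max(1, int(round(config.refractory_s * fs)))
    times, v_cross, v_peak = [], [], []
    last = -10 * n_refr
    for i in crossings:
        if i - last < n_refr:
            continue
        seg = V[i : min(i + n_peak + 1, V.size)]
        if seg.size == 0:
            continue
        pk = float(seg.max())
        if pk >= V[i] + config.min_peak_height:
            times.append(sweep.time[i])
            v_cross.append(V[i])
            v_peak.append(pk)
            last = i
    return SpikeTrain(
        spike_times=np.asarray(times),
        threshold_crossing_voltages=np.asarray(v_cross),
        peak_voltages=np.asarray(v_peak),
    )


def _command_at(sweep: TraceSweep, t: np.ndarray) -> np.ndarray:
    return np.interp(t, sweep.time, sweep.command)


def recruitment_measures(sweep: TraceSweep, train: SpikeTrain) -> dict:
    """Recruitment/de-recruitment currents, their difference, voltage
    threshold, and the de-recruitment minus recruitment frequency
    difference (first/last interspike interval; NaN below 3 spikes)."""
    if len(train) == 0:
        return {
            "recruitment_current": float("nan"),
            "derecruitment_current": float("nan"),
            "delta_i": float("nan"),
            "v_threshold": float("nan"),
            "delta_f": float("nan"),
        }
    i_rec = float(_command_at(sweep, train.spike_times[:1])[0])
    i_derec = float(_command_at(sweep, train.spike_times[-1:])[0])
    delta_f = float("nan")
    if len(train) >= 3:
        isi = np.diff(train.spike_times)
        delta_f = float(1.0 / isi[-1] - 1.0 / isi[0])
    return {
        "recruitment_current": i_rec,
        "derecruitment_current": i_derec,
        "delta_i": i_derec - i_rec,
        "v_threshold": float(train.threshold_crossing_voltages[0]),
        "delta_f": delta_f,
    }


def _apex_time(sweep: TraceSweep) -> float:
    k = max(3, int(round(0.005 * sweep.sampling_rate)) | 1)
    sm = median_filter(sweep.command, size=min(k, sweep.command.size), mode="nearest")
    return float(sweep.time[int(np.argmax(sm))])


def instantaneous_fi(
    sweep: TraceSweep, train: SpikeTrain
) -> Tuple[FISeries, FISeries]:
    """Instantaneous frequency vs injected current, split by ramp limb.

    One point per adjacent spike pair whose two spikes fall on the same
    limb; the current is interpolated at the interspike midpoint, which
    minimises the bias the ramping current would otherwise introduce.
    Limbs with fewer than 3 spikes give empty series.
    """
    t_apex = _apex_time(sweep)
    out = []
    for limb in ("asc", "desc"):
        if limb == "asc":
            sel = train.spike_times <= t_apex
        else:
            sel = train.spike_times > t_apex
        ts = train.spike_times[sel]
        if ts.size < 3:
            out.append(FISeries(np.empty(0), np.empty(0), limb))
            continue
        mid = 0.5 * (ts[:-1] + ts[1:])
        isi = np.diff(ts)
        out.append(FISeries(_command_at(sweep, mid), 1.0 / isi, limb))
    return out[0], out[1]


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sd = float(np.sqrt(np.sum(resid**2) / max(x.size - 2, 1)))
    return float(slope), float(intercept), sd


def segment_spr_pr(
    fi: FISeries, config: SprPrConfig = SprPrConfig()
) -> Optional[PRSegment]:
    """Deterministic surrogate for the visual PR identification.

    Points are ordered apex-first and the PR window grown outward while
    the running fit stays tight (see :class:`SprPrConfig`).  The
    transition is reported at the last accepted point -- the boundary of
    the PR -- so a perfectly linear series yields a PR covering the whole
    limb with the transition at its first (lowest-current) point.
    Returns None when no stable apex window exists (PR undefined).
    """
    n = fi.current.size
    if n < config.apex_points:
        return None
    # order points from the apex outward: ascending limb points arrive in
    # time order ending at the apex; descending ones start at the apex
    if fi.limb == "asc":
        order = np.arange(n)[::-1]
    else:
        order = np.arange(n)
    I = fi.current[order]
    F = fi.frequency[order]
    w = config.apex_points
    slope0, _, sd0 = _ols(I[:w], F[:w])
    # the apex window itself must be a credible linear stretch
    if sd0 > 3.0 * config.c2:
        return None
    thr_sd = max(config.c1 * sd0, config.c2)
    k = w
    while k < n:
        _, _, sd = _ols(I[: k + 1], F[: k + 1])
        m = config.local_points
        local_slope, _, _ = _ols(I[k + 1 - m : k + 1], F[k + 1 - m : k + 1])
        if sd > thr_sd or abs(local_slope) > config.c3 * max(abs(slope0), 1e-9):
            break
        k += 1
    pr = order[:k]
    boundary = pr[-1]
    return PRSegment(
        transition_current=float(fi.current[boundary]),
        transition_frequency=float(fi.frequency[boundary]),
        pr_indices=np.sort(pr),
    )


def fi_gain(fi: FISeries, pr: Optional[PRSegment]) -> float:
    """OLS slope (Hz/nA) of the F-I relation over the PR points only."""
    if pr is None or pr.pr_indices.size < 4:
        return float("nan")
    slope, _, _ = _ols(fi.current[pr.pr_indices], fi.frequency[pr.pr_indices])
    return slope


def classify_firing(
    ramp_train: SpikeTrain, step_train: Optional[SpikeTrain] = None
) -> str:
    """Non-firing: at most a few spikes to the ramp while still spiking
    to a current step (when a step sweep exists)."""
    if len(ramp_train) > NONFIRING_MAX_SPIKES:
        return REPETITIVE
    if step_train is not None and len(step_train) == 0:
        return REPETITIVE
    return NON_FIRING


def extract_cclamp(
    sweep: TraceSweep,
    step_sweep: Optional[TraceSweep] = None,
    spike_config: SpikeConfig = SpikeConfig(),
    sprpr_config: SprPrConfig = SprPrConfig(),
) -> FIMeasure:
    """Full chain on one CC ramp (plus optional step): detection,
    recruitment measures, F-I segmentation and gains."""
    if sweep.mode != CC:
        raise ProtocolError("extract_cclamp requires a CC sweep")
    train = detect_spikes(sweep, spike_config)
    step_train = detect_spikes(step_sweep, spike_config) if step_sweep is not None else None
    firing_class = classify_firing(train, step_train)
    if firing_class == NON_FIRING:
        return FIMeasure(firing_class=NON_FIRING)
    rec = recruitment_measures(sweep, train)
    fi_asc, fi_desc = instantaneous_fi(sweep, train)
    pr_asc = segment_spr_pr(fi_asc, sprpr_config) if fi_asc.current.size >= sprpr_config.apex_points else None
    pr_desc = segment_spr_pr(fi_desc, sprpr_config) if fi_desc.current.size >= sprpr_config.apex_points else None
    trans_i = trans_f = float("nan")
    if pr_asc is not None:
        trans_i = pr_asc.transition_current
        trans_f = pr_asc.transition_frequency
    return FIMeasure(
        recruitment_current=rec["recruitment_current"],
        derecruitment_current=rec["derecruitment_current"],
        delta_i=rec["delta_i"],
        v_threshold=rec["v_threshold"],
        spr_pr_transition_current=trans_i,
        spr_pr_transition_frequency=trans_f,
        gain_asc=fi_gain(fi_asc, pr_asc),
        gain_desc=fi_gain(fi_desc, pr_desc),
        delta_f=rec["delta_f"],
        firing_class=REPETITIVE,
    )
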