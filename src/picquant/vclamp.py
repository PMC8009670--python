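"""Voltage-clamp measurement chain: limb splitting, leak fit, leak
subtraction and PIC feature extraction.

The persistent inward current (PIC) is quantified on slow triangular
voltage ramps.  The passive leak is estimated by ordinary least squares
over a subthreshold window of the current-voltage relation (default -80
to -65 mV); its slope is the input conductance G_in (uS).  After
subtracting the fitted line, the PIC appears as a downward deflection
whose magnitude, peak voltage, onset voltage (ascending limb) and end
voltage (descending limb) are measured per limb.

Because the deflection's "visible departure from the horizontal" is a
judgement call on real traces, onset is operationalised as the first
ascending voltage at which the smoothed subtracted current stays below
``-max(k * residual_sd, floor)`` over a sustained voltage width; the end
voltage applies the mirrored rule on the descending limb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .types import ProtocolError, TraceSweep, VC

__all__ = [
    "LeakFit",
    "PICMeasure",
    "PICConfig",
    "RampLimb",
    "split_ramp",
    "fit_leak",
    "subtract_leak",
    "measure_pic",
    "extract_vclamp",
    "InsufficientDataError",
]

log = logging.getLogger("picquant.vclamp")


class InsufficientDataError(ValueError):
    """Too few samples to perform a fit."""


@dataclass(frozen=True)
class PICConfig:
    """Tunable constants of the PIC measurement chain.

    ``onset_k`` scales the leak-fit residual SD into a detection
    threshold, with an absolute ``onset_floor`` (nA) so noiseless traces
    do not trigger on numerical dust; the criterion must hold over
    ``onset_width_mv`` of command voltage.  ``smooth_mv`` is the
    moving-average window (in command mV) applied before the extremum
    search: slow ramps put thousands of samples per mV and a raw argmin
    would chase noise.
    """

    leak_window: Tuple[float, float] = (-80.0, -65.0)
    smooth_mv: float = 0.5
    onset_k: float = 3.0
    onset_floor: float = 0.05
    onset_width_mv: float = 1.0


@dataclass(frozen=True)
class LeakFit:
    """OLS line through the subthreshold I-V window.

    ``slope`` is the input conductance in uS (= nA/mV); the intercept
    absorbs any constant capacitive offset of the limb.
    """

    slope: float
    intercept: float
    window: Tuple[float, float]
    residual_sd: float
    n_points: int

    def predict(self, V):
        return self.slope * np.asarray(V, dtype=float) + self.intercept


@dataclass
class RampLimb:
    """One monotonic limb of a triangular sweep (command/response/time)."""

    command: np.ndarray
    response: np.ndarray
    time: np.ndarray
    limb: str  # "asc" | "desc"

    def __len__(self) -> int:
        return self.command.size


@dataclass
class LeakSubtracted:
    """Leak-subtracted current series of one limb, as I (nA) vs V (mV)."""

    voltage: np.ndarray
    current: np.ndarray
    limb: str
    fit: LeakFit


@dataclass
class PICMeasure:
    """PIC features of one cell's voltage-clamp ramp.

    Amplitudes are magnitudes (>= 0) of the maximal downward deflection
    of the leak-subtracted trace; voltages are commanded voltages.
    ``onset_voltage`` (ascending) or ``end_voltage`` (descending) is NaN
    when the deflection never clears the detection threshold.
    """

    amplitude_asc: float
    amplitude_desc: float
    peak_voltage_asc: float
    peak_voltage_desc: float
    onset_voltage: float
    end_voltage: float
    leak_fit: LeakFit
    leak_fit_desc: Optional[LeakFit] = None


def split_ramp(sweep: TraceSweep) -> Tuple[RampLimb, RampLimb]:
    """Split a triangular sweep at the command apex.

    The command is median-filtered before locating the apex; baseline
    samples before/after the ramp and any plateau at the peak are
    assigned to neither limb, so each limb is strictly monotonic in the
    denoised command.
    """
    cmd = sweep.command
    n = cmd.size
    k = max(3, int(round(0.005 * sweep.sampling_rate)) | 1)  # ~5 ms, odd
    sm = median_filter(cmd, size=min(k, n), mode="nearest")
    hi = sm.max()
    lo = sm.min()
    if hi - lo <= 0:
        raise ProtocolError("command is constant; not a triangular ramp")
    tol = max(2.0 * float(np.median(np.abs(np.diff(sm)))), 1e-9 * (hi - lo))
    at_top = np.flatnonzero(sm >= hi - tol)
    apex_first, apex_last = int(at_top[0]), int(at_top[-1])
    if apex_first < 2 or apex_last > n - 3:
        raise ProtocolError("command apex at the edge; not a triangular ramp")
    # trim flat baseline at start/end
    rising = np.flatnonzero(sm[: apex_first + 1] > lo + tol)
    start = max(int(rising[0]) - 1, 0) if rising.size else 0
    falling = np.flatnonzero(sm[apex_last:] > lo + tol)
    end = apex_last + int(falling[-1]) + 1 if falling.size else n - 1
    end = min(end + 1, n - 1)
    asc = slice(start, apex_first)
    desc = slice(apex_last + 1, end + 1)
    if asc.stop - asc.start < 2 or desc.stop - desc.start < 2:
        raise ProtocolError("could not isolate two monotonic limbs")
    if np.any(np.diff(sm[asc]) < -tol) or np.any(np.diff(sm[desc]) > tol):
        raise ProtocolError("command limbs are not monotonic; not a triangular ramp")
    return (
        RampLimb(cmd[asc], sweep.response[asc], sweep.time[asc], "asc"),
        RampLimb(cmd[desc], sweep.response[desc], sweep.time[desc], "desc"),
    )


def fit_leak(limb: RampLimb, window: Tuple[float, float] = (-80.0, -65.0)) -> LeakFit:
    """OLS regression of response on command over the voltage ``window``."""
    lo, hi = min(window), max(window)
    mask = (limb.command >= lo) & (limb.command <= hi)
    n_pts = int(mask.sum())
    if n_pts < 10:
        raise InsufficientDataError(
            f"leak fit needs >= 10 samples in [{lo}, {hi}] mV; found {n_pts}"
        )
    x = limb.command[mask]
    y = limb.response[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / max(n_pts - 2, 1)))
    return LeakFit(
        slope=float(slope),
        intercept=float(intercept),
        window=(lo, hi),
        residual_sd=residual_sd,
        n_points=n_pts,
    )


def subtract_leak(limb: RampLimb, fit: LeakFit) -> LeakSubtracted:
    """Remove the fitted linear leak from a limb's current."""
    return LeakSubtracted(
        voltage=limb.command,
        current=limb.response - fit.predict(limb.command),
        limb=limb.limb,
        fit=fit,
    )


def _smooth(sub: LeakSubtracted, smooth_mv: float) -> np.ndarray:
    dv = float(np.median(np.abs(np.diff(sub.voltage))))
    if dv <= 0:
        return sub.current
    size = max(1, int(round(smooth_mv / dv)))
    if size <= 1:
        return sub.current
    return uniform_filter1d(sub.current, size=size, mode="nearest")


def _noise_sd(sub: LeakSubtracted) -> float:
    """High-frequency noise SD of the subtracted current over the fit
    window, from first differences.  Unlike the OLS residual SD this is
    not inflated by any smooth active-current curvature that leaks into
    the window, so the onset threshold tracks the recording noise."""
    lo, hi = sub.fit.window
    y = sub.current[(sub.voltage >= lo) & (sub.voltage <= hi)]
    if y.size < 3:
        return sub.fit.residual_sd
    return float(np.std(np.diff(y)) / np.sqrt(2.0))


def _sustained_onset(
    voltage: np.ndarray, below: np.ndarray, width_mv: float
) -> float:
    """First voltage (in array order) from which ``below`` holds over
    ``width_mv`` of command.  NaN if never."""
    dv = float(np.median(np.abs(np.diff(voltage)))) if voltage.size > 1 else 0.0
    n_w = max(1, int(round(width_mv / dv))) if dv > 0 else 1
    if below.size < n_w:
        return float("nan")
    # forward window sum: sustained means all n_w samples from i onward hold
    csum = np.concatenate([[0], np.cumsum(below.astype(np.int64))])
    wsum = csum[n_w:] - csum[:-n_w]
    idx = np.flatnonzero(wsum == n_w)
    if idx.size == 0:
        return float("nan")
    return float(voltage[idx[0]])


def measure_pic(
    asc_sub: LeakSubtracted,
    desc_sub: LeakSubtracted,
    config: PICConfig = PICConfig(),
) -> PICMeasure:
    """Extract PIC amplitude/peak/onset/end from both leak-subtracted limbs.

    Amplitude is the magnitude of the minimum of the smoothed subtracted
    current (per limb); the peak voltage is the command at that minimum
    (ties: earliest ascending / latest descending sample).  Onset is the
    first ascending voltage where the trace stays below the detection
    threshold over the configured width; end voltage is the mirrored
    quantity on the descending limb.  A trace that never clears the
    threshold has no onset/end (NaN) but still reports its maximal
    deflection as amplitude.
    """
    s_asc = _smooth(asc_sub, config.smooth_mv)
    s_desc = _smooth(desc_sub, config.smooth_mv)

    i_asc = int(np.argmin(s_asc))  # first occurrence = earliest ascending
    rev = s_desc[::-1]
    i_desc = len(s_desc) - 1 - int(np.argmin(rev))  # last occurrence in time

    thr_asc = max(config.onset_k * _noise_sd(asc_sub), config.onset_floor)
    thr_desc = max(config.onset_k * _noise_sd(desc_sub), config.onset_floor)

    onset = _sustained_onset(
        asc_sub.voltage, s_asc < -thr_asc, config.onset_width_mv
    )
    # descending limb runs from apex to hyperpolarised: reverse so the
    # search runs from the hyperpolarised end, mirroring the onset rule
    end = _sustained_onset(
        desc_sub.voltage[::-1], (s_desc < -thr_desc)[::-1], config.onset_width_mv
    )
    if not np.isnan(onset):
        log.debug("PIC onset at %.2f mV", onset)
    return PICMeasure(
        amplitude_asc=max(0.0, -float(s_asc[i_asc])),
        amplitude_desc=max(0.0, -float(s_desc[i_desc])),
        peak_voltage_asc=float(asc_sub.voltage[i_asc]),
        peak_voltage_desc=float(desc_sub.voltage[i_desc]),
        onset_voltage=onset,
        end_voltage=end,
        leak_fit=asc_sub.fit,
        leak_fit_desc=desc_sub.fit,
    )


def extract_vclamp(sweep: TraceSweep, config: PICConfig = PICConfig()) -> PICMeasure:
    """Full chain on one VC ramp sweep: split, per-limb leak fit,
    subtraction, PIC measurement.

    Each limb gets its own leak fit so the constant capacitive offset
    (opposite sign per limb) is absorbed per limb.
    """
    if sweep.mode != VC:
        raise ProtocolError("extract_vclamp requires a VC sweep")
    asc, desc = split_ramp(sweep)
    fit_a = fit_leak(asc, config.leak_window)
    fit_d = fit_leak(desc, config.leak_window)
    return measure_pic(
        subtract_leak(asc, fit_a), subtract_leak(desc, fit_d), config
    )
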