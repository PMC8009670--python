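"""Core in-memory containers for intracellular ramp recordings.

Canonical units throughout the package: millivolts (mV), nanoamperes (nA),
seconds (s), hertz (Hz), microsiemens (uS) and nanofarads (nF).  With these
units conductance is nA/mV, so the slope of a leak current fit is an input
conductance with no further conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

__all__ = [
    "VC",
    "CC",
    "RampSpec",
    "StepSpec",
    "TraceSweep",
    "CellRecord",
    "ProtocolError",
    "ValidationError",
]

VC = "VC"
CC = "CC"

_GENOTYPES = ("WT", "mSOD1")

# relative tolerance between declared sampling rate and 1/median(dt)
_RATE_RTOL = 1e-3


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


class ProtocolError(ValueError):
    """A sweep does not follow the protocol an operation requires."""


@dataclass(frozen=True)
class RampSpec:
    """Triangular command: hold at ``start_level``, ramp to ``peak_level``
    at ``speed`` and back down at the same speed.

    Units are mV and mV/s in voltage clamp, nA and nA/s in current clamp.
    """

    start_level: float
    peak_level: float
    speed: float
    baseline_duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.peak_level > self.start_level:
            raise ValidationError("RampSpec requires peak_level > start_level")
        if not self.speed > 0:
            raise ValidationError("RampSpec requires speed > 0")
        if self.baseline_duration < 0:
            raise ValidationError("baseline_duration must be >= 0")

    @property
    def ramp_duration(self) -> float:
        """Duration of one limb, in seconds."""
        return (self.peak_level - self.start_level) / self.speed

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + 2.0 * self.ramp_duration


@dataclass(frozen=True)
class StepSpec:
    """Square command pulse on top of ``start_level``."""

    start_level: float
    amplitude: float
    duration: float
    baseline_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("StepSpec duration must be > 0")
        if self.baseline_duration < 0:
            raise ValidationError("baseline_duration must be >= 0")


ProtocolSpec = Union[RampSpec, StepSpec]


@dataclass
class TraceSweep:
    """One protocol's time/command/response series.

    In VC mode the command is a voltage (mV) and the response a current
    (nA); in CC mode the command is a current (nA) and the response a
    voltage (mV).
    """

    time: np.ndarray
    command: np.ndarray
    response: np.ndarray
    mode: str
    sampling_rate: float
    protocol: Optional[ProtocolSpec] = None
    #: free-form annotations (e.g. simulator ground truth); not persisted
    meta: Optional[dict] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValidationError("sweep needs at least 2 samples")
        if self.command.size != n or self.response.size != n:
            raise ValidationError(
                "time, command and response must have equal length "
                f"(got {n}, {self.command.size}, {self.response.size})"
            )
        if self.mode not in (VC, CC):
            raise ValidationError(f"mode must be 'VC' or 'CC', got {self.mode!r}")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        rate = 1.0 / float(np.median(dt))
        if abs(rate - self.sampling_rate) > _RATE_RTOL * self.sampling_rate:
            raise ValidationError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with "
                f"median time step ({rate:.6g} Hz)"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


@dataclass
class CellRecord:
    """All sweeps recorded from one motoneuron, plus its metadata.

    ``rmp`` is the resting membrane potential measured on the current-clamp
    baseline; it is ``None`` until extraction fills it in.  ``truth`` is an
    optional ground-truth sidecar attached by the simulator (simulated
    cells only); it never exists for real recordings.
    """

    cell_id: str
    animal_id: str
    genotype: str
    age_days: int
    sweeps: list = field(default_factory=list)
    rmp: Optional[float] = None
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.genotype not in _GENOTYPES:
            raise ValidationError(
                f"genotype must be one of {_GENOTYPES}, got {self.genotype!r}"
            )
        if not (isinstance(self.age_days, (int, np.integer)) and self.age_days > 0):
            raise ValidationError("age_days must be a positive integer")
        self.age_days = int(self.age_days)

    def _sweeps(self, mode: str, spec_type) -> list:
        return [
            s
            for s in self.sweeps
            if s.mode == mode and (spec_type is None or isinstance(s.protocol, spec_type))
        ]

    def vc_ramps(self) -> list:
        return self._sweeps(VC, RampSpec)

    def cc_ramps(self) -> list:
        return self._sweeps(CC, RampSpec)

    def cc_steps(self) -> list:
        return self._sweeps(CC, StepSpec)

    def protocol_dict(self) -> dict:
        return {s.mode: s.protocol for s in self.sweeps}


def protocol_to_dict(protocol: Optional[ProtocolSpec]) -> Optional[dict]:
    """JSON-friendly form of a protocol spec (round-trips through
    :func:`protocol_from_dict`)."""
    if protocol is None:
        return None
    d = asdict(protocol)
    d["kind"] = "ramp" if isinstance(protocol, RampSpec) else "step"
    return d


def protocol_from_dict(d: Optional[dict]) -> Optional[ProtocolSpec]:
    if d is None:
        return None
    d = dict(d)
    kind = d.pop("kind", "ramp")
    if kind == "ramp":
        return RampSpec(**d)
    if kind == "step":
        return StepSpec(**d)
    raise ValidationError(f"unknown protocol kind {kind!r}")
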