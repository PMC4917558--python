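"""Transient unisensory input signals.

Each stimulus (visual or auditory) is reduced to a four-dimensional,
time-varying signal: an *existence* bit that is 1 exactly while the stimulus
is physically present, a *reliability* in [0, 1], and the eye-centered
spherical position angles (ech, ecv). Positions and reliability are
piecewise constant over the presentation window; outside the window the
signal is the zero vector.

Angles are given in degrees at the interface (stimulus specifications,
config files, trace output) and converted to radians internally, where all
trigonometry operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeGrid",
    "StimulusSpec",
    "SignalSample",
    "ZERO_SAMPLE",
    "make_time_grid",
    "stimulus_signal",
]


class InvalidParameterError(ValueError):
    """A scalar argument violates its domain (non-positive step, etc.)."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation grid from ``t_start`` to ``t_end`` with step ``dt``."""

    t_start: float
    t_end: float
    dt: float

    @property
    def n_steps(self) -> int:
        # tolerance guards against 0.999... / dt falling one step short
        return int(math.floor((self.t_end - self.t_start) / self.dt + 1e-9)) + 1

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_steps) * self.dt


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus: modality, presentation window, position, reliability.

    ``ech`` and ``ecv`` are the two eye-centered spherical position angles,
    in degrees. ``reliability`` scales in [0, 1] from least to most reliable.
    """

    modality: str
    onset: float
    duration: float
    ech: float
    ecv: float
    reliability: float

    def __post_init__(self) -> None:
        if self.modality not in ("visual", "auditory"):
            raise InvalidParameterError(
                f"modality must be 'visual' or 'auditory', got {self.modality!r}"
            )
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.onset < 0:
            raise InvalidParameterError(f"onset must be >= 0, got {self.onset}")
        if not 0.0 <= self.reliability <= 1.0:
            raise InvalidParameterError(
                f"reliability must lie in [0, 1], got {self.reliability}"
            )

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SignalSample:
    """Instantaneous 4-D signal value: (ext, rel, ech, ecv), angles in radians.

    When ``ext == 0`` (no stimulus detected) every other component is 0.
    """

    ext: int
    rel: float
    ech: float
    ecv: float


ZERO_SAMPLE = SignalSample(0, 0.0, 0.0, 0.0)


def make_time_grid(t_end: float, dt: float) -> TimeGrid:
    """Build a uniform grid on [0, t_end] with step dt.

    Raises
    ------
    InvalidParameterError
        If ``t_end`` or ``dt`` is not strictly positive.
    """
    if t_end <= 0:
        raise InvalidParameterError(f"t_end must be > 0, got {t_end}")
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    return TimeGrid(0.0, t_end, dt)


def stimulus_signal(spec: StimulusSpec, t: float) -> SignalSample:
    """Sample the stimulus signal at time ``t``.

    The presentation window is half-open, [onset, onset + duration): a
    stimulus switching off at the instant another switches on contributes to
    exactly one sample at the shared boundary. Inside the window the sample
    carries the spec's reliability and position (degrees converted to
    radians); outside it is the zero vector.
    """
    if spec.onset <= t < spec.offset:
        return SignalSample(
            1,
            spec.reliability,
            math.radians(spec.ech),
            math.radians(spec.ecv),
        )
    return ZERO_SAMPLE
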