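"""Rotating-wedge stimulus model: time -> wedge angle -> visual-field quadrant.

The stimulus is a flickering checkerboard wedge rotating about a central
fixation point. The wedge center angle is measured in degrees on the screen
with 0 deg at the top (vertical meridian), increasing clockwise as seen by
the subject; a counterclockwise wedge rotation therefore *decreases* the
angle over time. Quadrant arcs are the four 90 deg sectors centered on the
vertical and horizontal meridians:

    top    [315, 360) u [0, 45)
    right  [45, 135)
    bottom [135, 225)
    left   [225, 315)

Arcs are half-open so every angle receives exactly one label.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Quadrant",
    "RotationDirection",
    "StimulusProtocol",
    "InstrumentConfig",
    "wedge_angle_at",
    "label_from_angle",
    "quadrant_passes",
]


class Quadrant(str, enum.Enum):
    """Visual-field quadrant stimulated by the wedge."""

    TOP = "top"
    BOTTOM = "bottom"
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


class RotationDirection(str, enum.Enum):
    COUNTERCLOCKWISE = "counterclockwise"
    CLOCKWISE = "clockwise"


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and geometry of the rotating-wedge stimulus.

    Parameters
    ----------
    revolution_period:
        Seconds per full wedge revolution (default 48 s, i.e. 1/48 Hz).
    flicker_rate:
        Checkerboard pattern-reversal flicker in Hz (default 5 Hz; there are
        ``2 * flicker_rate`` reversals per second).
    n_revolutions:
        Number of revolutions presented per recording block (default 8).
    rotation_direction:
        Direction of wedge rotation as seen by the subject.
    start_angle:
        Wedge-center angle at stimulus onset, degrees in [0, 360).
    pre_roll, post_roll:
        Seconds of recording before stimulus onset / after offset.
    """

    revolution_period: float = 48.0
    flicker_rate: float = 5.0
    n_revolutions: int = 8
    rotation_direction: RotationDirection = RotationDirection.COUNTERCLOCKWISE
    start_angle: float = 0.0
    pre_roll: float = 1.0
    post_roll: float = 1.0

    def __post_init__(self) -> None:
        if self.revolution_period <= 0:
            raise ConfigurationError("revolution_period must be positive")
        if self.flicker_rate <= 0:
            raise ConfigurationError("flicker_rate must be positive")
        if self.n_revolutions < 1:
            raise ConfigurationError("n_revolutions must be >= 1")
        if not 0.0 <= self.start_angle < 360.0:
            raise ConfigurationError("start_angle must lie in [0, 360)")
        if isinstance(self.rotation_direction, str) and not isinstance(
            self.rotation_direction, RotationDirection
        ):
            object.__setattr__(
                self, "rotation_direction", RotationDirection(self.rotation_direction)
            )

    @property
    def stimulus_duration(self) -> float:
        """Seconds of active stimulation (revolutions only)."""
        return self.revolution_period * self.n_revolutions

    @property
    def total_duration(self) -> float:
        """Seconds of recording including pre/post roll."""
        return self.pre_roll + self.stimulus_duration + self.post_roll

    @property
    def angular_rate(self) -> float:
        """Signed degrees per second of the wedge center."""
        rate = 360.0 / self.revolution_period
        if self.rotation_direction is RotationDirection.COUNTERCLOCKWISE:
            return -rate
        return rate


@dataclass(frozen=True)
class InstrumentConfig:
    """Frequency-domain optical instrument parameters.

    ``modulation_frequency`` is the radio-frequency modulation of the source
    light (110 MHz); ``sampling_rate`` is the effective per-channel sampling
    rate after source multiplexing (39.0625 Hz).
    """

    modulation_frequency: float = 110e6
    sampling_rate: float = 39.0625

    def __post_init__(self) -> None:
        if self.modulation_frequency <= 0:
            raise ConfigurationError("modulation_frequency must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")


def wedge_angle_at(t, protocol: StimulusProtocol):
    """Wedge-center angle (degrees in [0, 360)) at stimulus time ``t``.

    ``t`` is measured from stimulus onset and must lie within
    ``[0, protocol.stimulus_duration]``. Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > protocol.stimulus_duration + 1e-12):
        raise ConfigurationError(
            f"time outside stimulation interval [0, {protocol.stimulus_duration}] s"
        )
    angle = np.mod(protocol.start_angle + protocol.angular_rate * t_arr, 360.0)
    # mod can return 360.0 for tiny negative floating residues
    angle = np.where(angle >= 360.0, angle - 360.0, angle)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(angle)
    return angle


def label_from_angle(angle):
    """Quadrant label(s) for wedge-center angle(s) in degrees.

    Total on [0, 360) (inputs are wrapped); arcs are half-open [a, b) with the
    boundary belonging to the arc it opens (45 deg -> right).
    """
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    scalar = np.ndim(angle) == 0
    a = np.atleast_1d(a)
    out = np.empty(a.shape, dtype=object)
    out[(a >= 315.0) | (a < 45.0)] = Quadrant.TOP
    out[(a >= 45.0) & (a < 135.0)] = Quadrant.RIGHT
    out[(a >= 135.0) & (a < 225.0)] = Quadrant.BOTTOM
    out[(a >= 225.0) & (a < 315.0)] = Quadrant.LEFT
    if scalar:
        return out[0]
    return out


def quadrant_passes(protocol: StimulusProtocol) -> list[tuple[float, float, Quadrant]]:
    """Maximal constant-label time intervals over the stimulation period.

    Returns ``(t_start, t_end, label)`` triples in stimulus time. Interior
    passes last ``revolution_period / 4`` seconds; if the wedge does not start
    on an arc boundary, the first and last passes are the two parts of a split
    pass of the starting quadrant.
    """
    boundaries = np.array([45.0, 135.0, 225.0, 315.0])
    rate = protocol.angular_rate
    sign = math.copysign(1.0, rate)
    # Time until the wedge center reaches each arc boundary, in rotation direction.
    dts = np.mod(sign * (boundaries - protocol.start_angle), 360.0) / abs(rate)
    positive = dts[dts > 1e-9]
    quarter = protocol.revolution_period / 4.0
    first = float(positive.min()) if positive.size else quarter
    edges = [0.0]
    t = first
    while t < protocol.stimulus_duration - 1e-9:
        edges.append(t)
        t += quarter
    edges.append(protocol.stimulus_duration)
    passes = []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 - t0 <= 1e-9:
            continue
        label = label_from_angle(wedge_angle_at(0.5 * (t0 + t1), protocol))
        passes.append((t0, t1, label))
    return passes
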