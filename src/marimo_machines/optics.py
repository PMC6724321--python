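"""Light-field geometry: beams, occlusion by balls, mirror rerouting,
opaque/transparent float sections, and PAR sensor conversions.

The beam is treated as a single ray at a configurable height.  A ball
occludes a ray when the ray height falls within the ball's vertical extent.
Beam divergence applies a purely geometric attenuation 1/(1 + tan(θ)·L)²
over path length L, so light is never created along a path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .buoyancy import Column


@dataclass(frozen=True)
class LightSource:
    """A collimated lamp.

    par_at_exit : PAR at the lamp exit aperture, µmol m⁻² s⁻¹
    beam_height : ray height above the column floor, m
    divergence_deg : full divergence angle of the beam, degrees
    always_on : whether this is an 'always-on' supply beam (logic gates)
    """

    par_at_exit: float
    beam_height: float
    beam_half_width: float = 0.0
    divergence_deg: float = 4.0
    always_on: bool = False

    def __post_init__(self) -> None:
        if self.par_at_exit < 0:
            raise ValueError("PAR must be >= 0")
        if self.divergence_deg < 0:
            raise ValueError("divergence must be >= 0 degrees")

    def attenuation(self, path_length: float) -> float:
        """Geometric attenuation factor (≤ 1) after `path_length` m."""
        t = math.tan(math.radians(self.divergence_deg))
        return 1.0 / (1.0 + t * path_length) ** 2

    def par_at(self, path_length: float) -> float:
        return self.par_at_exit * self.attenuation(path_length)


@dataclass(frozen=True)
class SensorCal:
    """PAR sensor calibration: µmol m⁻² s⁻¹ per mV of sensor output."""

    factor: float = 5.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("calibration factor must be > 0")


def par_from_sensor_voltage(millivolts: float, cal: SensorCal = SensorCal()) -> float:
    """Convert a quantum-sensor voltage (mV) to PAR (µmol m⁻² s⁻¹)."""
    if not math.isfinite(millivolts) or millivolts < 0:
        raise ValueError("sensor voltage must be a finite value >= 0 mV")
    return millivolts * cal.factor


@dataclass(frozen=True)
class FloatSection:
    """One vertical segment of a float stack, relative to the ball centre.

    `lo`/`hi` are offsets (m) from the ball centre; `opaque` says whether
    the segment blocks a ray.
    """

    lo: float
    hi: float
    opaque: bool

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("section upper bound below lower bound")


@dataclass(frozen=True)
class FloatSections:
    """A stack of non-overlapping opaque/transparent sections above a ball."""

    sections: Sequence[FloatSection] = ()

    def __post_init__(self) -> None:
        ordered = sorted(self.sections, key=lambda s: s.lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo < a.hi:
                raise ValueError("float sections overlap")


def transmit_through_float(
    sections: FloatSections, ball_position: float, beam_height: float
) -> bool:
    """True if a ray at `beam_height` passes the float stack of a ball at
    `ball_position` (centre height).  Blocked iff an opaque segment,
    translated by the ball position, covers the ray height; transparent
    segments transmit by definition."""
    for s in sections.sections:
        if s.opaque and (
            ball_position + s.lo <= beam_height <= ball_position + s.hi
        ):
            return False
    return True


def ball_occludes(
    ball_position: float,
    ball_radius: float,
    beam_height: float,
    beam_half_width: float = 0.0,
) -> bool:
    """True if the (opaque) ball body intersects the beam band (a ray when
    `beam_half_width` is zero)."""
    return abs(ball_position - beam_height) <= ball_radius + beam_half_width


@dataclass(frozen=True)
class OscillatorRig:
    """Geometry of the two-column oscillator.

    The lamp fires a horizontal ray at `beam_height` through the right
    column (nearest the lamp) and then the left column.  If the ray clears
    both columns, a mirror pair folds it back onto the *left* column's top
    band, so a floating left ball keeps receiving light only while the
    bottom path stays clear.  Spikes restrict motion to the vertical axis,
    which is why only ball-centre heights appear here.
    """

    column: Column = Column()
    source: LightSource = LightSource(
        par_at_exit=1500.0, beam_height=0.050, beam_half_width=0.050
    )
    lamp_to_right_m: float = 0.30
    column_spacing_m: float = 0.15
    mirror_path_m: float = 1.00
    #: fraction of the transmitted beam the mirror pair actually delivers
    #: onto the floating left ball (two reflections, imperfect capture of a
    #: diverged beam) — the mirror feed is a deliberately weak maintenance
    #: supply, not a second lamp
    mirror_coupling: float = 0.02

    def beam_par_at_right(self) -> float:
        return self.source.par_at(self.lamp_to_right_m)

    def beam_par_at_left(self) -> float:
        return self.source.par_at(
            self.lamp_to_right_m + self.column.width + self.column_spacing_m
        )

    def mirror_par(self) -> float:
        return self.mirror_coupling * self.source.par_at(
            self.lamp_to_right_m + 2 * self.column.width
            + self.column_spacing_m + self.mirror_path_m
        )


def illumination_at_balls(
    rig: OscillatorRig, left_position: float, right_position: float
) -> tuple[float, float]:
    """PAR delivered to (left, right) balls for given centre heights.

    The bottom ray is intercepted by the first ball whose body covers the
    ray height — the right ball shadows the left.  If the ray clears both
    columns the mirror path lights the left ball, but only while the left
    ball sits in the top band.
    """
    col = rig.column
    r = col.ball_radius
    h = rig.source.beam_height
    left_par = 0.0
    right_par = 0.0
    w = rig.source.beam_half_width
    if ball_occludes(right_position, r, h, w):
        right_par = rig.beam_par_at_right()
    elif ball_occludes(left_position, r, h, w):
        left_par = rig.beam_par_at_left()
    elif col.in_top_band(left_position):
        left_par = rig.mirror_par()
    return left_par, right_par
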