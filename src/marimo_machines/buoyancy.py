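"""Component- and assembly-level buoyancy arithmetic, and drag-limited
vertical motion of a ballasted ball in a water column.

The central bookkeeping is the net buoyancy budget of a "ballasted Marimo"
assembly: a buoyant float sphere above the alga ball, a dense weight sphere
below it, a nichrome link through it, and a variable volume of attached
photosynthetic gas.  Net buoyancy is upthrust minus weight; positive means
the assembly rises.  Attached gas contributes ≈9.8 mN of lift per mL, which
is what couples photosynthesis to motion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from .units import DEFAULT_CONSTANTS, PhysicalConstants, n_to_mn


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """A construction material with density in g cm⁻³."""

    name: str
    density: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("material density must be > 0 g/cm^3")


@dataclass(frozen=True)
class SphereComponent:
    """A solid sphere (float, weight, or the alga ball itself).

    If `weight_override` (mN) is absent the weight is derived from the
    sphere volume and material density.  `buoyancy_override` (mN) stores a
    measured net buoyancy verbatim where the weight/density/diameter data
    are mutually inconsistent (living, water-logged material defies the
    solid-sphere formula); when present it takes precedence in assembly
    totals.
    """

    material: Material
    diameter: float  # mm
    weight_override: Optional[float] = None  # mN
    buoyancy_override: Optional[float] = None  # mN
    name: str = ""

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("sphere diameter must be >= 0 mm")

    @property
    def weight(self) -> float:
        """Weight in mN (derived from volume × density unless overridden)."""
        if self.weight_override is not None:
            return self.weight_override
        vol_cm3 = sphere_volume(self.diameter)
        return vol_cm3 * self.material.density * DEFAULT_CONSTANTS.g

    def net_buoyancy(self, medium_density: float = 1.0) -> float:
        if self.buoyancy_override is not None:
            return self.buoyancy_override
        if self.weight_override is not None:
            return net_buoyancy_from_weight(
                self.weight_override, self.material.density, medium_density
            )
        return net_buoyancy_of_sphere(
            self.diameter, self.material.density, medium_density
        )


@dataclass(frozen=True)
class WireComponent:
    """A wire link of known weight (mN) and length (mm)."""

    material: Material
    length: float  # mm
    weight: float  # mN
    buoyancy_override: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("wire weight must be >= 0 mN")

    def net_buoyancy(self, medium_density: float = 1.0) -> float:
        if self.buoyancy_override is not None:
            return self.buoyancy_override
        return net_buoyancy_from_weight(
            self.weight, self.material.density, medium_density
        )


Component = Union[SphereComponent, WireComponent]


@dataclass(frozen=True)
class Assembly:
    """A set of components plus attached gas volume (mL)."""

    components: Sequence[Component] = ()
    gas_volume: float = 0.0  # mL

    def __post_init__(self) -> None:
        if self.gas_volume < 0:
            raise ValueError("gas volume must be >= 0 mL")

    def with_gas(self, gas_volume: float) -> "Assembly":
        return replace(self, gas_volume=gas_volume)

    def net_buoyancy(self, medium_density: float = 1.0) -> float:
        return assembly_net_buoyancy(self, medium_density)

    def to_dict(self) -> dict:
        comps = []
        for c in self.components:
            d = {
                "name": c.name,
                "material": c.material.name,
                "density_g_per_cm3": c.material.density,
            }
            if isinstance(c, SphereComponent):
                d["kind"] = "sphere"
                d["diameter_mm"] = c.diameter
                if c.weight_override is not None:
                    d["weight_mN"] = c.weight_override
            else:
                d["kind"] = "wire"
                d["length_mm"] = c.length
                d["weight_mN"] = c.weight
            if c.buoyancy_override is not None:
                d["buoyancy_mN"] = c.buoyancy_override
            comps.append(d)
        return {"components": comps, "gas_volume_mL": self.gas_volume}

    @classmethod
    def from_dict(cls, data: dict) -> "Assembly":
        comps: list[Component] = []
        for d in data.get("components", []):
            mat = Material(d.get("material", "unknown"), d["density_g_per_cm3"])
            if d.get("kind", "sphere") == "wire":
                comps.append(
                    WireComponent(
                        material=mat,
                        length=d.get("length_mm", 0.0),
                        weight=d["weight_mN"],
                        buoyancy_override=d.get("buoyancy_mN"),
                        name=d.get("name", ""),
                    )
                )
            else:
                comps.append(
                    SphereComponent(
                        material=mat,
                        diameter=d.get("diameter_mm", 0.0),
                        weight_override=d.get("weight_mN"),
                        buoyancy_override=d.get("buoyancy_mN"),
                        name=d.get("name", ""),
                    )
                )
        return cls(components=tuple(comps), gas_volume=data.get("gas_volume_mL", 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Assembly":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class BodyState:
    """Instantaneous state of a ball in a column.

    position : height of the ball centre above the column floor, m
    velocity : vertical velocity, m s⁻¹ (positive up)
    gas_volume : attached gas, mL
    """

    position: float
    velocity: float = 0.0
    gas_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.gas_volume < 0:
            raise ValueError("gas volume must be >= 0 mL")


@dataclass(frozen=True)
class Column:
    """Water column geometry and the position bands used for 'up'/'down'.

    Positions are ball-centre heights in m above the floor; a resting ball
    of radius r sits at position r, a floating one at `height − r`.
    """

    height: float = 0.30  # m
    width: float = 0.11  # m
    ball_diameter: float = 0.060  # m
    top_band_fraction: float = 0.15
    bottom_band_fraction: float = 0.15
    mid_band: tuple[float, float] = (0.35, 0.65)  # fractions of height

    @property
    def ball_radius(self) -> float:
        return self.ball_diameter / 2.0

    @property
    def floor_position(self) -> float:
        return self.ball_radius

    @property
    def surface_position(self) -> float:
        return self.height - self.ball_radius

    def in_top_band(self, position: float) -> bool:
        return position >= self.height * (1.0 - self.top_band_fraction)

    def in_bottom_band(self, position: float) -> bool:
        return position <= self.height * self.bottom_band_fraction

    def in_mid_band(self, position: float) -> bool:
        lo, hi = self.mid_band
        return self.height * lo <= position <= self.height * hi


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sphere_volume(diameter: float) -> float:
    """Volume of a sphere of `diameter` mm, in cm³."""
    if not math.isfinite(diameter) or diameter < 0:
        raise ValueError("diameter must be a finite value >= 0 mm")
    return (math.pi / 6.0) * diameter**3 * 1e-3


def sphere_surface_area(diameter: float) -> float:
    """Surface area of a sphere of `diameter` mm, in cm².

    A 60 mm alga ball has π·6² ≈ 113 cm² of surface, of which only part of
    the lower hemisphere holds large bubbles.
    """
    if not math.isfinite(diameter) or diameter < 0:
        raise ValueError("diameter must be a finite value >= 0 mm")
    return math.pi * diameter**2 * 1e-2


def net_buoyancy_from_weight(
    weight: float, density: float, medium_density: float = 1.0
) -> float:
    """Net buoyancy (mN, positive up) of a body of given weight and density.

    B = W·(ρ_medium/ρ − 1): the displaced-medium weight is W·ρ_medium/ρ.
    """
    if density <= 0:
        raise ValueError("density must be > 0 g/cm^3")
    if weight < 0:
        raise ValueError("weight must be >= 0 mN")
    return weight * (medium_density / density - 1.0)


def net_buoyancy_of_sphere(
    diameter: float, density: float, medium_density: float = 1.0
) -> float:
    """Net buoyancy (mN) of a solid sphere from its diameter and density."""
    if density <= 0:
        raise ValueError("density must be > 0 g/cm^3")
    vol_cm3 = sphere_volume(diameter)
    return vol_cm3 * (medium_density - density) * DEFAULT_CONSTANTS.g


def buoyancy_from_gas_volume(
    volume: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Lift (mN) of `volume` mL of attached gas: ≈ 9.80 mN per mL."""
    if not math.isfinite(volume) or volume < 0:
        raise ValueError("gas volume must be a finite value >= 0 mL")
    return volume * (constants.water_density - constants.gas_density) * constants.g


def assembly_net_buoyancy(assembly: Assembly, medium_density: float = 1.0) -> float:
    """Net buoyancy (mN) of an assembly including its attached gas."""
    total = sum(c.net_buoyancy(medium_density) for c in assembly.components)
    return total + buoyancy_from_gas_volume(assembly.gas_volume)


def usable_lift_per_area(total_lift: float, effective_area: float) -> float:
    """Usable lift per unit of bubble-holding area, g cm⁻².

    With ~1.5 g of bubble lift spread over the ~50 cm² of lower hemisphere
    that actually retains large bubbles, a 60 mm ball musters ≈0.03 g cm⁻².
    """
    if effective_area <= 0:
        raise ValueError("effective area must be > 0 cm^2")
    return total_lift / effective_area


def vertical_step(
    state: BodyState,
    net_buoyancy: float,
    effective_mass: float,
    dt: float,
    column: Column = Column(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> BodyState:
    """Advance a ball's vertical state by `dt` seconds.

    net_buoyancy is in mN.  The velocity update solves the implicit Euler
    step of m·dv/dt = F − k·v|v| exactly (a quadratic in the new
    velocity), which is unconditionally stable and has the correct
    terminal speed √(|F|/k) as its fixed point at any dt.  The position is
    clamped to [floor, surface] with the velocity zeroed on contact.
    `effective_mass` should include added (virtual) mass.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0 s")
    if effective_mass <= 0:
        raise ValueError("effective mass must be > 0 kg")
    if not all(
        math.isfinite(x)
        for x in (state.position, state.velocity, net_buoyancy, effective_mass, dt)
    ):
        raise ValueError("non-finite input to vertical_step")

    force_n = net_buoyancy * 1e-3
    target = state.velocity + dt * force_n / effective_mass
    a_drag = dt * constants.drag_coefficient / effective_mass
    if a_drag * abs(target) < 1e-12:
        v = target
    else:
        v = math.copysign(
            (math.sqrt(1.0 + 4.0 * a_drag * abs(target)) - 1.0) / (2.0 * a_drag),
            target,
        )
    pos = state.position + dt * v
    lo, hi = column.floor_position, column.surface_position
    if pos <= lo:
        pos = lo
        if v < 0.0:
            v = 0.0
    elif pos >= hi:
        pos = hi
        if v > 0.0:
            v = 0.0
    return BodyState(position=pos, velocity=v, gas_volume=state.gas_volume)


def terminal_velocity(
    net_buoyancy: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Closed-form terminal speed √(|B|/k) for constant net buoyancy (mN)."""
    force_n = abs(net_buoyancy) * 1e-3
    return math.sqrt(force_n / constants.drag_coefficient)


def effective_mass(
    ball_mass: float, displaced_water_mass: float
) -> float:
    """Ball mass plus the standard 0.5× added mass of a sphere, kg."""
    if ball_mass <= 0 or displaced_water_mass < 0:
        raise ValueError("masses must be positive")
    return ball_mass + 0.5 * displaced_water_mass
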