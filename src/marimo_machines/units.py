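"""Unit conversions and physical constants.

All public interfaces in this package use the bench units of the problem
domain (mm for component dimensions, g cm⁻³ for densities, mL for gas
volumes, mN for forces, g-force for lift).  Internally the simulators work
in SI.  Every conversion between the two lives here so that no other module
hard-codes a factor.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Standard gravity, m s⁻².
G = 9.81

#: Density of fresh water at bench temperature, g cm⁻³.
WATER_DENSITY_G_PER_CM3 = 1.0

#: Density of the photosynthetic gas mix (O2/CO2/N2), g cm⁻³.
GAS_DENSITY_G_PER_CM3 = 0.001


def mm_to_m(x: float) -> float:
    return x * 1e-3


def mm3_to_cm3(x: float) -> float:
    return x * 1e-3


def ml_to_m3(x: float) -> float:
    return x * 1e-6


def mn_to_n(x: float) -> float:
    return x * 1e-3


def n_to_mn(x: float) -> float:
    return x * 1e3


def gforce_to_mn(grams: float) -> float:
    """Weight of `grams` grams under standard gravity, in mN."""
    return grams * G


def mn_to_gforce(mn: float) -> float:
    return mn / G


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of environment constants used by the vertical dynamics.

    Parameters
    ----------
    g : float
        Gravitational acceleration, m s⁻².
    water_density : float
        Density of the water column, g cm⁻³.
    gas_density : float
        Density of the attached photosynthetic gas, g cm⁻³.
    drag_coefficient : float
        Quadratic drag constant k in F_drag = k·v², N s² m⁻².  The default
        puts the terminal speed of a 60 mm ball carrying 1.5 g-force of net
        lift at about 0.02 m s⁻¹, so rise/sink transits take seconds to
        minutes.
    """

    g: float = G
    water_density: float = WATER_DENSITY_G_PER_CM3
    gas_density: float = GAS_DENSITY_G_PER_CM3
    drag_coefficient: float = 36.75

    def __post_init__(self) -> None:
        for name in ("g", "water_density", "gas_density", "drag_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_CONSTANTS = PhysicalConstants()
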