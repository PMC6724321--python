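"""Light-driven gas production and stochastic bubble retention.

The light response is a phenomenological saturating (hyperbolic) law

    r(PAR) = r_max · PAR / (PAR + K) · exp(−t_light / τ_decline)

with three regimes bolted on:

* an induction lag after any declared environment change, during which no
  bubbles form (fresh water, handling — the organism takes several hours to
  resume bubble production);
* a slow exponential decline of production under prolonged continuous
  illumination (timescale ~10 days; not CO₂-limited — raising dissolved CO₂
  does not restore production);
* a photo-damage cutoff: above `damage_threshold` the rate is zero and the
  exposure is flagged (over-illuminated balls visibly discolour).

Bubble *retention* is what turns production into lift.  Attached gas is lost
with a base hazard rate, multiplied when the ball sits in the surface band
(surface contact and rotation shed bubbles) and, optionally, while the ball
is sinking (a negatively buoyant ball tumbles and sheds).  Escape is
modelled as binomial thinning of small bubble quanta, so the expected loss
matches the exponential hazard and fixed seeds give identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .buoyancy import BodyState, Column


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Gas-production parameters.

    r_max : asymptotic production rate, mL day⁻¹
    half_saturation : PAR at which the rate is r_max/2, µmol m⁻² s⁻¹
    induction_lag_h : hours before production starts after an environment
        change
    decline_timescale_days : e-folding time of the long-term production
        decline under continuous light; ``inf`` disables it
    damage_threshold : PAR above which photo-damage suppresses production,
        µmol m⁻² s⁻¹
    """

    r_max: float = 18.0
    half_saturation: float = 3000.0
    induction_lag_h: float = 4.0
    decline_timescale_days: float = 10.0
    damage_threshold: float = 3000.0

    def __post_init__(self) -> None:
        if self.r_max < 0:
            raise ValueError("r_max must be >= 0 mL/day")
        if self.half_saturation <= 0:
            raise ValueError("half-saturation K must be > 0")
        if self.induction_lag_h < 0:
            raise ValueError("induction lag must be >= 0 h")


@dataclass(frozen=True)
class RetentionParams:
    """Bubble escape/retention parameters.

    base_escape_rate : hazard of attached gas escaping, h⁻¹
    surface_escape_multiplier : factor applied while the ball is in the
        column's top band (surface rotation sheds bubbles; lowered-centre-
        of-mass assemblies warrant a smaller value)
    sinking_escape_multiplier : factor applied while the ball descends
        faster than `sinking_speed_threshold` (tumbling sheds bubbles)
    max_attached_volume : saturation volume of attached gas, mL (default
        2.04 mL ≈ 20 mN of lift, the measured bubble-lift cap)
    quantum_ml : bubble quantum used by the binomial thinning, mL
    """

    base_escape_rate: float = 0.25
    surface_escape_multiplier: float = 3.0
    sinking_escape_multiplier: float = 1.0
    sinking_speed_threshold: float = 1e-3  # m/s
    max_attached_volume: float = 2.04
    quantum_ml: float = 0.002

    def __post_init__(self) -> None:
        if self.base_escape_rate < 0:
            raise ValueError("escape rate must be >= 0 per hour")
        if min(self.surface_escape_multiplier, self.sinking_escape_multiplier) < 0:
            raise ValueError("escape multipliers must be >= 0")
        if self.max_attached_volume <= 0:
            raise ValueError("max attached volume must be > 0 mL")

    def hazard(self, in_top_band: bool, sinking: bool) -> float:
        """Effective escape hazard (h⁻¹) for the given ball situation."""
        mult = 1.0
        if in_top_band:
            mult = max(mult, self.surface_escape_multiplier)
        if sinking:
            mult = max(mult, self.sinking_escape_multiplier)
        return self.base_escape_rate * mult


def gas_production_rate(
    par: float,
    params: PhotosynthesisParams,
    elapsed_light_time: float = 0.0,
    time_since_environment_change_h: Optional[float] = None,
) -> float:
    """Instantaneous gas production rate, mL day⁻¹.

    Parameters
    ----------
    par : irradiance at the ball, µmol m⁻² s⁻¹
    elapsed_light_time : days of continuous illumination so far (drives the
        long-term decline)
    time_since_environment_change_h : hours since the organism was moved to
        a new/refreshed environment; ``None`` means the induction lag has
        long passed.

    Returns 0 during the induction lag and above the damage threshold (use
    :func:`is_photo_damaging` to distinguish damage from darkness).
    """
    if not math.isfinite(par) or par < 0:
        raise ValueError("PAR must be a finite value >= 0")
    if (
        time_since_environment_change_h is not None
        and time_since_environment_change_h < params.induction_lag_h
    ):
        return 0.0
    if par > params.damage_threshold:
        return 0.0
    decline = 1.0
    if math.isfinite(params.decline_timescale_days):
        decline = math.exp(-elapsed_light_time / params.decline_timescale_days)
    return params.r_max * par / (par + params.half_saturation) * decline


def is_photo_damaging(par: float, params: PhotosynthesisParams) -> bool:
    return par > params.damage_threshold


def expected_escape_fraction(hazard_per_h: float, dt_h: float) -> float:
    """Fraction of attached gas expected to escape in `dt_h` hours."""
    return 1.0 - math.exp(-hazard_per_h * dt_h)


def update_gas_volume(
    state: BodyState,
    par: float,
    dt: float,
    params: PhotosynthesisParams = PhotosynthesisParams(),
    retention: RetentionParams = RetentionParams(),
    rng: Optional[np.random.Generator] = None,
    column: Column = Column(),
    elapsed_light_time: float = 0.0,
    time_since_environment_change_h: Optional[float] = None,
) -> BodyState:
    """Advance attached gas volume by `dt` hours.

    Production integrates the deterministic rate law; escape removes a
    binomially thinned number of bubble quanta with survival probability
    exp(−hazard·dt) (expected-value thinning when `rng` is None, which
    makes the update fully deterministic).  The volume is clipped to
    [0, max_attached_volume].
    """
    if dt <= 0:
        raise ValueError("dt must be > 0 h")
    rate_ml_day = gas_production_rate(
        par, params, elapsed_light_time, time_since_environment_change_h
    )
    produced = rate_ml_day * dt / 24.0

    hazard = retention.hazard(
        in_top_band=column.in_top_band(state.position),
        sinking=state.velocity < -retention.sinking_speed_threshold,
    )
    survive_p = math.exp(-hazard * dt)
    vol = state.gas_volume
    if rng is None:
        vol *= survive_p
    elif vol > 0.0:
        n_quanta = int(vol // retention.quantum_ml)
        if n_quanta > 0:
            kept = rng.binomial(n_quanta, survive_p)
            vol = kept * retention.quantum_ml
        # sub-quantum residue decays deterministically
        vol += (state.gas_volume - n_quanta * retention.quantum_ml) * survive_p

    vol = min(max(vol + produced, 0.0), retention.max_attached_volume)
    return BodyState(
        position=state.position, velocity=state.velocity, gas_volume=vol
    )
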