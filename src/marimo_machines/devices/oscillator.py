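"""Two-ball oscillator simulator.

Mechanism (a relaxation oscillation driven by light routing):

* Both balls down (state 00): the lamp's bottom ray hits the right ball,
  which charges with gas and floats.
* Right up, left down (01): the ray passes under the right ball and charges
  the left ball, which floats in turn.  The right ball, now unlit, slowly
  loses bubbles at the surface.
* Both up (11): the ray clears both columns and the mirror pair folds a
  weakened beam onto the floating left ball, which holds it just above the
  flotation threshold; the unlit right ball keeps draining and sinks.
* Left up, right down (10): the sunk right ball blocks the ray, the mirror
  feed dies, the left ball drains and sinks, closing the cycle 00→01→11→10.

A ball that sinks sheds most of its attached gas on the way down (tumbling),
so it reaches the floor needing a full recharge — this is what gives each
phase a finite dwell time instead of a flicker at the flotation threshold.

The shipped "ideal" preset is deterministic (expected-value bubble escape);
the "stochastic" preset adds seeded binomial bubble-escape noise.  The
preset's automaton sampling interval (4.25 min) is matched to the phase dwell
times (roughly one to two sampling intervals each), so the sampled chain
advances around the cycle rather than self-looping or skipping states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..buoyancy import BodyState, Column, buoyancy_from_gas_volume, vertical_step
from ..optics import LightSource, OscillatorRig, illumination_at_balls
from ..photosynthesis import (
    PhotosynthesisParams,
    RetentionParams,
    update_gas_volume,
)
from ..units import DEFAULT_CONSTANTS, PhysicalConstants
from .trajectory import Trajectory


@dataclass(frozen=True)
class OscillatorPreset:
    """Parameter bundle for the two-ball oscillator.

    The ballast values are the gas-free net buoyancies of the two
    ballasted balls (float + alga ball + weight + link; about −1 mN for
    the reference assembly), so a ball floats once its attached gas lifts
    more than its ballast pulls down.  The left ball is ballasted slightly
    heavier than the right: it needs a little more gas to float and sheds
    down to its threshold a little sooner, which separates the both-up and
    both-down phases of the cycle instead of letting the two balls swap
    simultaneously.  `stochastic_escape` switches the bubble-escape
    thinning from expected-value (fully deterministic) to seeded binomial
    sampling.
    """

    photosynthesis: PhotosynthesisParams = PhotosynthesisParams(
        r_max=72.0,
        half_saturation=3000.0,
        induction_lag_h=0.0,
        decline_timescale_days=float("inf"),
        damage_threshold=6000.0,
    )
    retention: RetentionParams = RetentionParams(
        base_escape_rate=0.5,
        surface_escape_multiplier=1.8,
        sinking_escape_multiplier=180.0,
        sinking_speed_threshold=3e-4,
        max_attached_volume=0.125,
        quantum_ml=0.0002,
    )
    ballast_left_mN: float = -1.12
    ballast_right_mN: float = -1.0
    effective_mass_kg: float = 0.17
    stochastic_escape: bool = False
    sample_interval_s: float = 255.0

    @classmethod
    def ideal(cls) -> "OscillatorPreset":
        """Deterministic preset: noise-free escape, clean 4-state cycle."""
        return cls()

    @classmethod
    def stochastic(cls) -> "OscillatorPreset":
        """Ideal physics plus seeded binomial bubble-escape noise."""
        return cls(stochastic_escape=True)


def default_rig() -> OscillatorRig:
    """Two 300 mm columns, lamp ray at sunk-ball-centre height, mirror
    feed delivering a weakened beam to the left column's top band."""
    return OscillatorRig(
        column=Column(),
        source=LightSource(
            par_at_exit=1500.0, beam_height=0.050, beam_half_width=0.050
        ),
        mirror_coupling=0.02,
    )


def simulate_oscillator(
    rig: Optional[OscillatorRig] = None,
    preset: Optional[OscillatorPreset] = None,
    duration_h: float = 8.0,
    dt_s: float = 1.0,
    seed: Optional[int] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    record_every_s: float = 5.0,
) -> Trajectory:
    """Time-step the two-ball oscillator and return its trajectory.

    Each step routes the light (occlusion + mirror), updates each ball's
    attached gas, converts gas to net buoyancy, and advances the drag-
    limited vertical motion.  With `seed` given and a stochastic preset the
    run is exactly reproducible.  If the device never leaves the all-down
    state (for instance with the lamp off), the result carries
    ``flags["settled"] = False`` rather than raising.
    """
    if rig is None:
        rig = default_rig()
    if preset is None:
        preset = OscillatorPreset.ideal()
    if dt_s <= 0 or duration_h <= 0:
        raise ValueError("duration and dt must be > 0")

    col = rig.column
    n_steps = int(round(duration_h * 3600.0 / dt_s))
    record_every = max(1, int(round(record_every_s / dt_s)))
    n_rec = n_steps // record_every + 1

    rng_l = rng_r = None
    if preset.stochastic_escape:
        ss = np.random.SeedSequence(0 if seed is None else seed)
        child_l, child_r = ss.spawn(2)
        rng_l = np.random.default_rng(child_l)
        rng_r = np.random.default_rng(child_r)

    left = BodyState(position=col.floor_position)
    right = BodyState(position=col.floor_position)
    dt_h = dt_s / 3600.0

    t = np.empty(n_rec)
    lp = np.empty(n_rec)
    rp = np.empty(n_rec)
    ll = np.empty(n_rec)
    lg = np.empty(n_rec)
    rg = np.empty(n_rec)
    lpar = np.empty(n_rec)
    rpar = np.empty(n_rec)

    k = 0
    ever_up = False
    for i in range(n_steps + 1):
        par_l, par_r = illumination_at_balls(rig, left.position, right.position)
        # exit sensor: light behind both columns (nonzero only when the
        # bottom ray clears both balls)
        blocked = _occludes(rig, right.position) or _occludes(rig, left.position)
        exit_light = 0.0 if blocked else rig.beam_par_at_left()

        if i % record_every == 0 and k < n_rec:
            t[k] = i * dt_s
            lp[k], rp[k] = left.position, right.position
            lg[k], rg[k] = left.gas_volume, right.gas_volume
            lpar[k], rpar[k] = par_l, par_r
            ll[k] = exit_light
            k += 1
        if i == n_steps:
            break

        left = update_gas_volume(
            left, par_l, dt_h, preset.photosynthesis, preset.retention,
            rng=rng_l, column=col,
        )
        right = update_gas_volume(
            right, par_r, dt_h, preset.photosynthesis, preset.retention,
            rng=rng_r, column=col,
        )
        b_l = preset.ballast_left_mN + buoyancy_from_gas_volume(
            left.gas_volume, constants
        )
        b_r = preset.ballast_right_mN + buoyancy_from_gas_volume(
            right.gas_volume, constants
        )
        left = vertical_step(
            left, b_l, preset.effective_mass_kg, dt_s, col, constants
        )
        right = vertical_step(
            right, b_r, preset.effective_mass_kg, dt_s, col, constants
        )
        if col.in_top_band(left.position) or col.in_top_band(right.position):
            ever_up = True

    return Trajectory(
        time_s=t[:k],
        left_pos_m=lp[:k],
        right_pos_m=rp[:k],
        light_level=ll[:k],
        left_gas_ml=lg[:k],
        right_gas_ml=rg[:k],
        left_par=lpar[:k],
        right_par=rpar[:k],
        flags={"settled": ever_up, "sample_interval_s": preset.sample_interval_s},
    )


def _occludes(rig: OscillatorRig, position: float) -> bool:
    from ..optics import ball_occludes

    return ball_occludes(
        position,
        rig.column.ball_radius,
        rig.source.beam_height,
        rig.source.beam_half_width,
    )
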