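"""Synthetic trajectory generation, the reference material fixture, and
CSV trajectory file IO.

The synthetic generator emulates the structure of the processed two-ball
oscillator recordings (time, left level, right level, light level): a
square-wave-like alternation with a configurable period, phase lag between
the balls, Gaussian position noise and sample dropout.  It replaces video
tracking; everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .buoyancy import (
    Assembly,
    Material,
    SphereComponent,
    WireComponent,
)
from .devices.trajectory import Trajectory

REQUIRED_COLUMNS = ("time_s", "left_pos_m", "right_pos_m", "light_level")
CSV_PRECISION = "%.6g"


class TrajectoryFormatError(ValueError):
    """A trajectory file violated the CSV contract."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


def make_reference_assembly() -> Assembly:
    """The reference ballasted-ball component set.

    Measured per-row data: a polypropylene float sphere (+7.8 mN), the alga
    ball itself (520 mN weight, −4.9 mN measured), a polyoxymethylene
    weight sphere (11 mm, 9.0 mN, −2.6 mN) and a 75 mm nichrome link
    (1.5 mN, −1.3 mN).  Measured net buoyancies are stored verbatim as
    overrides — a live, water-logged alga ball does not obey the
    solid-sphere formula — so the gas-free total is −1.0 mN, and +19.0 mN
    at the 2.04 mL bubble cap.
    """
    return Assembly(
        components=(
            SphereComponent(
                material=Material("polypropylene", 0.9),
                diameter=25.4,
                buoyancy_override=7.8,
                name="float",
            ),
            SphereComponent(
                material=Material("filamentous algae", 1.0),
                diameter=55.0,
                weight_override=520.0,
                buoyancy_override=-4.9,
                name="marimo",
            ),
            SphereComponent(
                material=Material("polyoxymethylene", 1.42),
                diameter=11.0,
                weight_override=9.0,
                buoyancy_override=-2.6,
                name="weight",
            ),
            WireComponent(
                material=Material("nichrome", 8.4),
                length=75.0,
                weight=1.5,
                buoyancy_override=-1.3,
                name="link",
            ),
        ),
        gas_volume=0.0,
    )


@dataclass(frozen=True)
class SyntheticTrajectoryParams:
    """Shape of the synthetic two-ball square-wave trajectory.

    period_h : full oscillation period
    rise_fraction : fraction of the period each ball spends up
    lag_h : phase lag of the left ball behind the right (period/4 gives
        the canonical 00→01→11→10 cycle)
    position_noise_sd_m : Gaussian noise on positions
    dropout_probability : chance a sample is missing (NaN)
    """

    period_h: float = 2.0
    rise_fraction: float = 0.5
    lag_h: float = 0.5
    position_noise_sd_m: float = 0.0
    dropout_probability: float = 0.0
    duration_h: float = 24.0
    #: default samples four times per period (once per cycle phase), so a
    #: noise-free trajectory encodes to the exact four-state cycle
    sample_interval_s: float = 1800.0
    up_position_m: float = 0.27
    down_position_m: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period must be > 0 h")
        if not 0.0 <= self.rise_fraction <= 1.0:
            raise ValueError("rise fraction must be in [0, 1]")
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ValueError("dropout probability must be in [0, 1]")


def synth_oscillator_trajectory(
    params: SyntheticTrajectoryParams = SyntheticTrajectoryParams(),
) -> Trajectory:
    """Generate a seeded square-wave two-ball trajectory."""
    rng = np.random.default_rng(params.seed)
    t = np.arange(
        0.0, params.duration_h * 3600.0 + 1e-9, params.sample_interval_s
    )
    t_h = t / 3600.0

    def up(phase_h: np.ndarray) -> np.ndarray:
        frac = np.mod(phase_h, params.period_h) / params.period_h
        return frac < params.rise_fraction

    right_up = up(t_h)
    left_up = up(t_h - params.lag_h)
    right = np.where(right_up, params.up_position_m, params.down_position_m)
    left = np.where(left_up, params.up_position_m, params.down_position_m)
    light = np.where(left_up & right_up, 100.0, 0.0)
    if params.position_noise_sd_m > 0:
        left = left + rng.normal(0.0, params.position_noise_sd_m, len(t))
        right = right + rng.normal(0.0, params.position_noise_sd_m, len(t))
    if params.dropout_probability > 0:
        drop = rng.random(len(t)) < params.dropout_probability
        left = np.where(drop, np.nan, left)
        right = np.where(drop, np.nan, right)
    return Trajectory(
        time_s=t,
        left_pos_m=left,
        right_pos_m=right,
        light_level=light,
        flags={"sample_interval_s": params.sample_interval_s},
    )


def write_trajectory_csv(trajectory: Trajectory, path: Union[str, Path]) -> None:
    """Write the four-column CSV (missing samples as empty fields)."""
    df = pd.DataFrame(
        {
            "time_s": trajectory.time_s,
            "left_pos_m": trajectory.left_pos_m,
            "right_pos_m": trajectory.right_pos_m,
            "light_level": trajectory.light_level,
        }
    )
    df.to_csv(path, index=False, float_format=CSV_PRECISION, na_rep="")


def read_trajectory_csv(path: Union[str, Path]) -> Trajectory:
    """Read a trajectory CSV, validating schema and time monotonicity."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError("empty trajectory file", line=1)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(
            f"missing required column(s): {', '.join(missing)}", line=1
        )
    t = df["time_s"].to_numpy(dtype=float)
    if np.isnan(t).any():
        line = int(np.flatnonzero(np.isnan(t))[0]) + 2  # +1 header, +1 1-based
        raise TrajectoryFormatError("missing time value", line=line)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise TrajectoryFormatError(
            "time column must be strictly increasing", line=int(bad[0]) + 3
        )
    return Trajectory(
        time_s=t,
        left_pos_m=df["left_pos_m"].to_numpy(dtype=float),
        right_pos_m=df["right_pos_m"].to_numpy(dtype=float),
        light_level=df["light_level"].to_numpy(dtype=float),
    )
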