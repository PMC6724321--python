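"""Sampled time-series container shared by the simulators and the file IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class Trajectory:
    """Uniformly sampled two-ball trajectory.

    Required series are the sample times (s), the two ball-centre heights
    (m) and the light level at the exit sensor (PAR behind both columns).
    Simulators additionally fill per-ball gas volumes (mL) and per-ball
    irradiance; file round-trips carry only the required four columns.
    Missing samples are NaN.
    """

    time_s: np.ndarray
    left_pos_m: np.ndarray
    right_pos_m: np.ndarray
    light_level: np.ndarray
    left_gas_ml: Optional[np.ndarray] = None
    right_gas_ml: Optional[np.ndarray] = None
    left_par: Optional[np.ndarray] = None
    right_par: Optional[np.ndarray] = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        series = [self.left_pos_m, self.right_pos_m, self.light_level]
        series += [
            s
            for s in (
                self.left_gas_ml,
                self.right_gas_ml,
                self.left_par,
                self.right_par,
            )
            if s is not None
        ]
        if any(len(s) != n for s in series):
            raise ValueError("all trajectory series must have the same length")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def dt_s(self) -> float:
        if len(self.time_s) < 2:
            raise ValueError("need at least two samples for a sampling interval")
        return float(self.time_s[1] - self.time_s[0])

    def resample_every(self, interval_s: float) -> "Trajectory":
        """Thin the trajectory to one sample per `interval_s` seconds."""
        step = max(1, int(round(interval_s / self.dt_s)))
        sl = slice(None, None, step)
        return Trajectory(
            time_s=self.time_s[sl],
            left_pos_m=self.left_pos_m[sl],
            right_pos_m=self.right_pos_m[sl],
            light_level=self.light_level[sl],
            left_gas_ml=None if self.left_gas_ml is None else self.left_gas_ml[sl],
            right_gas_ml=None if self.right_gas_ml is None else self.right_gas_ml[sl],
            left_par=None if self.left_par is None else self.left_par[sl],
            right_par=None if self.right_par is None else self.right_par[sl],
            flags=dict(self.flags),
        )
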