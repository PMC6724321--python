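"""Light-routed logic gates built from vertically mobile alga balls.

Each gate is a declarative layout: a set of water columns, each holding a
ballasted ball driven by one logical input (an input beam floods its column
when that input is 1, so the ball floats lit and sinks dark), plus one or
two always-on supply beams routed horizontally through the columns to
output sensors (F1, F2).  What each column does to a supply beam is set by
its float stack:

* ``transmit_when_up`` — an opaque section above the ball blocks the beam
  while the ball is sunk and clears it when the ball floats (the column
  passes the beam iff its input is 1);
* ``block_when_up`` — an opaque sleeve on the link below the ball rises
  into the beam when the ball floats (the column passes the beam iff its
  input is 0).

The gate output is 1 iff any output sensor reads more than half the supply
beam's PAR after a settle period.  The five shipped layouts (NOR, AND, OR,
NAND, XOR) reproduce their Boolean truth tables; XOR routes two supply
beams through four columns (two per logical input, labelled A–D) to two
sensors.  Layouts are data, not code: alternative routings can be loaded
from the same YAML schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import yaml

from ..buoyancy import BodyState, Column, buoyancy_from_gas_volume, vertical_step
from ..optics import (
    FloatSection,
    FloatSections,
    LightSource,
    ball_occludes,
    transmit_through_float,
)
from ..photosynthesis import PhotosynthesisParams, RetentionParams, update_gas_volume

class NonSettlingError(RuntimeError):
    """A gate layout failed to reach a stable ball configuration."""


#: named float stacks, offsets in m relative to the ball centre
STACKS: dict[str, FloatSections] = {
    "transmit_when_up": FloatSections(
        (FloatSection(lo=0.15, hi=0.19, opaque=True),)
    ),
    "block_when_up": FloatSections(
        (FloatSection(lo=-0.09, hi=-0.05, opaque=True),)
    ),
    "plain": FloatSections(()),
}

#: height of the horizontal supply beams above the column floor, m
OUTPUT_BEAM_HEIGHT = 0.20


@dataclass(frozen=True)
class GateColumn:
    name: str
    input_index: int
    stack: str  # key into STACKS

    def __post_init__(self) -> None:
        if self.stack not in STACKS:
            raise ValueError(f"unknown float stack {self.stack!r}")


@dataclass(frozen=True)
class OutputBeam:
    sensor: str  # "F1" or "F2"
    path: tuple[str, ...]  # column names, in traversal order


@dataclass(frozen=True)
class GateConfig:
    kind: str
    columns: tuple[GateColumn, ...]
    beams: tuple[OutputBeam, ...]
    source: LightSource = LightSource(
        par_at_exit=1000.0, beam_height=OUTPUT_BEAM_HEIGHT, always_on=True
    )
    input_par: float = 1500.0
    settle_time_h: float = 12.0

    @property
    def n_inputs(self) -> int:
        return 1 + max(c.input_index for c in self.columns)


#: ball/biology parameters shared by the gate columns: fast idealised
#: production, moderate dark loss, low gas cap so dark balls drain well
#: inside the settle window
GATE_PHOTOSYNTHESIS = PhotosynthesisParams(
    r_max=72.0,
    half_saturation=3000.0,
    induction_lag_h=0.0,
    decline_timescale_days=float("inf"),
    damage_threshold=6000.0,
)
GATE_RETENTION = RetentionParams(
    base_escape_rate=0.5,
    surface_escape_multiplier=1.0,
    sinking_escape_multiplier=1.0,
    max_attached_volume=0.3,
)
GATE_BALLAST_MN = -1.0
GATE_EFFECTIVE_MASS = 0.17


def _settle_column(
    lit: bool,
    config: GateConfig,
    column: Column,
    dt_s: float = 30.0,
) -> tuple[float, bool]:
    """Simulate one ball for the settle time; return (final position,
    stable flag).  Stability = no up/down flip in the final quarter."""
    state = BodyState(position=column.floor_position)
    par = config.input_par if lit else 0.0
    n = int(round(config.settle_time_h * 3600.0 / dt_s))
    dt_h = dt_s / 3600.0
    mid = column.height / 2.0
    flips = 0
    last_bit = state.position >= mid
    for i in range(n):
        state = update_gas_volume(
            state, par, dt_h, GATE_PHOTOSYNTHESIS, GATE_RETENTION, column=column
        )
        b = GATE_BALLAST_MN + buoyancy_from_gas_volume(state.gas_volume)
        state = vertical_step(state, b, GATE_EFFECTIVE_MASS, dt_s, column)
        bit = state.position >= mid
        if i >= 3 * n // 4 and bit != last_bit:
            flips += 1
        last_bit = bit
    return state.position, flips == 0


def evaluate_gate(
    gate: GateConfig,
    inputs: Sequence[int],
    column: Column = Column(),
    dt_s: float = 30.0,
) -> int:
    """Run the gate for its settle time and read the output bit.

    `inputs` are the logical input bits, one per distinct input index in
    the layout (two for all shipped gates).  Raises
    :class:`NonSettlingError` if any column is still flipping between up
    and down at the end of the settle window.
    """
    if len(inputs) != gate.n_inputs:
        raise ValueError(
            f"gate {gate.kind} expects {gate.n_inputs} inputs, got {len(inputs)}"
        )
    if any(b not in (0, 1) for b in inputs):
        raise ValueError("inputs must be bits")

    positions: dict[str, float] = {}
    for col_spec in gate.columns:
        pos, stable = _settle_column(
            bool(inputs[col_spec.input_index]), gate, column, dt_s
        )
        if not stable:
            raise NonSettlingError(
                f"column {col_spec.name} of gate {gate.kind} did not settle"
            )
        positions[col_spec.name] = pos

    threshold = 0.5 * gate.source.par_at_exit
    stacks = {c.name: STACKS[c.stack] for c in gate.columns}
    out = 0
    for beam in gate.beams:
        par = gate.source.par_at_exit
        for name in beam.path:
            pos = positions[name]
            body_block = ball_occludes(
                pos, column.ball_radius, gate.source.beam_height
            )
            section_block = not transmit_through_float(
                stacks[name], pos, gate.source.beam_height
            )
            if body_block or section_block:
                par = 0.0
                break
        if par > threshold:
            out = 1
    return out


def gate_truth_table(gate: GateConfig, **kwargs) -> dict[tuple[int, ...], int]:
    """Evaluate a gate over every input combination."""
    n = gate.n_inputs
    table = {}
    for i in range(2**n):
        bits = tuple((i >> (n - 1 - j)) & 1 for j in range(n))
        table[bits] = evaluate_gate(gate, bits, **kwargs)
    return table


def load_gate_layouts(path: Optional[str] = None) -> dict[str, GateConfig]:
    """Load the shipped (or a user) YAML gate-layout file."""
    if path is None:
        text = (
            resources.files("marimo_machines") / "presets.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    gates = {}
    for kind, spec in data["gates"].items():
        columns = tuple(
            GateColumn(name=c["name"], input_index=c["input"], stack=c["stack"])
            for c in spec["columns"]
        )
        beams = tuple(
            OutputBeam(sensor=b["sensor"], path=tuple(b["path"]))
            for b in spec["beams"]
        )
        gates[kind] = GateConfig(kind=kind, columns=columns, beams=beams)
    return gates
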