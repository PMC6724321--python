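"""The oscillator as a probabilistic four-state automaton.

A two-ball trajectory is encoded into the alphabet {00, 01, 10, 11}
(left bit, right bit; 1 = ball above the threshold height), transition
probabilities are estimated from the sampled symbol series, and the
maximum-likelihood cycle — the closed path obtained by always following
each state's most probable outgoing transition — summarises the device's
idealised behaviour.  For a working oscillator that cycle is
00 → 01 → 11 → 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence, Union

import numpy as np

from .devices.trajectory import Trajectory

MISSING = -1


class StateSymbol(IntEnum):
    """Two-bit ball-configuration state: left bit, right bit; 1 = up."""

    S00 = 0
    S01 = 1
    S10 = 2
    S11 = 3

    @property
    def label(self) -> str:
        return format(self.value, "02b")

    @classmethod
    def from_bits(cls, left: int, right: int) -> "StateSymbol":
        return cls(2 * left + right)


STATE_LABELS = tuple(s.label for s in StateSymbol)


def encode_states(
    left: Sequence[float],
    right: Sequence[float],
    up_threshold: float = 0.15,
) -> np.ndarray:
    """Encode two position series into state codes 0–3.

    A ball's bit is 1 iff its position is ≥ `up_threshold` (closed upper
    rule: exactly at the threshold counts as up).  Samples where either
    position is NaN encode as MISSING (−1) and are skipped downstream.
    """
    left_arr = np.asarray(left, dtype=float)
    right_arr = np.asarray(right, dtype=float)
    if left_arr.shape != right_arr.shape:
        raise ValueError("left and right series must have equal length")
    lbit = (left_arr >= up_threshold).astype(int)
    rbit = (right_arr >= up_threshold).astype(int)
    codes = 2 * lbit + rbit
    codes[np.isnan(left_arr) | np.isnan(right_arr)] = MISSING
    return codes


@dataclass
class TransitionMatrix:
    """Row-stochastic transition estimate over the four states.

    `probabilities[i, j]` estimates P(state j at t+lag | state i at t).
    Rows with no observed departures are NOT uniform-filled: they are NaN
    and flagged False in `observed`, and the cycle extractor treats them as
    dead ends.
    """

    probabilities: np.ndarray
    counts: np.ndarray
    lag: int = 1

    @property
    def observed(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        for i in range(4):
            row = p[i]
            if np.isnan(row).all():
                continue
            if np.any((row < -1e-12) | (row > 1 + 1e-12)):
                raise ValueError("probabilities must lie in [0, 1]")
            if abs(row.sum() - 1.0) > 1e-8:
                raise ValueError("observed rows must sum to 1")

    def summary(self) -> str:
        lines = [f"Transition probabilities (lag {self.lag}):"]
        header = "      " + "  ".join(f"{lab:>6}" for lab in STATE_LABELS)
        lines.append(header)
        for i, lab in enumerate(STATE_LABELS):
            if self.observed[i]:
                cells = "  ".join(f"{p:6.3f}" for p in self.probabilities[i])
            else:
                cells = "  ".join(f"{'--':>6}" for _ in range(4))
            lines.append(f"{lab:>6}  {cells}")
        return "\n".join(lines)

    def to_edge_list(self, min_probability: float = 0.0) -> list[dict]:
        """Weighted edges for graph tooling (JSON-serialisable)."""
        edges = []
        for i in range(4):
            if not self.observed[i]:
                continue
            for j in range(4):
                p = float(self.probabilities[i, j])
                if p > min_probability:
                    edges.append(
                        {
                            "from": STATE_LABELS[i],
                            "to": STATE_LABELS[j],
                            "probability": p,
                            "count": int(self.counts[i, j]),
                        }
                    )
        return edges

    def to_networkx(self, min_probability: float = 0.0):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(STATE_LABELS)
        for e in self.to_edge_list(min_probability):
            g.add_edge(e["from"], e["to"], probability=e["probability"])
        return g


def estimate_transitions(symbols: Sequence[int], lag: int = 1) -> TransitionMatrix:
    """Row-normalised transition counts at the given lag.

    Pairs that include a MISSING sample are skipped; unobserved rows stay
    NaN.  Raises on series too short to contain a single transition.
    """
    sym = np.asarray(symbols, dtype=int)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if sym.ndim != 1 or len(sym) < lag + 1:
        raise ValueError("need at least lag+1 samples to estimate transitions")
    src, dst = sym[:-lag], sym[lag:]
    ok = (src != MISSING) & (dst != MISSING)
    counts = np.zeros((4, 4), dtype=int)
    np.add.at(counts, (src[ok], dst[ok]), 1)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / totals
    probs[totals.ravel() == 0] = np.nan
    return TransitionMatrix(probabilities=probs, counts=counts, lag=lag)


def estimate_transitions_multi(
    series: Sequence[Sequence[int]], lag: int = 1
) -> TransitionMatrix:
    """Pooled transition estimate from several recordings of one device.

    Counts are summed across the recordings before row-normalising —
    transitions are never counted across recording boundaries.  This is
    the natural estimator for repeat runs of the same rig: per-run phase
    jitter averages out.
    """
    if not series:
        raise ValueError("need at least one symbol series")
    counts = sum(estimate_transitions(s, lag).counts for s in series)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / totals
    probs[totals.ravel() == 0] = np.nan
    return TransitionMatrix(probabilities=probs, counts=counts, lag=lag)


@dataclass
class CycleResult:
    """Maximum-likelihood path until the first repeated state.

    `states` lists the cycle (or, if `dead_end`, the path up to the
    unobserved/zero row); `edge_probabilities[k]` is P(states[k] →
    states[(k+1) % len]).  `is_cycle` is True iff the repeat closed on the
    start state.
    """

    states: list[StateSymbol]
    is_cycle: bool
    edge_probabilities: list[float] = field(default_factory=list)
    dead_end: bool = False

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]


def max_likelihood_cycle(
    matrix: TransitionMatrix, start: StateSymbol = StateSymbol.S00
) -> CycleResult:
    """Follow each state's most probable transition until a state repeats.

    Ties break toward the lowest state in (00, 01, 10, 11) order.  An
    unobserved or all-zero row ends the walk as an explicit dead end.
    """
    probs = matrix.probabilities
    path: list[StateSymbol] = []
    edge_p: list[float] = []
    seen: set[int] = set()
    current = int(StateSymbol(start))
    while current not in seen:
        seen.add(current)
        path.append(StateSymbol(current))
        row = probs[current]
        if np.isnan(row).all() or np.nansum(row) == 0.0:
            return CycleResult(
                states=path, is_cycle=False, edge_probabilities=edge_p,
                dead_end=True,
            )
        nxt = int(np.nanargmax(row))
        edge_p.append(float(row[nxt]))
        current = nxt
    closes_on_start = current == int(StateSymbol(start))
    return CycleResult(
        states=path, is_cycle=closes_on_start, edge_probabilities=edge_p
    )


def simulate_automaton(
    matrix: Union[TransitionMatrix, np.ndarray],
    n_steps: int,
    seed: Optional[int] = None,
    start: StateSymbol = StateSymbol.S00,
) -> np.ndarray:
    """Sample a Markov chain of length `n_steps` from the matrix.

    Requires a fully row-stochastic matrix (every row observed and
    summing to 1); raises ValueError otherwise.
    """
    probs = (
        matrix.probabilities if isinstance(matrix, TransitionMatrix) else
        np.asarray(matrix, dtype=float)
    )
    if probs.shape != (4, 4):
        raise ValueError("transition matrix must be 4x4")
    if np.isnan(probs).any() or np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("matrix entries must be probabilities in [0, 1]")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("every row must sum to 1")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(0 if seed is None else seed)
    out = np.empty(n_steps, dtype=int)
    current = int(StateSymbol(start))
    for i in range(n_steps):
        out[i] = current
        current = int(rng.choice(4, p=probs[current]))
    return out


@dataclass
class OscillationMetrics:
    period_samples: Optional[float]
    occupancy: np.ndarray  # fraction of samples per state, length 4
    transition_counts: Optional[np.ndarray]


def oscillation_metrics(
    data: Union[Sequence[int], Trajectory],
    up_threshold: float = 0.15,
    sample_interval_s: Optional[float] = None,
) -> OscillationMetrics:
    """Dominant period, state occupancy and transition counts.

    The period estimate is the median recurrence time of state 00 (median
    spacing of entries into 00), in samples — the median is robust to the
    spurious extra entries that symbol noise creates; None (flagged) when
    00 recurs fewer than twice, e.g. for a constant series.  Trajectories are
    resampled to `sample_interval_s` (default: their own declared
    interval) and threshold-encoded first.
    """
    if isinstance(data, Trajectory):
        interval = sample_interval_s or data.flags.get("sample_interval_s")
        traj = data.resample_every(interval) if interval else data
        sym = encode_states(traj.left_pos_m, traj.right_pos_m, up_threshold)
    else:
        sym = np.asarray(data, dtype=int)
    if len(sym) == 0:
        raise ValueError("empty symbol series")
    valid = sym[sym != MISSING]
    occupancy = np.bincount(valid, minlength=4) / max(len(valid), 1)
    entries = np.flatnonzero(
        (sym[1:] == StateSymbol.S00) & (sym[:-1] != StateSymbol.S00)
    ) + 1
    if sym[0] == StateSymbol.S00:
        entries = np.concatenate(([0], entries))
    period = float(np.median(np.diff(entries))) if len(entries) >= 2 else None
    counts = (
        estimate_transitions(sym).counts if len(sym) >= 2 else None
    )
    return OscillationMetrics(
        period_samples=period, occupancy=occupancy, transition_counts=counts
    )
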