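"""Quick-look plots: trajectories and transition diagrams."""

from __future__ import annotations

from typing import Optional

import matplotlib.pyplot as plt
import numpy as np

from .automaton import STATE_LABELS, TransitionMatrix
from .devices.trajectory import Trajectory


def plot_trajectory(trajectory: Trajectory, ax: Optional[plt.Axes] = None):
    """Ball heights and exit-sensor light level against time (hours)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t_h = trajectory.time_s / 3600.0
    ax.plot(t_h, trajectory.left_pos_m, label="left ball", color="tab:red")
    ax.plot(t_h, trajectory.right_pos_m, label="right ball", color="tab:green")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("height (m)")
    ax2 = ax.twinx()
    light = trajectory.light_level
    if np.nanmax(light) > 0:
        light = light / np.nanmax(light)
    ax2.plot(t_h, light, ".", color="black", ms=2, alpha=0.4, label="exit light")
    ax2.set_ylabel("exit light (norm.)")
    ax.legend(loc="upper right")
    return ax


def plot_transition_diagram(
    matrix: TransitionMatrix,
    min_probability: float = 0.05,
    ax: Optional[plt.Axes] = None,
):
    """State-transition diagram with edges weighted by probability."""
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    g = matrix.to_networkx(min_probability)
    pos = {lab: p for lab, p in zip(STATE_LABELS, [(0, 0), (1, 0), (0, 1), (1, 1)])}
    weights = [5.0 * g[u][v]["probability"] for u, v in g.edges]
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_color="#cde8cd", node_size=1200,
        width=weights, connectionstyle="arc3,rad=0.15", arrows=True,
    )
    labels = {
        (u, v): f"{g[u][v]['probability']:.2f}" for u, v in g.edges
    }
    nx.draw_networkx_edge_labels(
        g, pos=pos, ax=ax, edge_labels=labels, label_pos=0.3, font_size=7
    )
    ax.set_axis_off()
    return ax
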