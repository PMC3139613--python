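"""Rendering of simulation snapshots: cell bodies over the slime field."""

from __future__ import annotations

import numpy as np

from .simulation import SimulationState

__all__ = ["render_state"]


def render_state(state: SimulationState, ax=None, show_slime: bool = True,
                 cell_color: str = "k", slime_cmap: str = "Blues"):
    """Draw the current population: node chains in black, EPS in light blue.

    Returns the matplotlib axes.  Cell bodies crossing the periodic seam are
    drawn unwrapped from the leading pole, so short segments may poke out of
    the frame rather than streak across it.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    d = state.domain
    if show_slime and state.field is not None and state.field.total > 0:
        ax.imshow(
            np.log1p(state.field.counts.T), origin="lower", cmap=slime_cmap,
            extent=(0, d.width, 0, d.height), interpolation="nearest", alpha=0.8,
        )
    from .core import min_image_displacement

    for i in range(state.n):
        k = state.n_nodes[i]
        nodes = state.nodes[i, :k]
        rel = np.vstack([[0.0, 0.0],
                         np.cumsum(min_image_displacement(nodes[:-1], nodes[1:], d), axis=0)])
        chain = nodes[0] + rel
        ax.plot(chain[:, 0], chain[:, 1], "-", color=cell_color, lw=0.7)
    ax.set_xlim(0, d.width)
    ax.set_ylim(0, d.height)
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"t = {state.time_min:.0f} min")
    return ax
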