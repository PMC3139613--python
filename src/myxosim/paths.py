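"""Waypoint buffers and arc-length body following.

The leading pole traces a polyline of recent waypoints; the body nodes trail
behind it *along that polyline* at arc-length spacing L.  This keeps the
equal-segment invariant of the node chain exact for any step length: when
the distance moved per step equals L it degenerates to the simple rule of
shifting every node to its predecessor's old position.

All functions are batch-first: arrays hold ``m`` cells along axis 0 and the
per-cell API simply passes ``m = 1``.  Waypoints are stored newest-first in
*unwrapped* coordinates (each cell's own continuous frame); callers rebase
them whenever the pole is wrapped back into the domain.
"""

from __future__ import annotations

import numpy as np

from .core import DomainConfig, min_image_displacement

PATH_CAPACITY = 8
"""Waypoints kept per cell.

Seven polyline segments of at least one segment length L each always cover
the full body arc (n_nodes - 1) * L <= 5 µm.
"""

__all__ = [
    "PATH_CAPACITY",
    "straight_path",
    "path_from_chain",
    "push_waypoint",
    "chain_from_path",
    "arc_positions",
]


def straight_path(poles: np.ndarray, headings: np.ndarray, spacing: np.ndarray | float,
                  capacity: int = PATH_CAPACITY) -> np.ndarray:
    """Collinear waypoint buffers trailing straight behind each pole."""
    poles = np.atleast_2d(np.asarray(poles, dtype=float))
    headings = np.atleast_2d(np.asarray(headings, dtype=float))
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), poles.shape[:1])
    k = np.arange(capacity)
    return poles[:, None, :] - (k[None, :, None] * spacing[:, None, None]) * headings[:, None, :]


def path_from_chain(nodes: np.ndarray, n_nodes: np.ndarray, domain: DomainConfig,
                    capacity: int = PATH_CAPACITY) -> np.ndarray:
    """Rebuild waypoint buffers from (wrapped, possibly padded) node chains.

    Used after a polarity reversal: the reversed body itself becomes the
    path the new leading pole just traced.  Entry 0 is node 0 (the new
    leading pole); entries beyond the chain extrapolate straight along the
    last body segment so the buffer is always full.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim == 2:
        nodes = nodes[None]
    m, max_nodes, _ = nodes.shape
    n_nodes = np.broadcast_to(np.asarray(n_nodes, dtype=np.int64), (m,))
    path = np.empty((m, capacity, 2))
    path[:, 0] = nodes[:, 0]
    # unwrap the chain: accumulate minimum-image steps from the leading pole
    last_step = np.zeros((m, 2))
    seg_len = np.ones(m)
    for j in range(1, capacity):
        if j < max_nodes:
            step = min_image_displacement(nodes[:, j - 1], nodes[:, j], domain)
            valid = j < n_nodes
            step = np.where(valid[:, None], step, last_step)
        else:
            step = last_step
        path[:, j] = path[:, j - 1] + step
        last_step = step
        if j < max_nodes:
            norm = np.linalg.norm(step, axis=1)
            seg_len = np.where(norm > 1e-12, norm, seg_len)
    # guard: a chain shorter than the capacity with a degenerate last step
    # would stall the buffer; extrapolation above reuses the last real step.
    return path


def push_waypoint(path: np.ndarray, new_pole: np.ndarray) -> np.ndarray:
    """Prepend the new pole position, dropping the oldest waypoint."""
    out = np.empty_like(path)
    out[:, 1:] = path[:, :-1]
    out[:, 0] = new_pole
    return out


def arc_positions(path: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Points at given arc-length distances behind the newest waypoint.

    ``path`` is ``(m, K, 2)`` newest-first; ``targets`` is ``(m, j)`` arc
    lengths (µm).  Targets beyond the stored polyline clamp to its far end.
    """
    seg = path[:, :-1] - path[:, 1:]                      # (m, K-1, 2)
    d = np.linalg.norm(seg, axis=2)                       # (m, K-1)
    cum = np.concatenate([np.zeros((len(path), 1)), np.cumsum(d, axis=1)], axis=1)  # (m, K)
    t = np.minimum(targets, cum[:, -1][:, None])
    # index of the last waypoint whose cumulative arc <= t
    idx = (cum[:, :, None] <= t[:, None, :] + 1e-12).sum(axis=1) - 1
    idx = np.clip(idx, 0, path.shape[1] - 2)
    d_seg = np.take_along_axis(d, idx, axis=1)
    frac = (t - np.take_along_axis(cum, idx, axis=1)) / np.where(d_seg > 1e-12, d_seg, 1.0)
    frac = np.clip(frac, 0.0, 1.0)
    p0 = np.take_along_axis(path, idx[:, :, None], axis=1)
    p1 = np.take_along_axis(path, idx[:, :, None] + 1, axis=1)
    return p0 + frac[:, :, None] * (p1 - p0)


def chain_from_path(path: np.ndarray, seg_length: np.ndarray, max_nodes: int) -> np.ndarray:
    """Node chains trailing the pole at arc spacing L (unwrapped coordinates)."""
    seg_length = np.atleast_1d(np.asarray(seg_length, dtype=float))
    targets = np.arange(max_nodes)[None, :] * seg_length[:, None]
    return arc_positions(path, targets)
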