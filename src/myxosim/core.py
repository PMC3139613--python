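"""Domain types and 2-D periodic geometry shared by the whole simulator.

Cells glide on a flat periodic surface. All positions are continuous 2-D
coordinates in micrometres with the origin at the bottom-left corner; every
inter-agent measurement goes through the minimum-image convention so that a
cell near one edge of the domain interacts with cells near the opposite edge
exactly as if they were adjacent.

A cell is a string of ``n_nodes`` nodes joined by segments of equal length
``L`` (a bead-chain / follow-the-leader representation).  Node 0 is the
leading pole, node ``n_nodes - 1`` the lagging pole, and the cell's
orientation is the unit vector from the lagging to the leading pole.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

__all__ = [
    "DomainConfig",
    "CellParams",
    "Cell",
    "RngStream",
    "GeometryError",
    "wrap",
    "min_image_displacement",
    "orientation",
    "orientation_of_chain",
    "rotate",
    "unit",
]


class GeometryError(ValueError):
    """Raised for degenerate geometry (e.g. coincident cell poles)."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainConfig:
    """Rectangular periodic domain.

    Parameters
    ----------
    width, height:
        Domain side lengths in µm.
    dt:
        Simulation time step in minutes.  One step corresponds to 1/3 min,
        so a cell gliding at 4.5 µm/min advances 1.5 µm per step.
    periodic:
        Kept for clarity; the simulator only supports periodic boundaries.
    """

    width: float
    height: float
    dt: float = 1.0 / 3.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("domain sides must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.periodic:
            raise ValueError("only periodic domains are supported")

    @property
    def size(self) -> np.ndarray:
        return np.array([self.width, self.height], dtype=float)

    def n_steps(self, hours: float) -> int:
        """Number of whole time steps covering ``hours`` of simulated time."""
        return int(round(hours * 60.0 / self.dt))


@dataclass(frozen=True)
class CellParams:
    """Per-cell behavioural parameters, sampled once at initialization.

    ``length`` is drawn uniformly from 3–5 µm and the node count is tied to
    it (``n_nodes = round(length)`` clamped to [3, 5]) so the segment length
    stays between 1 and 1.7 µm.  ``width`` is a tenth of the length.  The
    gliding speed is fixed at 4.5 µm/min.  ``reversal_period`` is the
    baseline clock period (Normal, mean 6.24 min, sd 0.5 min); the *current*
    period lives on the cell because quorum sensing modulates it.  Turning
    parameters describe the spontaneous ("active") turning behaviour: a
    Normal turning interval around 3 min and a Normal turning-angle
    magnitude around 30 degrees.
    """

    length: float
    n_nodes: int
    width: float
    speed: float = 4.5
    reversal_period: float = 6.24
    turning_interval: float = 3.0
    turning_angle_mean: float = 30.0
    turning_angle_sd: float = 10.0
    turning_angle_max: float = 90.0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("at least three nodes (two segments) are required")
        if not (self.length > 0 and self.width > 0 and self.speed > 0):
            raise ValueError("length, width and speed must be positive")
        if self.reversal_period <= 0 or self.turning_interval <= 0:
            raise ValueError("sampled periods must be positive")

    @property
    def segment_length(self) -> float:
        """Arc-length spacing L between consecutive nodes (µm)."""
        return self.length / (self.n_nodes - 1)

    @staticmethod
    def n_nodes_for_length(length: float) -> int:
        return int(np.clip(round(length), 3, 5))

    @classmethod
    def from_length(cls, length: float, n_nodes: int | None = None, **kw) -> "CellParams":
        if n_nodes is None:
            n_nodes = cls.n_nodes_for_length(length)
        return cls(length=length, n_nodes=n_nodes, width=0.1 * length, **kw)


@dataclass
class Cell:
    """One bacterium: a node chain plus its behavioural clocks.

    ``nodes`` holds wrapped positions, shape ``(n_nodes, 2)``, node 0 being
    the leading pole.  ``path`` is a bounded queue of recent leading-pole
    waypoints (newest first, *unwrapped* coordinates) along which the body
    nodes trail at arc-length spacing L.  ``reversal_phase`` is the time in
    minutes since the reversal clock was last reset and ``current_period``
    the (possibly quorum-modulated) period at which it fires.
    """

    id: int
    nodes: np.ndarray
    params: CellParams
    path: np.ndarray
    reversal_phase: float = 0.0
    current_period: float | None = None
    last_turn_time: float = 0.0
    turning_interval: float | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (self.params.n_nodes, 2):
            raise ValueError("node array shape does not match n_nodes")
        if self.current_period is None:
            self.current_period = self.params.reversal_period
        if self.turning_interval is None:
            self.turning_interval = self.params.turning_interval

    @property
    def leading_pole(self) -> np.ndarray:
        return self.nodes[0]

    @property
    def lagging_pole(self) -> np.ndarray:
        return self.nodes[-1]

    def centroid(self, domain: DomainConfig) -> np.ndarray:
        """Centre of mass of the nodes under the minimum-image convention."""
        rel = min_image_displacement(self.nodes[0], self.nodes, domain)
        return wrap(self.nodes[0] + rel.mean(axis=0), domain)


class RngStream:
    """Named, independent random substreams derived from one seed.

    Separate generators are used for initialization, reversal-period
    sampling, turning sampling, collision choices and tie-breaking so that
    switching one behavioural subsystem off (a mutant preset) does not shift
    the draws consumed by the others.
    """

    NAMES = ("init", "reversal", "turning", "collision", "tiebreak")

    def __init__(self, seed: int):
        self.seed = int(seed)
        children = np.random.SeedSequence(self.seed).spawn(len(self.NAMES))
        for name, child in zip(self.NAMES, children):
            setattr(self, name, np.random.Generator(np.random.PCG64(child)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngStream(seed={self.seed})"


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------


def wrap(position: np.ndarray, domain: DomainConfig) -> np.ndarray:
    """Map positions into [0, width) x [0, height), congruent modulo the domain."""
    out = np.mod(np.asarray(position, dtype=float), domain.size)
    # float rounding in np.mod can land exactly on the open upper edge
    return np.where(out >= domain.size, 0.0, out)


def min_image_displacement(a: np.ndarray, b: np.ndarray, domain: DomainConfig) -> np.ndarray:
    """Shortest displacement ``b - a`` under the periodic wrap.

    Broadcasts over leading axes; each component of the result has magnitude
    at most half the corresponding domain side.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - domain.size * np.round(d / domain.size)


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize vectors along the last axis; degenerate input raises."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise GeometryError("cannot normalize a zero-length vector")
    return v / n


def orientation_of_chain(nodes: np.ndarray, domain: DomainConfig) -> np.ndarray:
    """Unit vector from the lagging pole (last node) to the leading pole (node 0)."""
    d = min_image_displacement(nodes[-1], nodes[0], domain)
    if np.linalg.norm(d) < 1e-9:
        raise GeometryError("coincident poles: orientation undefined")
    return unit(d)


def orientation(cell: Cell, domain: DomainConfig) -> np.ndarray:
    """Cell orientation: the unit vector pointing from lagging to leading pole."""
    return orientation_of_chain(cell.nodes, domain)


def rotate(v: np.ndarray, angle_deg: float | np.ndarray) -> np.ndarray:
    """Rotate 2-vectors by ``angle_deg`` (positive = counterclockwise).

    ``v`` may be a single vector or an array ``(..., 2)``; ``angle_deg``
    broadcasts against its leading axes.
    """
    v = np.asarray(v, dtype=float)
    theta = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(theta), np.sin(theta)
    x, y = v[..., 0], v[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def signed_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed angle in degrees from ``a`` to ``b`` (counterclockwise positive)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = (a * b).sum(axis=-1)
    return np.rad2deg(np.arctan2(cross, dot))
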