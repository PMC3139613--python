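"""Per-cell, per-step motility rules for gliding *M. xanthus* cells.

Each step a cell resolves exactly one of six movement modes, in strict
priority order:

a. **Reversal** — the reversal clock fired; leading and lagging poles swap
   and the cell does not translate this step.  At a reversal the local cell
   density is measured and, with quorum sensing on, the reversal period is
   re-drawn from the density-matched range.
b. **Collision** — the leading pole came within one cell width of another
   cell's node.  Pole-to-side contact aligns the cell with its neighbour at
   an acute angle; pole-to-pole contact makes the cell either swerve
   slightly past the other cell or reverse, with equal probability.
c. **EPS trail following** — slime found in the forward semicircle steers
   the cell toward the sector of highest concentration (an acute turn).
d. **Active turning** — with no external cue, a cell still spontaneously
   turns by a Normal-distributed angle (mean 30 degrees) once its turning
   timer (Normal, mean 3 min) elapses, left or right with equal chance.
e. **Straight** — otherwise the cell glides along its tail-to-head axis.

The functions in this module operate on one :class:`~myxosim.core.Cell` at
a time and are the reference semantics; the vectorized population step in
:mod:`myxosim.engine` is cross-checked against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from . import paths
from .core import (
    Cell,
    DomainConfig,
    RngStream,
    min_image_displacement,
    orientation,
    rotate,
    signed_angle,
    unit,
    wrap,
)
from .slime import SlimeField, eps_direction, sense_region

__all__ = [
    "Mode",
    "DecisionOutcome",
    "QuorumTable",
    "check_reversal",
    "reverse_polarity",
    "local_density",
    "modulate_period",
    "detect_collision",
    "resolve_pole_to_side",
    "resolve_pole_to_pole",
    "check_active_turn",
    "decide",
    "advance",
    "truncated_normal",
]


class Mode(IntEnum):
    """One-hot movement mode resolved for each cell at each step."""

    REVERSED = 0
    COLLISION_ALIGN = 1
    COLLISION_POLE = 2
    EPS_FOLLOW = 3
    ACTIVE_TURN = 4
    STRAIGHT = 5


@dataclass
class DecisionOutcome:
    """Result of one per-cell decision: the mode, the motility direction
    (``None`` for a non-moving reversal step) and event metadata."""

    mode: Mode
    direction: np.ndarray | None
    details: dict

    def __post_init__(self) -> None:
        if self.mode is not Mode.REVERSED and not self.details.get("reversed", False):
            if self.direction is None:
                raise ValueError("moving modes require a direction")


@dataclass(frozen=True)
class QuorumTable:
    """Density-dependent reversal-period table.

    Each class maps a neighbour-count range to a reversal-period range in
    minutes; at a reversal the new period is drawn uniformly from the range
    matching the cell's local density.  Below the lowest class the cell
    falls back to its baseline sampled period.  The open-ended highest
    class (>= 1000 neighbours, >= 300 min) is capped at 360 min — longer
    than any simulated run, i.e. behaviourally non-reversing.
    """

    classes: tuple[tuple[float, float, float, float], ...] = (
        (5, 19, 8.0, 12.0),
        (20, 99, 15.0, 30.0),
        (100, 999, 30.0, 40.0),
        (1000, np.inf, 300.0, 360.0),
    )

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for lo, hi, plo, phi in self.classes:
            if not (lo > prev_hi and hi >= lo and phi >= plo > 0):
                raise ValueError("quorum classes must be increasing and non-overlapping")
            prev_hi = hi

    def lookup(self, density: int) -> tuple[float, float] | None:
        for lo, hi, plo, phi in self.classes:
            if lo <= density <= hi:
                return (plo, phi)
        return None


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float = -np.inf,
    hi: float = np.inf,
    size: int | tuple | None = None,
) -> np.ndarray | float:
    """Truncated-Normal draws via inverse-CDF on uniforms (stream friendly)."""
    if sd <= 0:
        x = np.clip(mean, lo, hi)
        return np.full(size, x) if size is not None else x
    u = rng.random(size)
    return truncnorm.ppf(u, (lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


# ---------------------------------------------------------------------------
# clock, quorum
# ---------------------------------------------------------------------------


def reverse_polarity(cell: Cell, domain: DomainConfig) -> None:
    """Swap leading and lagging poles (and their functions) in place.

    Node order flips, the orientation is thereby negated, the reversal
    clock resets and the path history is rebuilt from the reversed body —
    the new pole retraces the body's own arc, so an undisturbed cell glides
    back along the path it came on.
    """
    cell.nodes = cell.nodes[::-1].copy()
    cell.reversal_phase = 0.0
    cell.path = paths.path_from_chain(cell.nodes, cell.params.n_nodes, domain)[0]


def check_reversal(cell: Cell, dt: float, domain: DomainConfig) -> bool:
    """Advance the reversal clock by ``dt``; fire and reverse if it expires.

    Returns True when the cell reversed, in which case it does not
    translate this step.
    """
    cell.reversal_phase += dt
    if cell.reversal_phase >= cell.current_period:
        reverse_polarity(cell, domain)
        return True
    return False


def local_density(cell: Cell, all_cells: Sequence[Cell], domain: DomainConfig) -> int:
    """Neighbour count inside the cell's measuring domain.

    The measuring domain is the axis-aligned square of side one cell length
    centred at the cell's node centroid; any other cell with at least one
    node partly inside (boundary inclusive, minimum-image) counts.
    """
    center = cell.centroid(domain)
    half = cell.params.length / 2.0
    count = 0
    for other in all_cells:
        if other.id == cell.id:
            continue
        rel = min_image_displacement(center, other.nodes, domain)
        if np.any((np.abs(rel[:, 0]) <= half) & (np.abs(rel[:, 1]) <= half)):
            count += 1
    return count


def modulate_period(cell: Cell, density: int, table: QuorumTable, rng: RngStream) -> float:
    """Re-draw the current reversal period from the density-matched range.

    Called at reversal events only.  Densities below the lowest class fall
    back to the cell's baseline sampled period, so a cell that leaves a
    dense region recovers its normal reversal rhythm.
    """
    rng_ = rng.reversal if isinstance(rng, RngStream) else rng
    match = table.lookup(density)
    if match is None:
        cell.current_period = cell.params.reversal_period
    else:
        cell.current_period = float(rng_.uniform(*match))
    return cell.current_period


# ---------------------------------------------------------------------------
# collisions
# ---------------------------------------------------------------------------


def detect_collision(
    cell: Cell, neighbors: Sequence[Cell], domain: DomainConfig
) -> tuple[Cell, int] | None:
    """Nearest node of another cell within one cell width of the leading pole.

    Returns ``(partner, node_index)`` or ``None``; node index 0 is the
    partner's leading pole (pole-to-pole), anything else pole-to-side.  The
    threshold is strict (< one width of the colliding cell).
    """
    pole = cell.leading_pole
    best: tuple[float, Cell, int] | None = None
    for other in neighbors:
        if other.id == cell.id:
            continue
        d = np.linalg.norm(min_image_displacement(pole, other.nodes, domain), axis=1)
        j = int(np.argmin(d))
        if d[j] < cell.params.width and (best is None or d[j] < best[0]):
            best = (float(d[j]), other, j)
    if best is None:
        return None
    return best[1], best[2]


def resolve_pole_to_side(
    cell: Cell, partner: Cell, domain: DomainConfig, rng: RngStream
) -> np.ndarray:
    """Acute alignment with the collided neighbour.

    Returns the partner orientation or its negation, whichever makes an
    acute angle with the cell's own orientation; a perpendicular tie is
    broken by the tie-break stream.
    """
    oi = orientation(cell, domain)
    oj = orientation(partner, domain)
    dot = float(oi @ oj)
    if abs(dot) < 1e-12:
        rng_ = rng.tiebreak if isinstance(rng, RngStream) else rng
        sign = 1.0 if rng_.random() < 0.5 else -1.0
    else:
        sign = np.sign(dot)
    return sign * oj


def resolve_pole_to_pole(
    cell: Cell,
    domain: DomainConfig,
    rng: RngStream,
    slight_turn: tuple[float, float] = (10.0, 30.0),
) -> DecisionOutcome:
    """Head-on collision: swerve slightly past, or reverse, with equal odds.

    The swerve angle is drawn uniformly from ``±[slight_turn]``; the
    reversal branch performs the full polarity-reversal action (clock reset
    included) and the cell does not move this step.
    """
    rng_ = rng.collision if isinstance(rng, RngStream) else rng
    if rng_.random() < 0.5:
        reverse_polarity(cell, domain)
        return DecisionOutcome(Mode.COLLISION_POLE, None, {"reversed": True})
    mag = rng_.uniform(*slight_turn)
    sign = 1.0 if rng_.random() < 0.5 else -1.0
    d = rotate(orientation(cell, domain), sign * mag)
    return DecisionOutcome(Mode.COLLISION_POLE, d, {"reversed": False, "angle_deg": sign * mag})


# ---------------------------------------------------------------------------
# active turning
# ---------------------------------------------------------------------------


def check_active_turn(
    cell: Cell,
    now: float,
    rng: RngStream,
    domain: DomainConfig,
    interval_mean: float = 3.0,
    interval_sd: float = 1.0,
    interval_min: float = 0.1,
) -> np.ndarray | None:
    """Spontaneous turn once the turning timer has elapsed.

    The magnitude is Normal around the cell's turning-angle mean, truncated
    to (0, max]; left and right are equally likely.  On firing, the timer
    resets and a fresh turning interval is drawn.
    """
    if now - cell.last_turn_time < cell.turning_interval:
        return None
    rng_ = rng.turning if isinstance(rng, RngStream) else rng
    p = cell.params
    mag = float(truncated_normal(rng_, p.turning_angle_mean, p.turning_angle_sd,
                                 lo=0.0, hi=p.turning_angle_max))
    sign = 1.0 if rng_.random() < 0.5 else -1.0
    cell.last_turn_time = now
    cell.turning_interval = float(
        truncated_normal(rng_, interval_mean, interval_sd, lo=interval_min)
    )
    return rotate(orientation(cell, domain), sign * mag)


# ---------------------------------------------------------------------------
# full decision and movement
# ---------------------------------------------------------------------------


def decide(
    cell: Cell,
    neighbors: Sequence[Cell],
    field: SlimeField | None,
    now: float,
    domain: DomainConfig,
    rng: RngStream,
    *,
    reversal_enabled: bool = True,
    quorum: QuorumTable | None = None,
    all_cells: Sequence[Cell] | None = None,
    collisions_enabled: bool = True,
    eps_enabled: bool = True,
    turning_enabled: bool = True,
    slight_turn: tuple[float, float] = (10.0, 30.0),
    align_tol_deg: float = 15.0,
    n_sectors: int = 6,
    sense_radius: float | None = None,
    straight_tol_deg: float | None = None,
    saturation: float | None = None,
    exclude_bins: Sequence[int] = (),
    interval_mean: float = 3.0,
    interval_sd: float = 1.0,
) -> DecisionOutcome:
    """Resolve the cell's one-hot movement mode for this step.

    Applies the strict priority reversal > collision > trail following >
    active turning > straight.  Disabled subsystems (mutant presets) are
    skipped transparently.  Mutates the cell's clocks (and body, for
    reversals) as side effects; call :func:`advance` afterwards to move it.
    """
    dt = domain.dt
    if reversal_enabled and check_reversal(cell, dt, domain):
        details: dict = {}
        if quorum is not None:
            density = local_density(cell, all_cells if all_cells is not None else neighbors, domain)
            details["density"] = density
            details["period_min"] = modulate_period(cell, density, quorum, rng)
        return DecisionOutcome(Mode.REVERSED, None, details)

    o = orientation(cell, domain)

    if collisions_enabled:
        hit = detect_collision(cell, neighbors, domain)
        if hit is not None:
            partner, node_idx = hit
            if node_idx == 0:
                out = resolve_pole_to_pole(cell, domain, rng, slight_turn)
                out.details["partner"] = partner.id
                return out
            # a side contact only steers while the axes are not yet aligned;
            # contacting cells gliding (anti-)parallel are a stream, not an
            # alignment event, and remain open to slime cues and turning
            dot = float(o @ orientation(partner, domain))
            if abs(dot) < np.cos(np.deg2rad(align_tol_deg)):
                d = resolve_pole_to_side(cell, partner, domain, rng)
                return DecisionOutcome(
                    Mode.COLLISION_ALIGN, d,
                    {"partner": partner.id, "angle_deg": float(signed_angle(o, d))},
                )

    d_eps = None
    if eps_enabled and field is not None:
        radius = cell.params.length if sense_radius is None else sense_radius
        sensed = sense_region(field, cell.leading_pole, o, radius, exclude_bins)
        rng_tie = rng.tiebreak if isinstance(rng, RngStream) else rng
        d_eps = eps_direction(field, cell, sensed, n_sectors=n_sectors, rng=rng_tie,
                              saturation=saturation)

    # a trail whose winning direction is within the straight-ahead dead band
    # is the trail the cell is already on: it does not steer, and the cell
    # stays open to active turning
    tol = 90.0 / n_sectors if straight_tol_deg is None else straight_tol_deg
    steering = d_eps is not None and float(d_eps @ o) < np.cos(np.deg2rad(tol))

    if turning_enabled and not steering:
        d = check_active_turn(cell, now, rng, domain, interval_mean, interval_sd)
        if d is not None:
            return DecisionOutcome(
                Mode.ACTIVE_TURN, d, {"angle_deg": float(signed_angle(o, d))}
            )

    if steering:
        return DecisionOutcome(
            Mode.EPS_FOLLOW, d_eps, {"angle_deg": float(signed_angle(o, d_eps))}
        )

    return DecisionOutcome(Mode.STRAIGHT, o, {})


def advance(cell: Cell, outcome: DecisionOutcome, dt: float, domain: DomainConfig) -> Cell:
    """Move the cell along the decided direction for one step.

    The leading pole displaces by exactly ``speed * dt``; the body nodes
    re-position along the recorded pole path at arc spacing L, which keeps
    the equal-segment invariant.  A reversal outcome consumes the step
    without translation.
    """
    if outcome.mode is Mode.REVERSED or outcome.details.get("reversed", False):
        return cell
    d = np.asarray(outcome.direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("motility direction must be a unit vector")
    new_pole = cell.path[0] + cell.params.speed * dt * d
    path = paths.push_waypoint(cell.path[None], new_pole[None])
    nodes = paths.chain_from_path(path, cell.params.segment_length, cell.params.n_nodes)[0]
    cell.nodes = wrap(nodes, domain)
    # rebase the unwrapped buffer so it stays near the wrapped pole
    offset = cell.nodes[0] - path[0, 0]
    cell.path = path[0] + offset
    return cell
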