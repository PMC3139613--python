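"""Initialization, main loop, experiment presets and run artifacts.

A run starts from cells placed uniformly at random with uniform random
orientations and straight bodies; each reversal clock begins at a random
phase of its period.  The loop then repeats: rebuild the neighbour index,
let every cell decide its movement mode from the previous step's positions,
move the movers, and deposit slime — for the configured number of steps
(one step = 1/3 min, so 12 h = 2160 steps).

Snapshots of cell centroids (plus leading poles and orientations) are kept
at a fixed cadence for the analysis module; events and per-step mode counts
are collected for behavioural statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd

from . import engine, paths
from .config import SimConfig, get_preset, scale_preset  # re-exported
from .core import Cell, CellParams, DomainConfig, RngStream, min_image_displacement, wrap
from .motility import Mode, truncated_normal
from .slime import SlimeField

__all__ = [
    "SimulationState",
    "RunResult",
    "initialize",
    "run",
    "get_preset",
    "scale_preset",
    "write_run",
]


class SimulationState:
    """All cells, the slime field and the clock state of one simulation.

    Cell state is stored as structure-of-arrays (axis 0 = cell) so the
    population step can be vectorized; :attr:`cells` materializes plain
    :class:`~myxosim.core.Cell` objects for analysis and per-cell checks.
    """

    max_nodes = 5

    def __init__(self, config: SimConfig, seed: int):
        self.config = config
        self.domain = DomainConfig(config.domain.width, config.domain.height, config.domain.dt)
        self.rng = RngStream(seed)
        self.seed = int(seed)
        self.step = 0
        n = self.n = int(config.cells.n)
        if n <= 0:
            raise ValueError("cell count must be positive")
        init = self.rng.init

        lo, hi = config.cells.length_range
        self.lengths = init.uniform(lo, hi, n)
        if config.cells.n_nodes is None:
            self.n_nodes = np.clip(np.round(self.lengths).astype(np.int64), 3, self.max_nodes)
        else:
            self.n_nodes = np.full(n, int(config.cells.n_nodes), dtype=np.int64)
        self.widths = 0.1 * self.lengths
        self.seg_len = self.lengths / (self.n_nodes - 1)
        self.speeds = np.full(n, config.cells.speed)

        rev = config.reversal
        self.base_period = np.asarray(
            truncated_normal(init, rev.mean, rev.sd, lo=rev.min_period, size=n), dtype=float)
        self.period = self.base_period.copy()
        self.phase = init.uniform(0.0, self.period)

        tc = config.turning
        self.turn_interval = np.asarray(
            truncated_normal(init, tc.interval_mean, tc.interval_sd,
                             lo=tc.interval_min, size=n), dtype=float)
        self.last_turn = np.zeros(n)

        poles = init.uniform(0.0, 1.0, (n, 2)) * self.domain.size
        theta = init.uniform(0.0, 2.0 * np.pi, n)
        heading = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        offsets = np.arange(self.max_nodes)[None, :, None] * self.seg_len[:, None, None]
        self.nodes = wrap(poles[:, None, :] - offsets * heading[:, None, :], self.domain)
        self.path = paths.straight_path(poles, heading, self.speeds * self.domain.dt)

        # no slime machinery at all for EPS-null (dif) mutants
        self.field = (SlimeField(self.domain, config.eps.bin_size, config.eps.deposit_rate)
                      if config.eps.enabled else None)
        self.recent_bins = np.full((n, max(1, int(config.eps.self_exclude_steps))), -1,
                                   dtype=np.int64)

    # -- derived views -----------------------------------------------------

    @property
    def time_min(self) -> float:
        return self.step * self.domain.dt

    def centroids(self) -> np.ndarray:
        """Per-cell node centre of mass (minimum image), wrapped."""
        valid = np.arange(self.max_nodes)[None, :] < self.n_nodes[:, None]
        rel = min_image_displacement(self.nodes[:, :1, :], self.nodes, self.domain)
        rel = np.where(valid[:, :, None], rel, 0.0)
        return wrap(self.nodes[:, 0, :] + rel.sum(axis=1) / self.n_nodes[:, None], self.domain)

    def orientations(self) -> np.ndarray:
        ar = np.arange(self.n)
        o = min_image_displacement(self.nodes[ar, self.n_nodes - 1, :],
                                   self.nodes[:, 0, :], self.domain)
        return o / np.linalg.norm(o, axis=1, keepdims=True)

    @property
    def cells(self) -> list[Cell]:
        """Materialize plain Cell objects (copies) from the array state."""
        tc = self.config.turning
        out = []
        for i in range(self.n):
            params = CellParams(
                length=float(self.lengths[i]), n_nodes=int(self.n_nodes[i]),
                width=float(self.widths[i]), speed=float(self.speeds[i]),
                reversal_period=float(self.base_period[i]),
                turning_interval=float(self.turn_interval[i]),
                turning_angle_mean=tc.angle_mean, turning_angle_sd=tc.angle_sd,
                turning_angle_max=tc.angle_max,
            )
            out.append(Cell(
                id=i, nodes=self.nodes[i, : self.n_nodes[i]].copy(), params=params,
                path=self.path[i].copy(), reversal_phase=float(self.phase[i]),
                current_period=float(self.period[i]), last_turn_time=float(self.last_turn[i]),
                turning_interval=float(self.turn_interval[i]),
            ))
        return out


@dataclass
class RunResult:
    """Artifacts of one run: snapshot series, mode counts and event log."""

    config: SimConfig
    seed: int
    snapshot_times: np.ndarray            # (S,) minutes
    snapshot_centroids: np.ndarray        # (S, n, 2) µm
    snapshot_poles: np.ndarray            # (S, n, 2) µm
    snapshot_orientations: np.ndarray     # (S, n, 2) unit vectors
    mode_counts: np.ndarray               # (steps, 6) cells per mode per step
    events: pd.DataFrame                  # reversal/turn/collision/EPS events
    moved_per_step: np.ndarray            # (steps,)
    deposited_per_step: np.ndarray        # (steps,)
    state: SimulationState

    @property
    def final_centroids(self) -> np.ndarray:
        return self.snapshot_centroids[-1]


def initialize(config: SimConfig, seed: int | None = None) -> SimulationState:
    """Build the initial population state for a configuration."""
    return SimulationState(config, config.run.seed if seed is None else seed)


_EVENT_COLUMNS = ["step", "time_min", "cell_id", "mode", "angle_deg", "density", "period_min"]


def run(
    state: SimulationState,
    hours: float | None = None,
    record_events: bool = True,
    snapshot_every_min: float | None = None,
    on_snapshot: Callable[[SimulationState, list[float], list[np.ndarray]], bool] | None = None,
) -> RunResult:
    """Execute the main loop for ``hours`` of simulated time.

    ``on_snapshot`` may terminate a run early (e.g. once aggregation is
    confirmed); it receives the state plus the snapshot series so far and
    returns True to stop.
    """
    cfg = state.config
    if hours is None:
        hours = cfg.run.hours
    if snapshot_every_min is None:
        snapshot_every_min = cfg.run.snapshot_every_min
    n_steps = state.domain.n_steps(hours)
    snap_every = max(1, int(round(snapshot_every_min / state.domain.dt)))

    times: list[float] = []
    cents: list[np.ndarray] = []
    poles: list[np.ndarray] = []
    orients: list[np.ndarray] = []
    mode_counts = np.zeros((n_steps, len(Mode)), dtype=np.int64)
    moved = np.zeros(n_steps, dtype=np.int64)
    deposited = np.zeros(n_steps, dtype=np.int64)
    ev_frames: list[pd.DataFrame] = []

    def take_snapshot() -> None:
        times.append(state.time_min)
        cents.append(state.centroids())
        poles.append(state.nodes[:, 0, :].copy())
        orients.append(state.orientations())

    take_snapshot()
    n_done = 0
    for s in range(n_steps):
        rep = engine.step(state, record_events=record_events)
        mode_counts[s] = np.bincount(rep.modes, minlength=len(Mode))
        moved[s] = rep.n_moved
        deposited[s] = rep.n_deposited
        n_done = s + 1
        if record_events and len(rep.event_ids):
            ev_frames.append(pd.DataFrame({
                "step": rep.step, "time_min": rep.time_min,
                "cell_id": rep.event_ids,
                "mode": pd.Categorical.from_codes(
                    rep.event_modes, categories=[m.name for m in Mode]),
                "angle_deg": rep.event_angles,
                "density": rep.event_density, "period_min": rep.event_period,
            }))
        if state.step % snap_every == 0 or s == n_steps - 1:
            take_snapshot()
            if on_snapshot is not None and on_snapshot(state, times, cents):
                break

    if ev_frames:
        events = pd.concat(ev_frames, ignore_index=True)
    else:
        events = pd.DataFrame({c: pd.Series(dtype=f) for c, f in zip(
            _EVENT_COLUMNS, ["int64", "float", "int64", "object", "float", "float", "float"])})
    return RunResult(
        config=cfg, seed=state.seed,
        snapshot_times=np.asarray(times),
        snapshot_centroids=np.stack(cents),
        snapshot_poles=np.stack(poles),
        snapshot_orientations=np.stack(orients),
        mode_counts=mode_counts[:n_done], events=events,
        moved_per_step=moved[:n_done], deposited_per_step=deposited[:n_done],
        state=state,
    )


def write_run(result: RunResult, outdir: str, slime: bool = True) -> None:
    """Write run artifacts (trajectory.csv, events.csv, slime array, config)."""
    os.makedirs(outdir, exist_ok=True)
    S, n, _ = result.snapshot_poles.shape
    dt = result.state.domain.dt
    rows = {
        "step": np.repeat(np.round(result.snapshot_times / dt).astype(int), n),
        "time_min": np.repeat(result.snapshot_times, n),
        "cell_id": np.tile(np.arange(n), S),
        "x": result.snapshot_poles[:, :, 0].ravel(),
        "y": result.snapshot_poles[:, :, 1].ravel(),
        "ox": result.snapshot_orientations[:, :, 0].ravel(),
        "oy": result.snapshot_orientations[:, :, 1].ravel(),
    }
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "trajectory.csv"), index=False)
    result.events.to_csv(os.path.join(outdir, "events.csv"), index=False)
    if slime and result.state.field is not None:
        fld = result.state.field
        header = (f"bin_w={fld.bin_w:.6g} bin_h={fld.bin_h:.6g} "
                  f"width={fld.domain.width:.6g} height={fld.domain.height:.6g}")
        np.savetxt(os.path.join(outdir, f"slime_{result.state.step}.txt.gz"),
                   fld.counts, fmt="%g", header=header)
    result.config.to_yaml(os.path.join(outdir, "config_resolved.yaml"))
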