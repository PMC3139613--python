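"""Vectorized population step.

One call to :func:`step` advances every cell by one time step with the same
semantics as the per-cell reference operations in :mod:`myxosim.motility`:
strict mode priority (reversal > collision > EPS following > active turning
> straight), synchronous reads (all decisions see the positions other cells
had at the start of the step) and simultaneous writes.  Because decisions
never depend on within-step updates, no per-step iteration order is needed
and runs are bit-reproducible for a fixed seed and configuration.

Neighbour search uses a periodic cKD-tree over all cell nodes, rebuilt each
step — an exact superset of any radius query.  Random draws come from the
named substreams in a fixed order (collision, tiebreak, turning, reversal),
each consumed only by its own subsystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from . import paths
from .core import min_image_displacement, rotate, signed_angle, wrap
from .motility import Mode, truncated_normal
from .slime import batched_eps_directions

__all__ = ["step", "StepReport", "local_densities"]


@dataclass
class StepReport:
    """Per-step outcome summary: one mode per cell plus event metadata."""

    step: int
    time_min: float
    modes: np.ndarray                      # (n,) Mode codes
    n_moved: int = 0
    n_deposited: int = 0
    event_ids: np.ndarray = dc_field(default_factory=lambda: np.zeros(0, np.int64))
    event_modes: np.ndarray = dc_field(default_factory=lambda: np.zeros(0, np.int8))
    event_angles: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    event_density: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    event_period: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))


def local_densities(nodes: np.ndarray, n_nodes: np.ndarray, lengths: np.ndarray,
                    idx: np.ndarray, domain,
                    tree: cKDTree | None = None, owner: np.ndarray | None = None) -> np.ndarray:
    """Neighbour counts for the cells in ``idx`` (measuring-domain rule).

    A neighbour is any other cell with at least one node inside the
    axis-aligned square of side one cell length centred on the measuring
    cell's node centroid (boundary inclusive, minimum image).  A periodic
    node KD-tree (with each node's ``owner`` cell) may be passed to avoid
    the all-pairs scan.
    """
    if len(idx) == 0:
        return np.zeros(0, dtype=np.int64)
    n, max_nodes, _ = nodes.shape
    valid = np.arange(max_nodes)[None, :] < n_nodes[:, None]          # (n, 5)
    sub = nodes[idx]                                                   # (s, 5, 2)
    rel0 = min_image_displacement(sub[:, :1, :], sub, domain)
    rel0 = np.where(valid[idx][:, :, None], rel0, 0.0)
    centroid = sub[:, 0, :] + rel0.sum(axis=1) / n_nodes[idx][:, None]
    half = lengths[idx] / 2.0

    if tree is not None and owner is not None:
        centers = wrap(centroid, domain)
        cand_lists = tree.query_ball_point(centers, half * np.sqrt(2.0) + 1e-9)
        lens = np.array([len(c) for c in cand_lists])
        if lens.sum() == 0:
            return np.zeros(len(idx), dtype=np.int64)
        cand = np.concatenate([np.asarray(c, dtype=np.int64) for c in cand_lists if c])
        rows = np.repeat(np.arange(len(idx)), lens)
        rel = min_image_displacement(centers[rows], tree.data[cand], domain)
        inside = (np.abs(rel[:, 0]) <= half[rows]) & (np.abs(rel[:, 1]) <= half[rows])
        # distinct (measuring cell, neighbour) pairs, excluding self
        own = owner[cand[inside]]
        keep = own != idx[rows[inside]]
        key = rows[inside][keep] * np.int64(n) + own[keep]
        uniq_rows = np.unique(key) // n
        return np.bincount(uniq_rows, minlength=len(idx)).astype(np.int64)

    rel = min_image_displacement(centroid[:, None, None, :], nodes[None], domain)
    inside = (np.abs(rel[..., 0]) <= half[:, None, None]) & \
             (np.abs(rel[..., 1]) <= half[:, None, None]) & valid[None]
    hit = inside.any(axis=2)                                           # (s, n)
    hit[np.arange(len(idx)), idx] = False
    return hit.sum(axis=1)


def step(state, record_events: bool = False) -> StepReport:
    """Advance the whole population by one time step (in place)."""
    cfg = state.config
    domain = state.domain
    dt = domain.dt
    n = state.n
    ar = np.arange(n)
    t_now = state.step * dt
    rng = state.rng

    nodes = state.nodes                       # snapshot view; mutated only at the end
    poles = nodes[:, 0, :].copy()
    lag = nodes[ar, state.n_nodes - 1, :].copy()
    o = min_image_displacement(lag, poles, domain)
    o /= np.linalg.norm(o, axis=1, keepdims=True)

    modes = np.full(n, int(Mode.STRAIGHT), dtype=np.int8)
    angles = np.full(n, np.nan)

    # ---- (a) reversal clocks --------------------------------------------
    if cfg.reversal.enabled:
        state.phase += dt
        clock_rev = state.phase >= state.period
    else:
        clock_rev = np.zeros(n, dtype=bool)
    modes[clock_rev] = int(Mode.REVERSED)

    # ---- (b) collisions --------------------------------------------------
    partner = np.full(n, -1, dtype=np.int64)
    pnode = np.full(n, -1, dtype=np.int64)
    tree = None
    owner = None
    if cfg.collision.enabled and n > 1:
        valid = np.arange(state.max_nodes)[None, :] < state.n_nodes[:, None]
        pos = nodes[valid]
        owner = np.broadcast_to(ar[:, None], valid.shape)[valid]
        nidx = np.broadcast_to(np.arange(state.max_nodes)[None, :], valid.shape)[valid]
        tree = cKDTree(pos, boxsize=domain.size)
        k = min(6, len(pos))
        dist, j = tree.query(poles, k=k)
        dist = np.atleast_2d(dist.T).T.reshape(n, k)
        j = np.atleast_2d(j.T).T.reshape(n, k)
        j = np.minimum(j, len(pos) - 1)
        dist = np.where(owner[j] == ar[:, None], np.inf, dist)
        best = np.argmin(dist, axis=1)
        bestd = dist[ar, best]
        hit = (bestd < state.widths) & ~clock_rev
        bj = j[ar, best]
        partner[hit] = owner[bj[hit]]
        pnode[hit] = nidx[bj[hit]]
    else:
        hit = np.zeros(n, dtype=bool)

    pole_side = hit & (pnode > 0)
    pole_pole = hit & (pnode == 0)
    if pole_side.any():
        # a side contact steers the cell only while the two axes are not yet
        # aligned; cells already gliding (anti-)parallel in contact are a
        # stream, not a collision event, and stay open to slime and turning
        dots = (o[pole_side] * o[partner[pole_side]]).sum(axis=1)
        aligned = np.abs(dots) >= np.cos(np.deg2rad(cfg.collision.align_tol_deg))
        pole_side[np.nonzero(pole_side)[0][aligned]] = False
    hit = pole_side | pole_pole
    modes[pole_side] = int(Mode.COLLISION_ALIGN)
    modes[pole_pole] = int(Mode.COLLISION_POLE)

    # head-on: reverse or swerve with equal probability (collision stream)
    idx_pp = np.nonzero(pole_pole)[0]
    pp_reverse = np.zeros(0, dtype=np.int64)
    pp_turn = np.zeros(0, dtype=np.int64)
    pp_delta = np.zeros(0)
    if len(idx_pp):
        u = rng.collision.random(len(idx_pp))
        mag = rng.collision.uniform(cfg.collision.slight_turn_min,
                                    cfg.collision.slight_turn_max, len(idx_pp))
        sgn = np.where(rng.collision.random(len(idx_pp)) < 0.5, 1.0, -1.0)
        rev_branch = u < 0.5
        pp_reverse = idx_pp[rev_branch]
        pp_turn = idx_pp[~rev_branch]
        pp_delta = (sgn * mag)[~rev_branch]

    # side contact: align with the neighbour at an acute angle
    idx_ps = np.nonzero(pole_side)[0]
    ps_dirs = np.zeros((0, 2))
    if len(idx_ps):
        oj = o[partner[idx_ps]]
        dots = (o[idx_ps] * oj).sum(axis=1)
        tie = rng.tiebreak.random(len(idx_ps))
        sign = np.where(np.abs(dots) < 1e-12, np.where(tie < 0.5, 1.0, -1.0), np.sign(dots))
        ps_dirs = sign[:, None] * oj

    # ---- (c) EPS trail following ----------------------------------------
    # Trail following models a cell *encountering* slime that calls for a
    # turn.  A winning direction within the straight-ahead dead band is the
    # trail the cell is already on: it does not steer, and the cell stays
    # open to active turning (its clock keeps running).
    eps_cand = np.zeros(n, dtype=bool)
    straightish = np.zeros(n, dtype=bool)
    all_dirs_e = np.zeros((n, 2))
    if cfg.eps.enabled and state.field is not None:
        idx_e = np.nonzero(~clock_rev & ~hit)[0]
        if len(idx_e):
            radii = (state.lengths[idx_e] if cfg.eps.sense_radius is None
                     else np.full(len(idx_e), cfg.eps.sense_radius))
            dirs, ok = batched_eps_directions(
                state.field, poles[idx_e], o[idx_e], radii,
                n_sectors=cfg.eps.n_sectors,
                exclude=state.recent_bins[idx_e],
                rng=rng.tiebreak,
                saturation=cfg.eps.saturation,
            )
            eps_cand[idx_e] = ok
            all_dirs_e[idx_e] = dirs
            tol = cfg.eps.straight_tol_deg
            if tol is None:
                tol = 90.0 / cfg.eps.n_sectors
            head_dot = (dirs * o[idx_e]).sum(axis=1)
            straightish[idx_e] = ok & (head_dot >= np.cos(np.deg2rad(tol)))

    # ---- (d) active turning ---------------------------------------------
    idx_t = np.zeros(0, dtype=np.int64)
    turn_delta = np.zeros(0)
    if cfg.turning.enabled:
        can_turn = (~clock_rev & ~hit & (~eps_cand | straightish)
                    & (t_now - state.last_turn >= state.turn_interval))
        idx_t = np.nonzero(can_turn)[0]
        if len(idx_t):
            tc = cfg.turning
            mags = truncated_normal(rng.turning, tc.angle_mean, tc.angle_sd,
                                    lo=0.0, hi=tc.angle_max, size=len(idx_t))
            sgn = np.where(rng.turning.random(len(idx_t)) < 0.5, 1.0, -1.0)
            turn_delta = sgn * mags
            state.last_turn[idx_t] = t_now
            state.turn_interval[idx_t] = truncated_normal(
                rng.turning, tc.interval_mean, tc.interval_sd,
                lo=tc.interval_min, size=len(idx_t))
            modes[idx_t] = int(Mode.ACTIVE_TURN)

    eps_follow = eps_cand & ~straightish
    if len(idx_t):
        eps_follow[idx_t] = False
    idx_e_valid = np.nonzero(eps_follow)[0]
    eps_dirs = all_dirs_e[idx_e_valid]
    modes[idx_e_valid] = int(Mode.EPS_FOLLOW)

    # ---- apply reversals -------------------------------------------------
    idx_rev = np.nonzero(clock_rev)[0]
    idx_rev_all = np.concatenate([idx_rev, pp_reverse])
    density = np.zeros(0, dtype=np.int64)
    if len(idx_rev_all):
        if cfg.quorum.enabled:
            density = local_densities(nodes, state.n_nodes, state.lengths,
                                      idx_rev_all, domain, tree=tree, owner=owner)
            new_p = state.base_period[idx_rev_all].copy()
            for ci, (lo, hi, plo, phi) in enumerate(cfg.quorum.table.classes):
                in_class = (density >= lo) & (density <= hi)
                if in_class.any():
                    draws = rng.reversal.uniform(plo, phi, int(in_class.sum()))
                    new_p[in_class] = draws
            state.period[idx_rev_all] = new_p
        jj = np.arange(state.max_nodes)[None, :]
        src = np.clip(state.n_nodes[idx_rev_all, None] - 1 - jj, 0, state.max_nodes - 1)
        state.nodes[idx_rev_all] = state.nodes[idx_rev_all[:, None], src]
        state.phase[idx_rev_all] = 0.0
        state.path[idx_rev_all] = paths.path_from_chain(
            state.nodes[idx_rev_all], state.n_nodes[idx_rev_all], domain)

    # ---- assemble directions and advance movers -------------------------
    dirs = o.copy()
    if len(idx_ps):
        dirs[idx_ps] = ps_dirs
    if len(pp_turn):
        dirs[pp_turn] = rotate(o[pp_turn], pp_delta)
    if len(idx_e_valid):
        dirs[idx_e_valid] = eps_dirs
    if len(idx_t):
        dirs[idx_t] = rotate(o[idx_t], turn_delta)

    movers = np.ones(n, dtype=bool)
    movers[idx_rev_all] = False
    idx_m = np.nonzero(movers)[0]
    if len(idx_m):
        new_pole = state.path[idx_m, 0] + (state.speeds[idx_m] * dt)[:, None] * dirs[idx_m]
        new_path = paths.push_waypoint(state.path[idx_m], new_pole)
        chains = paths.chain_from_path(new_path, state.seg_len[idx_m], state.max_nodes)
        state.nodes[idx_m] = wrap(chains, domain)
        off = state.nodes[idx_m, 0, :] - new_path[:, 0, :]
        state.path[idx_m] = new_path + off[:, None, :]

    # ---- slime deposition and self-trail memory --------------------------
    # a cell follows trails laid by *other* cells: its own deposits over the
    # last self_exclude_steps stay invisible to its own sensing
    n_deposited = 0
    if state.field is not None:
        slot = state.step % state.recent_bins.shape[1]
        state.recent_bins[:, slot] = -1
        if cfg.eps.enabled and len(idx_m):
            lag_new = state.nodes[idx_m, state.n_nodes[idx_m] - 1, :]
            state.field.deposit(lag_new)
            state.recent_bins[idx_m, slot] = state.field.flat_indices(lag_new)
            n_deposited = len(idx_m)

    state.step += 1

    # ---- event logging ---------------------------------------------------
    if record_events:
        angles[:] = np.nan
        if len(idx_ps):
            angles[idx_ps] = signed_angle(o[idx_ps], ps_dirs)
        if len(pp_turn):
            angles[pp_turn] = pp_delta
        if len(idx_e_valid):
            angles[idx_e_valid] = signed_angle(o[idx_e_valid], eps_dirs)
        if len(idx_t):
            angles[idx_t] = turn_delta
        ev = np.nonzero(modes != int(Mode.STRAIGHT))[0]
        dens_all = np.full(n, np.nan)
        per_all = np.full(n, np.nan)
        if len(idx_rev_all):
            if cfg.quorum.enabled:
                dens_all[idx_rev_all] = density
            per_all[idx_rev_all] = state.period[idx_rev_all]
        return StepReport(state.step - 1, t_now, modes, len(idx_m), n_deposited,
                          ev, modes[ev], angles[ev], dens_all[ev], per_all[ev])
    return StepReport(state.step - 1, t_now, modes, len(idx_m), n_deposited)
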