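"""Quantify simulation outcomes.

The qualitative readouts of the developmental experiments — "an aggregation
center formed", "90% of cells joined it", "round and dense, stable" — are
operationalized here as computable metrics:

* an **aggregation center** is a density-connected cluster of cell
  centroids under the minimum-image metric: every member must have at least
  ``k`` neighbours within ``radius``, clusters below ``min_cells`` members
  are discarded;
* the **recruitment fraction** is the fraction of all cells belonging to
  any qualifying cluster;
* a cluster's **shape class** is derived from its rasterized footprint:
  circularity 4*pi*A/P^2, an interior-hole flag, the principal-axis
  elongation and the number of density peaks;
* **time to aggregation** is the earliest time at which recruitment reaches
  a threshold and the largest cluster is round — and stays round for a full
  hour of subsequent snapshots ("stable").

Every threshold is an explicit argument with the package default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.measure import perimeter as _perimeter

from .core import DomainConfig, wrap
from .motility import Mode

__all__ = [
    "ShapeClass",
    "Cluster",
    "AggregateReport",
    "detect_aggregates",
    "shape_classify",
    "rasterize",
    "time_to_aggregation",
    "round_stable_at_end",
    "behavior_stats",
    "BehaviorStats",
]

DEFAULT_RADIUS = 4.0       # one cell length, µm
DEFAULT_K = 10             # neighbours within radius required of a member
DEFAULT_MIN_FRACTION = 0.02
DEFAULT_RASTER_BIN = 2.0   # µm, footprint raster


class ShapeClass(str, Enum):
    NONE = "NONE"
    ROUND = "ROUND"
    ROUND_STABLE = "ROUND_STABLE"
    HOLED = "HOLED"
    LONG_MULTI = "LONG_MULTI"


@dataclass
class Cluster:
    members: np.ndarray          # cell indices
    centroid: np.ndarray         # periodic centroid, µm
    area: float                  # filled footprint area, µm^2
    circularity: float           # 4*pi*A/P^2 of the filled footprint
    shape: ShapeClass
    metrics: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AggregateReport:
    clusters: list[Cluster]
    recruitment_fraction: float
    shape_class: ShapeClass      # of the largest cluster (NONE if no cluster)
    time_to_aggregation: float | None = None   # minutes, None = not reached

    @property
    def largest(self) -> Cluster | None:
        return max(self.clusters, key=lambda c: c.size) if self.clusters else None


# ---------------------------------------------------------------------------
# density-connected clustering
# ---------------------------------------------------------------------------


def _periodic_centroid(points: np.ndarray, domain: DomainConfig) -> np.ndarray:
    """Centre of mass on the torus via the circular (angular) mean."""
    ang = 2.0 * np.pi * points / domain.size
    mean = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return wrap(mean / (2.0 * np.pi) * domain.size, domain)


def detect_aggregates(
    positions: np.ndarray,
    domain: DomainConfig,
    radius: float = DEFAULT_RADIUS,
    k: int = DEFAULT_K,
    min_cells: int | None = None,
    raster_bin: float = DEFAULT_RASTER_BIN,
) -> AggregateReport:
    """Detect aggregation centers among wrapped cell positions.

    A cluster is a maximal set of cells that each have at least ``k``
    neighbours within ``radius`` (minimum-image metric) and are mutually
    connected through such cells; clusters smaller than ``min_cells``
    (default 2% of the population) are discarded.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if min_cells is None:
        min_cells = max(2, int(round(DEFAULT_MIN_FRACTION * n)))
    if n == 0:
        return AggregateReport([], 0.0, ShapeClass.NONE)

    tree = cKDTree(wrap(positions, domain), boxsize=domain.size)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    counts = np.bincount(pairs.ravel(), minlength=n)
    core = counts >= k

    clusters: list[Cluster] = []
    if core.any() and len(pairs):
        both = core[pairs[:, 0]] & core[pairs[:, 1]]
        cp = pairs[both]
        graph = coo_matrix(
            (np.ones(len(cp)), (cp[:, 0], cp[:, 1])), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
        labels = np.where(core, labels, -1)
        for lab in np.unique(labels[labels >= 0]):
            members = np.nonzero(labels == lab)[0]
            if len(members) < min_cells:
                continue
            pts = positions[members]
            occ_counts = rasterize(pts, domain, raster_bin)
            shape, metrics = shape_classify(occ_counts > 0, raster_bin, occ_counts)
            clusters.append(Cluster(
                members=members,
                centroid=_periodic_centroid(pts, domain),
                area=metrics.get("area", 0.0),
                circularity=metrics.get("circularity", 0.0),
                shape=shape, metrics=metrics,
            ))
    recruited = sum(c.size for c in clusters)
    largest = max(clusters, key=lambda c: c.size) if clusters else None
    return AggregateReport(
        clusters=clusters,
        recruitment_fraction=recruited / n,
        shape_class=largest.shape if largest else ShapeClass.NONE,
    )


# ---------------------------------------------------------------------------
# footprint shape classification
# ---------------------------------------------------------------------------


def rasterize(positions: np.ndarray, domain: DomainConfig, bin_size: float = DEFAULT_RASTER_BIN) -> np.ndarray:
    """Count grid of positions on a periodic lattice of ~``bin_size`` bins."""
    nx = max(1, int(round(domain.width / bin_size)))
    ny = max(1, int(round(domain.height / bin_size)))
    p = wrap(np.atleast_2d(positions), domain)
    ix = np.minimum((p[:, 0] / domain.width * nx).astype(int), nx - 1)
    iy = np.minimum((p[:, 1] / domain.height * ny).astype(int), ny - 1)
    grid = np.zeros((nx, ny))
    np.add.at(grid, (ix, iy), 1.0)
    return grid


def _recenter(occ: np.ndarray) -> np.ndarray:
    """Roll a periodic grid so the occupied mass sits at the array centre."""
    nx, ny = occ.shape
    idx = np.nonzero(occ)
    shifts = []
    for ax, m in zip((0, 1), (nx, ny)):
        ang = 2.0 * np.pi * idx[ax] / m
        mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        center = (mean / (2.0 * np.pi)) * m
        shifts.append(int(round(m / 2 - center)))
    return np.roll(occ, shifts, axis=(0, 1))


def shape_classify(
    occ: np.ndarray,
    bin_size: float = DEFAULT_RASTER_BIN,
    density: np.ndarray | None = None,
    circ_threshold: float = 0.6,
    hole_threshold: float = 0.2,
    axis_ratio_threshold: float = 3.0,
    peak_threshold: int = 3,
) -> tuple[ShapeClass, dict]:
    """Classify a cluster's rasterized footprint.

    ``occ`` is a boolean occupancy grid on the (periodic) domain raster;
    ``density`` optionally carries per-bin cell counts for peak detection.
    Returns the class plus the measured metrics.  Classes:

    * HOLED       — interior holes exceed ``hole_threshold`` of the filled area;
    * LONG_MULTI  — principal-axis ratio >= 3, or >= 3 density peaks
      (several small aggregates strung together);
    * ROUND       — circularity 4*pi*A/P^2 >= ``circ_threshold`` and no hole;
    * NONE        — anything else (including degenerate footprints).
    """
    occ = np.asarray(occ, dtype=bool)
    if occ.sum() < 3:
        return ShapeClass.NONE, {"area": float(occ.sum()) * bin_size**2}
    rolled = _recenter(occ)
    dens = _recenter(np.asarray(density)) if density is not None else rolled.astype(float)
    closed = ndimage.binary_closing(rolled, structure=np.ones((3, 3)))
    filled = ndimage.binary_fill_holes(closed)
    hole_frac = (filled.sum() - closed.sum()) / filled.sum()
    area = float(filled.sum()) * bin_size**2
    per = _perimeter(filled, neighborhood=4) * bin_size
    circularity = float(min(1.0, 4.0 * np.pi * area / per**2)) if per > 0 else 1.0

    ii, jj = np.nonzero(filled)
    ci, cj = ii.mean(), jj.mean()
    cov = np.cov(np.stack([ii - ci, jj - cj]))
    evals = np.sort(np.linalg.eigvalsh(cov))
    axis_ratio = float(np.sqrt(evals[1] / evals[0])) if evals[0] > 1e-9 else np.inf

    # density peaks: connected plateaus of local maxima (a flat disc is one peak)
    smoothed = ndimage.gaussian_filter(dens * filled, sigma=2.0, mode="wrap")
    is_max = (smoothed >= ndimage.maximum_filter(smoothed, size=9, mode="wrap") - 1e-12) \
        & (smoothed > 0.35 * smoothed.max())
    _, n_peaks = ndimage.label(is_max)

    metrics = {
        "area": area, "perimeter": float(per), "circularity": circularity,
        "hole_fraction": float(hole_frac), "axis_ratio": axis_ratio,
        "n_peaks": n_peaks,
    }
    if hole_frac > hole_threshold:
        return ShapeClass.HOLED, metrics
    if axis_ratio >= axis_ratio_threshold or n_peaks >= peak_threshold:
        return ShapeClass.LONG_MULTI, metrics
    if circularity >= circ_threshold:
        return ShapeClass.ROUND, metrics
    return ShapeClass.NONE, metrics


# ---------------------------------------------------------------------------
# time to aggregation
# ---------------------------------------------------------------------------


def _snapshot_condition(positions: np.ndarray, domain: DomainConfig,
                        recruit_threshold: float, **detect_kw) -> tuple[bool, AggregateReport]:
    rep = detect_aggregates(positions, domain, **detect_kw)
    ok = (rep.recruitment_fraction >= recruit_threshold
          and rep.shape_class is ShapeClass.ROUND)
    return ok, rep


def time_to_aggregation(
    times: Sequence[float],
    centroid_series: np.ndarray,
    domain: DomainConfig,
    recruit_threshold: float = 0.8,
    persist_min: float = 60.0,
    **detect_kw,
) -> float | None:
    """Earliest time (minutes) of a persistent round aggregation center.

    The criterion holds at ``t*`` when recruitment reaches the threshold
    and the largest cluster is ROUND both at ``t*`` and throughout the
    following ``persist_min`` of snapshots (which must exist — a candidate
    too close to the end of the horizon cannot be confirmed).  Returns
    ``None`` when never reached.
    """
    times = np.asarray(times, dtype=float)
    ok = np.array([
        _snapshot_condition(centroid_series[i], domain, recruit_threshold, **detect_kw)[0]
        for i in range(len(times))
    ])
    for i in np.nonzero(ok)[0]:
        window = (times > times[i]) & (times <= times[i] + persist_min)
        if times[-1] < times[i] + persist_min:
            continue
        if ok[window].all():
            return float(times[i])
    return None


def round_stable_at_end(
    times: Sequence[float],
    centroid_series: np.ndarray,
    domain: DomainConfig,
    persist_min: float = 60.0,
    **detect_kw,
) -> bool:
    """Largest cluster ROUND at the final snapshot and over the trailing hour."""
    times = np.asarray(times, dtype=float)
    sel = np.nonzero(times >= times[-1] - persist_min)[0]
    for i in sel:
        rep = detect_aggregates(centroid_series[i], domain, **detect_kw)
        if rep.shape_class is not ShapeClass.ROUND:
            return False
    return True


# ---------------------------------------------------------------------------
# behavioural statistics
# ---------------------------------------------------------------------------


@dataclass
class BehaviorStats:
    """Pooled per-event statistics recovered from a run's event log."""

    reversal_intervals: np.ndarray
    turning_angles: np.ndarray
    turning_intervals: np.ndarray
    mode_frequencies: dict[str, float]

    @property
    def mean_reversal_interval(self) -> float:
        return float(np.mean(self.reversal_intervals)) if len(self.reversal_intervals) else np.nan

    @property
    def mean_turning_angle(self) -> float:
        return float(np.mean(self.turning_angles)) if len(self.turning_angles) else np.nan

    @property
    def mean_turning_interval(self) -> float:
        return float(np.mean(self.turning_intervals)) if len(self.turning_intervals) else np.nan


def behavior_stats(events: pd.DataFrame, mode_counts: np.ndarray | None = None) -> BehaviorStats:
    """Recover behavioural parameters from an event log.

    Reversal intervals are per-cell differences between successive clock
    reversals; turning angles are the logged active-turn magnitudes and
    turning intervals the per-cell gaps between successive turns.  A cell
    with fewer than two events of a kind contributes no interval (absent,
    not zero).
    """
    def _intervals(mode: str) -> np.ndarray:
        sub = events[events["mode"] == mode]
        if not len(sub):
            return np.zeros(0)
        d = sub.sort_values("time_min").groupby("cell_id")["time_min"].diff().dropna()
        return d.to_numpy()

    turns = events[events["mode"] == Mode.ACTIVE_TURN.name]
    freqs: dict[str, float] = {}
    if mode_counts is not None and mode_counts.sum():
        total = mode_counts.sum()
        freqs = {m.name: float(mode_counts[:, m].sum() / total) for m in Mode}
    return BehaviorStats(
        reversal_intervals=_intervals(Mode.REVERSED.name),
        turning_angles=np.abs(turns["angle_deg"].to_numpy(dtype=float)),
        turning_intervals=_intervals(Mode.ACTIVE_TURN.name),
        mode_frequencies=freqs,
    )
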