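"""Periodic EPS-slime lattice: deposition, sensing and trail-following.

Gliding cells secrete extracellular polysaccharide (EPS) slime from the
lagging pole; pre-existing trails bias movement because a cell crossing a
trail turns onto it at an acute angle.  The original description keeps every
deposited slime point individually; here the domain is quantized into small
bins (0.5 µm by default) holding deposition counts, which preserves the
"region with higher EPS concentration" semantics at O(1) deposit cost and
bounded memory.  Slime never decays: counts only grow.

Sensing works in the forward semicircle ahead of the leading pole (radius of
roughly one cell length, the reach of a type-IV pilus).  The semicircle is
split into equal angular sectors; the cell steers toward the count-weighted
centroid of the sector holding the most slime, which by construction is an
acute turn relative to the current orientation.
"""

from __future__ import annotations

from typing import Sequence

import numba
import numpy as np

from .core import Cell, DomainConfig, min_image_displacement, orientation, unit, wrap

__all__ = ["SlimeField", "deposit", "sense_region", "eps_direction", "batched_eps_directions"]


class SlimeField:
    """2-D lattice of EPS deposition counts covering a periodic domain.

    The nominal ``bin_size`` is adjusted per axis so the lattice tiles the
    domain exactly.  ``deposit_rate`` is the number of EPS points a cell
    lays down per moving step.
    """

    def __init__(self, domain: DomainConfig, bin_size: float = 0.5, deposit_rate: float = 1.0):
        if bin_size <= 0 or deposit_rate <= 0:
            raise ValueError("bin_size and deposit_rate must be positive")
        self.domain = domain
        self.nx = max(1, int(round(domain.width / bin_size)))
        self.ny = max(1, int(round(domain.height / bin_size)))
        self.bin_w = domain.width / self.nx
        self.bin_h = domain.height / self.ny
        self.deposit_rate = float(deposit_rate)
        self.counts = np.zeros((self.nx, self.ny), dtype=np.float64)
        self._stencils: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    # -- indexing ----------------------------------------------------------

    def bin_indices(self, positions: np.ndarray) -> np.ndarray:
        """Integer (ix, iy) of the bins containing wrapped ``positions``."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        ix = np.minimum((p[:, 0] / self.bin_w).astype(np.int64), self.nx - 1)
        iy = np.minimum((p[:, 1] / self.bin_h).astype(np.int64), self.ny - 1)
        return np.stack([ix, iy], axis=1)

    def flat_indices(self, positions: np.ndarray) -> np.ndarray:
        idx = self.bin_indices(positions)
        return idx[:, 0] * self.ny + idx[:, 1]

    def bin_centers(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        return np.stack(
            [(idx[..., 0] + 0.5) * self.bin_w, (idx[..., 1] + 0.5) * self.bin_h], axis=-1
        )

    @property
    def total(self) -> float:
        """Total deposited EPS; nondecreasing over a run (no decay)."""
        return float(self.counts.sum())

    # -- deposition --------------------------------------------------------

    def deposit(self, positions: np.ndarray, rate: float | None = None) -> None:
        """Add ``rate`` EPS points to the bin containing each position."""
        idx = self.bin_indices(positions)
        np.add.at(self.counts, (idx[:, 0], idx[:, 1]), self.deposit_rate if rate is None else rate)

    # -- stencil cache -----------------------------------------------------

    def _stencil(self, max_radius: float) -> tuple[np.ndarray, np.ndarray]:
        """Integer bin offsets probing a disc of ``max_radius`` around a bin.

        Offsets are clipped to at most half the lattice in each axis so a
        bin is never probed twice through the periodic wrap.
        """
        key = round(max_radius, 9)
        if key not in self._stencils:
            nrx = min(int(np.ceil(max_radius / self.bin_w)) + 1, (self.nx - 1) // 2)
            nry = min(int(np.ceil(max_radius / self.bin_h)) + 1, (self.ny - 1) // 2)
            ox, oy = np.meshgrid(np.arange(-nrx, nrx + 1), np.arange(-nry, nry + 1), indexing="ij")
            offsets = np.stack([ox.ravel(), oy.ravel()], axis=1)
            # displacement of probed bin centre relative to the pole's bin centre;
            # the pole sits at most half a bin diagonal from its bin centre
            disp = offsets * np.array([self.bin_w, self.bin_h])
            half_diag = 0.5 * np.hypot(self.bin_w, self.bin_h)
            r = np.hypot(disp[:, 0], disp[:, 1])
            keep = r <= max_radius + half_diag + 1e-9
            offsets, r = offsets[keep], r[keep]
            order = np.argsort(r)  # radially sorted: sensing can stop early
            offsets, r = offsets[order], r[order]
            dmin = np.maximum(r - half_diag, 0.0)
            self._stencils[key] = (offsets, dmin**2)
        return self._stencils[key]


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def deposit(field: SlimeField, lagging_pole: np.ndarray) -> SlimeField:
    """Deposit one unit of slime (``deposit_rate``) at the lagging pole."""
    field.deposit(np.atleast_2d(lagging_pole))
    return field


def sense_region(
    field: SlimeField,
    leading_pole: np.ndarray,
    heading: np.ndarray,
    radius: float,
    exclude_bins: Sequence[int] = (),
) -> list[tuple[np.ndarray, float]]:
    """Nonzero slime bins in the forward semicircle ahead of the leading pole.

    Returns ``(bin_centre, count)`` pairs for every bin whose minimum-image
    displacement ``d`` from the pole satisfies ``|d| <= radius`` and
    ``d . heading > 0``.  ``exclude_bins`` (flat indices) removes the cell's
    own freshly deposited trail from its sensing.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pole = np.asarray(leading_pole, dtype=float)
    heading = np.asarray(heading, dtype=float)
    offsets, _ = field._stencil(radius)
    pbin = field.bin_indices(pole[None, :])[0]
    bins = (pbin[None, :] + offsets) % np.array([field.nx, field.ny])
    centers = field.bin_centers(bins)
    d = min_image_displacement(pole, centers, field.domain)
    counts = field.counts[bins[:, 0], bins[:, 1]]
    mask = (
        (counts > 0)
        & (np.hypot(d[:, 0], d[:, 1]) <= radius)
        & (d @ heading > 0)
    )
    if len(exclude_bins):
        flat = bins[:, 0] * field.ny + bins[:, 1]
        mask &= ~np.isin(flat, np.asarray(exclude_bins))
    return [(centers[i], float(counts[i])) for i in np.nonzero(mask)[0]]


def eps_direction(
    field: SlimeField,
    cell: Cell,
    sensed: list[tuple[np.ndarray, float]],
    n_sectors: int = 6,
    rng: np.random.Generator | None = None,
    saturation: float | None = None,
) -> np.ndarray | None:
    """Trail-following direction from a sensed slime neighbourhood.

    The forward semicircle is split into ``n_sectors`` equal angular sectors
    about the orientation; the sector with the largest slime count wins
    (ties broken toward the smaller turning angle, then randomly) and the
    returned unit vector points at the count-weighted centroid of its bins.
    Returns ``None`` when nothing eligible is sensed.  The result is always
    at an acute angle to the cell's orientation.

    ``saturation`` caps the count a single bin contributes: sensing then
    responds to how much *area* a sector covers with slime rather than to
    how often one line has been retraced (receptor saturation).
    """
    if not sensed:
        return None
    if saturation is not None:
        sensed = [(c, min(cnt, saturation)) for c, cnt in sensed]
    o = orientation(cell, field.domain)
    pole = cell.leading_pole
    width = 180.0 / n_sectors
    sums = np.zeros(n_sectors)
    vecs = np.zeros((n_sectors, 2))
    for center, count in sensed:
        d = min_image_displacement(pole, np.asarray(center, dtype=float), field.domain)
        dot = float(d @ o)
        if dot <= 0:
            continue
        ang = np.rad2deg(np.arctan2(o[0] * d[1] - o[1] * d[0], dot))
        k = min(int((ang + 90.0) // width), n_sectors - 1)
        sums[k] += count
        vecs[k] += count * d
    if sums.max() <= 0:
        return None
    centers_ang = np.abs(-90.0 + (np.arange(n_sectors) + 0.5) * width)
    tie_eps = np.zeros(n_sectors) if rng is None else rng.random(n_sectors)
    key = sums - centers_ang * 1e-6 / 90.0 + tie_eps * 1e-9
    key[sums <= 0] = -np.inf
    winner = int(np.argmax(key))
    return unit(vecs[winner])


def batched_eps_directions(
    field: SlimeField,
    poles: np.ndarray,
    headings: np.ndarray,
    radii: np.ndarray,
    n_sectors: int = 6,
    exclude: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    saturation: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized trail-following direction for many cells at once.

    Same semantics as :func:`sense_region` + :func:`eps_direction`, computed
    for ``m`` cells with one lattice stencil.  ``exclude`` is an ``(m, k)``
    array of flat bin indices (-1 padding) removed from each cell's own
    sensing.  Returns ``(directions (m, 2), valid (m,))``.
    """
    poles = np.atleast_2d(poles)
    headings = np.atleast_2d(headings)
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    m = len(poles)
    if m == 0 or field.counts.max() == 0:
        return np.zeros((m, 2)), np.zeros(m, dtype=bool)
    offsets, _ = field._stencil(float(radii.max()))
    pbin = field.bin_indices(poles)  # (m, 2)
    pole_off = field.bin_centers(pbin) - poles  # (m, 2), sub-bin offset

    width = 180.0 / n_sectors
    # sector boundaries without arctan2: within the forward half-plane,
    # angle >= b  <=>  cross >= tan(b) * dot
    tans = np.tan(np.deg2rad(-90.0 + np.arange(1, n_sectors) * width))
    centers_ang = np.abs(-90.0 + (np.arange(n_sectors) + 0.5) * width)
    tie = rng.random((m, n_sectors)) if rng is not None else np.zeros((m, n_sectors))
    if exclude is None or not exclude.size:
        exclude = np.full((m, 1), -1, dtype=np.int64)
    sat = -1.0 if saturation is None else float(saturation)

    _, dmin2 = field._stencil(float(radii.max()))
    return _sense_kernel(
        field.counts, pbin[:, 0], pbin[:, 1], pole_off[:, 0], pole_off[:, 1],
        headings[:, 0], headings[:, 1], radii**2,
        np.ascontiguousarray(offsets), dmin2,
        offsets[:, 0] * field.bin_w, offsets[:, 1] * field.bin_h,
        np.ascontiguousarray(exclude), tans, centers_ang, tie, sat,
    )


@numba.njit(cache=False)
def _sense_kernel(counts, pbx, pby, pox, poy, hx, hy, r2, offs, dmin2, dispx, dispy,
                  excl, tans, centers_ang, tie, sat):  # pragma: no cover
    nx, ny = counts.shape
    m = pbx.shape[0]
    n_off = offs.shape[0]
    ns = tans.shape[0] + 1
    dirs = np.zeros((m, 2))
    valid = np.zeros(m, dtype=np.bool_)
    sums = np.zeros(ns)
    vx = np.zeros(ns)
    vy = np.zeros(ns)
    for i in range(m):
        for k in range(ns):
            sums[k] = 0.0
            vx[k] = 0.0
            vy[k] = 0.0
        for j in range(n_off):
            if dmin2[j] > r2[i]:
                break  # offsets are radially sorted: nothing closer remains
            bx = (pbx[i] + offs[j, 0]) % nx
            by = (pby[i] + offs[j, 1]) % ny
            c = counts[bx, by]
            if c <= 0.0:
                continue
            dx = dispx[j] + pox[i]
            dy = dispy[j] + poy[i]
            dot = hx[i] * dx + hy[i] * dy
            if dot <= 0.0 or dx * dx + dy * dy > r2[i]:
                continue
            flat = bx * ny + by
            skip = False
            for e in range(excl.shape[1]):
                if excl[i, e] == flat:
                    skip = True
                    break
            if skip:
                continue
            if sat > 0.0 and c > sat:
                c = sat
            cr = hx[i] * dy - hy[i] * dx
            k = 0
            for b in range(tans.shape[0]):
                if cr >= tans[b] * dot:
                    k += 1
            sums[k] += c
            vx[k] += c * dx
            vy[k] += c * dy
        best = -1
        bestkey = -1e300
        for k in range(ns):
            if sums[k] <= 0.0:
                continue
            key = sums[k] - centers_ang[k] * 1e-6 / 90.0 + tie[i, k] * 1e-9
            if key > bestkey:
                bestkey = key
                best = k
        if best >= 0:
            norm = np.sqrt(vx[best] ** 2 + vy[best] ** 2)
            if norm > 0.0:
                dirs[i, 0] = vx[best] / norm
                dirs[i, 1] = vy[best] / norm
                valid[i] = True
    return dirs, valid
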