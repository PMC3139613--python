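"""Simulation configuration, experiment presets and desk-scaling.

Every behavioural subsystem (reversal, quorum sensing, EPS deposition and
following, collisions, active turning) has its own settings block with an
``enabled`` switch, so mutant presets differ from the wild type only in the
parameters their genetics affect:

* ``WT_LOW``   — 100 cells, 2 h: the low-density gliding-pattern experiment.
* ``WT_DEV``   — 5000 cells, 12 h: developmental aggregation.
* ``SW504``    — no EPS production or following (dif mutant).
* ``SW600``    — reversal period 120 min, quorum sensing off (hypo-reversing
  frz mutant).
* ``SW601``    — reversal period 2 min, quorum sensing off (hyper-reversing
  frz mutant).
* ``ANGLE_SWEEP`` — the wild-type developmental run with the mean active
  turning angle swept over {5, 15, 30, 45, 60} degrees, up to 20 h.

Domain sizes are model choices (100x100 µm at low density, 300x300 µm for
development); :func:`scale_preset` shrinks cell count and domain area by the
same factor so the number density — the controlled variable — is preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .motility import QuorumTable

__all__ = ["SimConfig", "get_preset", "scale_preset", "PRESET_NAMES"]


@dataclass
class DomainSettings:
    width: float = 100.0
    height: float = 100.0
    dt: float = 1.0 / 3.0


@dataclass
class CellSettings:
    n: int = 100
    length_range: tuple[float, float] = (3.0, 5.0)
    speed: float = 4.5
    n_nodes: int | None = None  # None: round(length) clamped to [3, 5]


@dataclass
class ReversalSettings:
    enabled: bool = True
    mean: float = 6.24
    sd: float = 0.5
    min_period: float = 0.1  # truncation keeping sampled periods positive


@dataclass
class QuorumSettings:
    enabled: bool = True
    table: QuorumTable = field(default_factory=QuorumTable)


@dataclass
class EpsSettings:
    enabled: bool = True
    deposit_rate: float = 1.0
    bin_size: float = 0.5
    sense_radius: float | None = None  # None: one cell length, per cell
    n_sectors: int = 6
    straight_tol_deg: float = 0.0          # dead band freeing a due turn; 0 = off
    saturation: float | None = None        # per-bin cap on sensed counts
    self_exclude_steps: int = 5            # own-trail memory (steps) hidden from sensing


@dataclass
class CollisionSettings:
    enabled: bool = True
    slight_turn_min: float = 10.0  # head-on swerve angle range, degrees
    slight_turn_max: float = 30.0
    align_tol_deg: float = 15.0    # axes already within this: no alignment event


@dataclass
class TurningSettings:
    enabled: bool = True
    angle_mean: float = 30.0
    angle_sd: float = 10.0
    angle_max: float = 90.0
    interval_mean: float = 3.0
    interval_sd: float = 1.0
    interval_min: float = 0.1


@dataclass
class RunSettings:
    hours: float = 2.0
    seed: int = 0
    snapshot_every_min: float = 15.0


@dataclass
class SimConfig:
    """Full resolved configuration of one simulation run."""

    domain: DomainSettings = field(default_factory=DomainSettings)
    cells: CellSettings = field(default_factory=CellSettings)
    reversal: ReversalSettings = field(default_factory=ReversalSettings)
    quorum: QuorumSettings = field(default_factory=QuorumSettings)
    eps: EpsSettings = field(default_factory=EpsSettings)
    collision: CollisionSettings = field(default_factory=CollisionSettings)
    turning: TurningSettings = field(default_factory=TurningSettings)
    run: RunSettings = field(default_factory=RunSettings)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quorum"]["table"] = [list(c) for c in self.quorum.table.classes]
        d["cells"]["length_range"] = list(self.cells.length_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = {k: dict(v) for k, v in data.items()}
        if "table" in data.get("quorum", {}):
            data["quorum"]["table"] = QuorumTable(
                tuple(tuple(c) for c in data["quorum"]["table"])
            )
        if "length_range" in data.get("cells", {}):
            data["cells"]["length_range"] = tuple(data["cells"]["length_range"])
        sections = {f.name: f.type for f in dataclasses.fields(cls)}
        types = dict(
            domain=DomainSettings, cells=CellSettings, reversal=ReversalSettings,
            quorum=QuorumSettings, eps=EpsSettings, collision=CollisionSettings,
            turning=TurningSettings, run=RunSettings,
        )
        kwargs = {name: types[name](**data[name]) for name in sections if name in data}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("WT_LOW", "WT_DEV", "ANGLE_SWEEP", "SW504", "SW600", "SW601")


def _wt_dev() -> SimConfig:
    # 5000 cells at 0.083 cells/µm² — dense enough for streaming and for the
    # quorum classes to engage inside streams and centers (the developmental
    # assay spots cells near-confluent; the exact density is a model choice)
    cfg = SimConfig()
    cfg.cells.n = 5000
    cfg.domain.width = cfg.domain.height = 246.0
    cfg.run.hours = 12.0
    return cfg


def get_preset(name: str, turning_angle_mean: float | None = None) -> SimConfig:
    """Build the configuration for a named experiment preset.

    ``turning_angle_mean`` applies to ``ANGLE_SWEEP`` (and overrides any
    preset for convenience).
    """
    name = name.upper()
    if name == "WT_LOW":
        cfg = SimConfig()  # defaults: 100 cells, 100x100 µm, 2 h
    elif name == "WT_DEV":
        cfg = _wt_dev()
    elif name == "ANGLE_SWEEP":
        cfg = _wt_dev()
        cfg.run.hours = 20.0
    elif name == "SW504":
        cfg = _wt_dev()
        cfg.eps.enabled = False
    elif name == "SW600":
        cfg = _wt_dev()
        cfg.reversal.mean, cfg.reversal.sd = 120.0, 0.0
        cfg.quorum.enabled = False
    elif name == "SW601":
        cfg = _wt_dev()
        cfg.reversal.mean, cfg.reversal.sd = 2.0, 0.0
        cfg.quorum.enabled = False
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if turning_angle_mean is not None:
        cfg.turning.angle_mean = float(turning_angle_mean)
    return cfg


def scale_preset(config: SimConfig, factor: float) -> SimConfig:
    """Scale cell count and domain area together, preserving number density.

    Behavioural parameters are untouched, so a desk-scale run probes the
    same local physics as the full-size experiment.
    """
    if not (0 < factor <= 1):
        raise ValueError("scale factor must be in (0, 1]")
    cfg = SimConfig.from_dict(config.to_dict())  # deep copy
    cfg.cells.n = max(1, int(round(config.cells.n * factor)))
    side = float(factor) ** 0.5
    cfg.domain.width = config.domain.width * side
    cfg.domain.height = config.domain.height * side
    return cfg
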