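import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myxosim.core import Cell, CellParams, DomainConfig
from myxosim.paths import straight_path

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def domain():
    return DomainConfig(100.0, 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell(pole, heading, length=4.0, cell_id=0, **params) -> Cell:
    """Straight cell with its leading pole at ``pole`` pointing along ``heading``."""
    heading = np.asarray(heading, dtype=float)
    heading = heading / np.linalg.norm(heading)
    p = CellParams.from_length(length, **params)
    pole = np.asarray(pole, dtype=float)
    nodes = pole[None, :] - np.arange(p.n_nodes)[:, None] * p.segment_length * heading
    path = straight_path(pole[None], heading[None], p.speed / 3.0)[0]
    return Cell(id=cell_id, nodes=nodes, params=p, path=path)
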