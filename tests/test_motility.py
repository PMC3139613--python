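"""Per-cell motility rules: reversal clock, quorum, collisions, turning."""

import numpy as np
import pytest

from myxosim.core import DomainConfig, RngStream, orientation, wrap
from myxosim.motility import (
    Mode,
    QuorumTable,
    advance,
    check_active_turn,
    check_reversal,
    decide,
    detect_collision,
    local_density,
    modulate_period,
    resolve_pole_to_pole,
    resolve_pole_to_side,
    truncated_normal,
)
from myxosim.slime import SlimeField, deposit

from conftest import make_cell

DT = 1.0 / 3.0


class TestReversalClock:
    def test_threshold_crossing_reverses(self, domain):
        cell = make_cell((50, 50), (1, 0))
        cell.current_period = 5.0
        cell.reversal_phase = 5.0 - DT / 2
        o_before = orientation(cell, domain)
        assert check_reversal(cell, DT, domain)
        assert cell.reversal_phase == 0.0
        assert np.allclose(orientation(cell, domain), -o_before)

    def test_first_reversal_on_step_19(self, domain):
        # T = 6.24 min, dt = 1/3 min: 19 * (1/3) = 6.33 >= 6.24
        cell = make_cell((50, 50), (1, 0))
        cell.current_period = 6.24
        steps = 0
        while not check_reversal(cell, DT, domain):
            steps += 1
        assert steps + 1 == 19

    def test_free_cell_retraces_path(self, domain, rng):
        # two consecutive reversals bring an undisturbed cell back over
        # the same straight segment
        cell = make_cell((50, 50), (1, 0))
        cell.current_period = 1.9  # fires on the 6th step (6 * 1/3 min >= 1.9)
        cell.reversal_phase = 0.0
        initial_nodes = cell.nodes.copy()
        stream = RngStream(3)
        poles, modes = [], []
        for _ in range(12):  # one full period = 6 steps
            out = decide(cell, [], None, 0.0, domain, stream,
                         eps_enabled=False, turning_enabled=False)
            advance(cell, out, DT, domain)
            poles.append(cell.leading_pole.copy())
            modes.append(out.mode)
        assert modes[5] is Mode.REVERSED and modes[11] is Mode.REVERSED
        # every pole position stays on the same straight segment
        poles = np.array(poles)
        assert np.allclose(poles[:, 1], 50.0, atol=1e-9)
        assert poles[:, 0].min() >= 46.0 - 1e-9 and poles[:, 0].max() <= 57.5 + 1e-9
        # after a full out-and-back cycle the body is exactly where it started
        assert np.allclose(cell.nodes, initial_nodes, atol=1e-9)


class TestLocalDensity:
    def test_isolated_cell(self, domain):
        cell = make_cell((50, 50), (1, 0))
        assert local_density(cell, [cell], domain) == 0

    def test_measuring_domain_counts_five(self, domain):
        # five neighbours with a node inside the square, two outside
        # measuring square: centroid (48, 50), side 4 -> x in [46, 50], y in [48, 52]
        k = make_cell((50, 50), (1, 0), length=4.0, cell_id=0)
        inside = [make_cell((46.5 + 0.75 * i, 49.0), (0, 1), cell_id=1 + i) for i in range(5)]
        outside = [make_cell((80, 80), (1, 0), cell_id=10),
                   make_cell((56, 50), (1, 0), cell_id=11)]  # nodes reach only x = 52
        cells = [k] + inside + outside
        assert local_density(k, cells, domain) == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, domain, seed):
        rng = np.random.default_rng(seed)
        cells = [make_cell(rng.uniform(40, 60, 2), rng.normal(size=2), cell_id=i)
                 for i in range(30)]
        cell = cells[0]
        center = cell.centroid(domain)
        half = cell.params.length / 2
        expected = 0
        for other in cells[1:]:
            rel = other.nodes - center
            rel -= domain.size * np.round(rel / domain.size)
            if np.any((np.abs(rel[:, 0]) <= half) & (np.abs(rel[:, 1]) <= half)):
                expected += 1
        assert local_density(cell, cells, domain) == expected


class TestQuorum:
    def test_table_ranges(self):
        t = QuorumTable()
        assert t.lookup(2) is None
        assert t.lookup(7) == (8.0, 12.0)
        assert t.lookup(150) == (30.0, 40.0)
        assert t.lookup(5000) == (300.0, 360.0)

    def test_overlapping_table_rejected(self):
        with pytest.raises(ValueError):
            QuorumTable(classes=((5, 20, 8.0, 12.0), (15, 99, 15.0, 30.0)))

    @pytest.mark.parametrize("density, lo, hi", [(7, 8, 12), (150, 30, 40), (1500, 300, 360)])
    def test_modulation_draws_in_range(self, domain, density, lo, hi):
        stream = RngStream(0)
        for _ in range(20):
            cell = make_cell((50, 50), (1, 0))
            p = modulate_period(cell, density, QuorumTable(), stream)
            assert lo <= p <= hi

    def test_low_density_restores_baseline(self, domain):
        cell = make_cell((50, 50), (1, 0))
        cell.current_period = 35.0
        p = modulate_period(cell, 2, QuorumTable(), RngStream(0))
        assert p == cell.params.reversal_period


class TestCollision:
    def test_pole_to_side_hit(self, domain):
        cell = make_cell((50, 50), (1, 0), length=4.0)  # width 0.4
        partner = make_cell((50.3 + 4.0 / 3, 50.0), (1, 0), cell_id=1)  # its node 1 at 50.3
        hit = detect_collision(cell, [partner], domain)
        assert hit is not None
        assert hit[0].id == 1 and hit[1] == 1

    def test_boundary_distance_is_no_collision(self, domain):
        cell = make_cell((50, 50), (1, 0), length=4.0)
        partner = make_cell((52.0, 50.0), (1, 0), cell_id=1)
        # nearest node just beyond one cell width: no collision
        partner.nodes[1] = [50.0 + cell.params.width + 1e-9, 50.0]
        assert detect_collision(cell, [partner], domain) is None
        # just inside: collision
        partner.nodes[1] = [50.0 + cell.params.width - 1e-6, 50.0]
        assert detect_collision(cell, [partner], domain) is not None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_brute_force(self, domain, seed):
        rng = np.random.default_rng(seed)
        cells = [make_cell(rng.uniform(45, 55, 2), rng.normal(size=2), cell_id=i)
                 for i in range(20)]
        cell = cells[0]
        hit = detect_collision(cell, cells, domain)
        best = None
        for other in cells[1:]:
            rel = other.nodes - cell.leading_pole
            rel -= domain.size * np.round(rel / domain.size)
            d = np.linalg.norm(rel, axis=1)
            j = int(np.argmin(d))
            if d[j] < cell.params.width and (best is None or d[j] < best[0]):
                best = (d[j], other.id, j)
        if best is None:
            assert hit is None
        else:
            assert hit is not None and hit[0].id == best[1] and hit[1] == best[2]

    def test_pole_to_side_acute_alignment(self, domain):
        stream = RngStream(0)
        cell = make_cell((50, 50), (1, 0))
        partner = make_cell((52, 52), (0.8, 0.6), cell_id=1)
        d = resolve_pole_to_side(cell, partner, domain, stream)
        assert np.allclose(d, orientation(partner, domain))
        anti = make_cell((52, 52), (-1, 0), cell_id=2)
        d = resolve_pole_to_side(cell, anti, domain, stream)
        assert np.allclose(d, [1, 0])

    def test_perpendicular_tie_deterministic_per_seed(self, domain):
        cell = make_cell((50, 50), (0, 1))
        partner = make_cell((52, 52), (1, 0), cell_id=1)
        d1 = resolve_pole_to_side(cell, partner, domain, RngStream(11))
        d2 = resolve_pole_to_side(cell, partner, domain, RngStream(11))
        assert np.allclose(d1, d2)
        assert abs(d1 @ np.array([1.0, 0.0])) == pytest.approx(1.0)

    def test_pole_to_pole_statistics(self, domain):
        stream = RngStream(42)
        n = 10_000
        reversed_count = 0
        for i in range(n):
            cell = make_cell((50, 50), (1, 0), cell_id=i)
            out = resolve_pole_to_pole(cell, domain, stream)
            assert out.mode is Mode.COLLISION_POLE
            if out.details["reversed"]:
                reversed_count += 1
                assert np.allclose(orientation(cell, domain), [-1, 0])
            else:
                ang = out.details["angle_deg"]
                assert 10.0 <= abs(ang) <= 30.0
                assert out.direction is not None
        frac = reversed_count / n
        assert abs(frac - 0.5) <= 3 * 0.5 / np.sqrt(n)


class TestActiveTurning:
    def test_not_elapsed_returns_none(self, domain):
        cell = make_cell((50, 50), (1, 0))
        cell.turning_interval = 3.0
        cell.last_turn_time = 0.0
        assert check_active_turn(cell, 2.0, RngStream(0), domain) is None

    def test_event_statistics(self, domain):
        # pooled over many events: mean |angle| ~ 30 deg, mean interval ~ 3 min,
        # left/right balanced
        stream = RngStream(7)
        cell = make_cell((50, 50), (1, 0))
        cell.turning_interval = 0.0
        angles, intervals, lefts = [], [], 0
        n = 10_000
        for k in range(n):
            o = orientation(cell, domain)
            intervals.append(cell.turning_interval)
            d = check_active_turn(cell, 1000.0 * (k + 1), stream, domain)
            assert d is not None
            ang = np.rad2deg(np.arctan2(o[0] * d[1] - o[1] * d[0], o @ d))
            angles.append(abs(ang))
            lefts += ang > 0
        intervals = np.array(intervals[1:])
        angles = np.array(angles)
        assert abs(angles.mean() - 30.0) <= 3 * angles.std() / np.sqrt(n) + 0.1
        assert np.all((0 < angles) & (angles <= 90.0))
        assert abs(intervals.mean() - 3.0) <= 3 * intervals.std() / np.sqrt(len(intervals)) + 0.05
        assert abs(lefts / n - 0.5) <= 3 * 0.5 / np.sqrt(n)

    def test_truncated_normal_bounds(self, rng):
        x = truncated_normal(rng, 30.0, 10.0, lo=0.0, hi=90.0, size=1000)
        assert np.all((x > 0) & (x <= 90.0))
        x = truncated_normal(rng, 3.0, 1.0, lo=0.1, size=1000)
        assert np.all(x >= 0.1)
        assert truncated_normal(rng, 5.0, 0.0, lo=0.1) == 5.0


class TestDecidePriority:
    def test_reversal_beats_collision(self, domain):
        stream = RngStream(0)
        cell = make_cell((50, 50), (1, 0))
        cell.current_period = 1.0
        cell.reversal_phase = 1.0
        partner = make_cell((50.2, 50.0), (0, 1), cell_id=1)
        out = decide(cell, [partner], None, 0.0, domain, stream, eps_enabled=False)
        assert out.mode is Mode.REVERSED and out.direction is None

    def test_default_straight(self, domain):
        stream = RngStream(0)
        cell = make_cell((50, 50), (1, 0))
        cell.reversal_phase = 0.0
        cell.last_turn_time = 0.0
        cell.turning_interval = 10.0
        out = decide(cell, [], None, 0.0, domain, stream, eps_enabled=False)
        assert out.mode is Mode.STRAIGHT
        assert np.allclose(out.direction, [1, 0])

    def test_steering_slime_beats_elapsed_turn_timer(self, domain):
        stream = RngStream(0)
        f = SlimeField(domain)
        for _ in range(8):
            deposit(f, np.array([52.5, 51.8]))  # ~36 degrees off axis: steering
        cell = make_cell((50, 50), (1, 0))
        cell.turning_interval = 0.0  # turn overdue
        out = decide(cell, [], f, 10.0, domain, stream)
        assert out.mode is Mode.EPS_FOLLOW
        assert out.direction @ np.array([1.0, 0.0]) > 0  # acute

    def test_straight_trail_leaves_turning_open(self, domain):
        stream = RngStream(0)
        f = SlimeField(domain)
        for _ in range(8):
            deposit(f, np.array([52.25, 50.25]))  # dead ahead
        cell = make_cell((50, 50), (1, 0))
        cell.turning_interval = 0.0
        out = decide(cell, [], f, 10.0, domain, stream, straight_tol_deg=15.0)
        assert out.mode is Mode.ACTIVE_TURN

    def test_collision_beats_slime(self, domain):
        stream = RngStream(0)
        f = SlimeField(domain)
        for _ in range(8):
            deposit(f, np.array([52.5, 51.8]))
        cell = make_cell((50, 50), (1, 0))
        partner = make_cell((50.2, 50.1), (0, 1), cell_id=1)
        out = decide(cell, [partner], f, 0.0, domain, stream)
        assert out.mode in (Mode.COLLISION_ALIGN, Mode.COLLISION_POLE)


class TestAdvance:
    def test_step_arithmetic(self, domain):
        cell = make_cell((50, 50), (1, 0), length=4.0)
        out = decide(cell, [], None, 0.0, domain, RngStream(0),
                     eps_enabled=False, turning_enabled=False)
        advance(cell, out, DT, domain)
        assert np.allclose(cell.leading_pole, [51.5, 50.0])

    def test_straight_motion_keeps_chain_collinear(self, domain):
        cell = make_cell((10, 10), (0.6, 0.8))
        stream = RngStream(0)
        for _ in range(30):
            out = decide(cell, [], None, 0.0, domain, stream,
                         eps_enabled=False, turning_enabled=False,
                         reversal_enabled=False)
            advance(cell, out, DT, domain)
        L = cell.params.segment_length
        rel = cell.path[0] - np.arange(cell.params.n_nodes)[:, None] * L * np.array([0.6, 0.8])
        assert np.allclose(cell.nodes, wrap(rel, domain), atol=1e-9)

    def test_non_unit_direction_rejected(self, domain):
        from myxosim.motility import DecisionOutcome
        cell = make_cell((50, 50), (1, 0))
        with pytest.raises(ValueError):
            advance(cell, DecisionOutcome(Mode.STRAIGHT, np.array([2.0, 0.0]), {}), DT, domain)
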