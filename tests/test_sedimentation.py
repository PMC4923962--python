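"""Descent engine: ladder sampling, collisions, boundaries, absorption."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fibrosim import (
    CellAgent,
    CellState,
    ContractError,
    Lattice,
    MoveKind,
    SimulationConfig,
    Site,
    StallError,
    compute_level_probabilities,
    run_sedimentation_phase,
    sample_target,
    sedimentation_step,
    surface_contact_ids,
)
from fibrosim.io_cli import generate_fixture
from fibrosim.sedimentation import admissible_moves

LADDER = compute_level_probabilities()


def _suspended(cid, col, row):
    return CellAgent(id=cid, footprint=[Site(col, row)])


def _attached(cid, col):
    return CellAgent(
        id=cid, footprint=[Site(col, 0)], state=CellState.CONTACT, attach_time_s=0.0
    )


def _build(width, height, cells):
    lattice = Lattice(width, height)
    for c in cells:
        for s in c.footprint:
            lattice.place(s, c.id)
    return lattice, {c.id: c for c in cells}


class TestSampleTarget:
    def test_cdf_partition_all_neighbors_free(self, forced_rng):
        """With all four neighbors free the draw partitions (0,1) in the
        documented order down, left, right, up with masses 4/7,1/7,1/7,1/7."""
        lattice, cells = _build(9, 9, [_suspended(0, 4, 4)])
        cases = [
            (0.99 * 4 / 7, "down", Site(4, 3)),
            (4 / 7 + 0.001, "left", Site(3, 4)),
            (5 / 7 + 0.001, "right", Site(5, 4)),
            (6 / 7 + 0.001, "up", Site(4, 5)),
        ]
        for u, direction, target in cases:
            out = sample_target(cells[0], lattice, LADDER, forced_rng([u]))
            assert (out.direction, out.target) == (direction, target)

    def test_single_admissible_target_is_certain(self, forced_rng):
        cells = [
            _suspended(0, 4, 2),
            _suspended(1, 4, 1),  # below
            _suspended(2, 3, 2),  # left
            _suspended(3, 5, 2),  # right
        ]
        lattice, cmap = _build(9, 9, cells)
        for u in (0.01, 0.5, 0.999):
            out = sample_target(cmap[0], lattice, LADDER, forced_rng([u]))
            assert out.kind == MoveKind.MOVED
            assert out.target == Site(4, 3)  # up is the only option

    def test_down_blocked_renormalizes_to_thirds(self, forced_rng):
        """down occupied, laterals and up free: 1/7:1/7:1/7 renormalizes to
        equal thirds over (left, right, up)."""
        lattice, cmap = _build(9, 9, [_suspended(0, 4, 4), _suspended(1, 4, 3)])
        expect = [(0.2, "left"), (0.5, "right"), (0.9, "up")]
        for u, direction in expect:
            out = sample_target(cmap[0], lattice, LADDER, forced_rng([u]))
            assert out.direction == direction

    def test_renormalization_matches_redraw_until_free(self, rng):
        """The conditional law equals the redraw-until-free procedure."""
        lattice, cmap = _build(9, 9, [_suspended(0, 4, 4), _suspended(1, 4, 3)])
        n = 60_000
        # implementation
        counts = {"left": 0, "right": 0, "up": 0}
        for _ in range(n):
            counts[sample_target(cmap[0], lattice, LADDER, rng).direction] += 1
        # independent redraw-until-free oracle over the raw per-position law
        per = [float(p) for p in LADDER.per_position]  # up,left,right,down
        directions = ["up", "left", "right", "down"]
        redraw = {"left": 0, "right": 0, "up": 0}
        for _ in range(n):
            while True:
                d = directions[rng.choice(4, p=per)]
                if d != "down":  # down is the blocked target
                    redraw[d] += 1
                    break
        for d in counts:
            p_impl = counts[d] / n
            p_oracle = redraw[d] / n
            se = np.sqrt(2 * (1 / 3) * (2 / 3) / n)
            assert abs(p_impl - p_oracle) < 4 * se
            assert abs(p_impl - 1 / 3) < 4 * se

    def test_non_suspended_cell_rejected(self, rng):
        lattice, cmap = _build(5, 5, [_attached(0, 2)])
        with pytest.raises(ContractError):
            sample_target(cmap[0], lattice, LADDER, rng)

    def test_down_move_onto_substrate_attaches(self, forced_rng):
        lattice, cmap = _build(5, 5, [_suspended(0, 2, 1)])
        out = sample_target(cmap[0], lattice, LADDER, forced_rng([0.1]))
        assert out.kind == MoveKind.ATTACHED
        assert out.target == Site(2, 0)

    @given(
        occupied=st.sets(
            st.tuples(st.integers(0, 4), st.integers(0, 4)), max_size=10
        ),
        col=st.integers(0, 4),
        row=st.integers(1, 4),
    )
    def test_admissible_set_is_free_neighbors_plus_exits(self, occupied, col, row):
        occupied = {Site(c, r) for c, r in occupied} - {Site(col, row)}
        lattice = Lattice(5, 5)
        cells = {99: _suspended(99, col, row)}
        lattice.place(Site(col, row), 99)
        for i, s in enumerate(sorted(occupied)):
            lattice.place(s, i)
        moves = admissible_moves(cells[99], lattice, LADDER, "open_exit")
        targets = {t for _, t, _ in moves if t is not None}
        exits = {d for d, t, _ in moves if t is None}
        for t in targets:
            assert lattice.is_free(t)
            assert abs(t.column - col) + abs(t.row - row) == 1
        for d in exits:
            assert (d == "left" and col == 0) or (d == "right" and col == 4)
        # weights stay proportional to the raw ladder: down 4x any other
        weights = {d: w for d, _, w in moves}
        if "down" in weights and "up" in weights:
            assert weights["down"] == 4 * weights["up"]


class TestBoundaries:
    def test_top_row_is_reflective(self):
        lattice, cmap = _build(5, 5, [_suspended(0, 2, 4)])
        moves = admissible_moves(cmap[0], lattice, LADDER, "open_exit")
        assert "up" not in {d for d, _, _ in moves}

    def test_open_exit_allows_lateral_departure(self, forced_rng):
        lattice, cmap = _build(5, 5, [_suspended(0, 0, 3)])
        # CDF order (down, left[exit], right, up): u just past 4/7 picks left
        out = sample_target(
            cmap[0], lattice, LADDER, forced_rng([4 / 7 + 0.01]), "open_exit"
        )
        assert out.kind == MoveKind.EXITED

    def test_closed_wall_renormalizes_inward(self):
        lattice, cmap = _build(5, 5, [_suspended(0, 0, 3)])
        moves = admissible_moves(cmap[0], lattice, LADDER, "closed")
        assert {d for d, _, _ in moves} == {"down", "right", "up"}
        assert all(t is not None for _, t, _ in moves)


class TestStep:
    def test_forced_attach_transition(self, forced_rng):
        lattice, cmap = _build(7, 5, [_suspended(0, 5, 1)])
        events = []
        rep = sedimentation_step(
            lattice, cmap, LADDER, 0.5, forced_rng([0.1], [[0]]), events=events
        )
        assert rep.attached == [0]
        assert cmap[0].state == CellState.CONTACT
        assert cmap[0].site == Site(5, 0)
        assert [e.kind.value for e in events] == ["SUBSTRATE_ATTACH", "SURFACE_CONTACT"]

    @pytest.mark.parametrize("order", [[0, 1], [1, 0]])
    def test_collision_exactly_one_obtains_contested_site(self, order, forced_rng):
        """Two cells aiming at the same free site: the first processed takes
        it, the second re-resolves among its remaining admissible targets.
        Exclusion holds for both processing orders."""
        base = [_attached(10, 2), _attached(11, 3), _attached(12, 4)]
        movers = [_suspended(0, 2, 1), _suspended(1, 4, 1)]
        lattice, cmap = _build(7, 4, base + movers)
        # first processed: admissible (left,right,up) thirds; u=0.5 -> right
        # for cell 0 that is the contested Site(3,1); for cell 1, u=0.2 -> left
        uniforms = [0.5, 0.5] if order == [0, 1] else [0.2, 0.2]
        # scripted permutation refers to position among suspended ids [0, 1]
        sedimentation_step(
            lattice, cmap, LADDER, 0.5, forced_rng(uniforms, [order])
        )
        occupants = [lattice.occupant(Site(3, 1))]
        assert occupants[0] == order[0]  # first processed wins the middle site
        lattice.validate_against(cmap)
        assert cmap[order[1]].site != Site(3, 1)

    def test_exclusion_and_contact_monotonicity_over_run(self, rng):
        cfg = SimulationConfig(
            grid_width_sites=12, grid_height_sites=8, n_cells=20, seed=5
        )
        lattice, cells = generate_fixture("uniform_random", width=12, height=8, n=20, seed=5)
        ladder = LADDER
        n_contact_prev = 0
        for step in range(200):
            if not any(c.state == CellState.SUSPENDED for c in cells.values()):
                break
            sedimentation_step(lattice, cells, ladder, 0.5 * (step + 1), rng)
            lattice.validate_against(cells)
            n_contact = sum(1 for c in cells.values() if c.state >= CellState.CONTACT)
            assert n_contact >= n_contact_prev
            n_contact_prev = n_contact


class TestSurfaceContact:
    def test_predicate_covers_substrate_adjacency_and_stacks(self):
        cells = [
            _attached(0, 2),
            _suspended(1, 2, 1),  # on attached cell: settled, adjacent
            _suspended(2, 2, 2),  # atop the settled stack
            _suspended(3, 1, 2),  # beside suspended cells only: no contact
            _suspended(4, 3, 1),  # beside the settled cell, not on it: no contact
            _suspended(5, 6, 3),  # far away
        ]
        lattice, cmap = _build(8, 5, cells)
        ids = surface_contact_ids(lattice, cmap)
        assert 0 in ids  # on the substrate
        assert 1 in ids  # axially adjacent to an attached cell
        assert 2 in ids  # resting on a settled stack
        assert 3 not in ids  # lateral adjacency to suspended cells is not contact
        assert 4 not in ids
        assert 5 not in ids


class TestPhase:
    def test_vacuous_population(self, rng):
        cfg = SimulationConfig(n_cells=0)
        lattice = Lattice(5, 5)
        stats = run_sedimentation_phase(cfg, lattice, {}, rng)
        assert stats.end_time_s == 0.0
        assert stats.first_contact_time_s is None
        assert stats.all_attached_time_s is None

    def test_cell_starting_on_substrate_attaches_at_time_zero(self, rng):
        cfg = SimulationConfig()
        lattice, cells = _build(5, 5, [_suspended(0, 2, 0)])
        stats = run_sedimentation_phase(cfg, lattice, cells, rng)
        assert stats.first_contact_time_s == 0.0
        assert stats.all_attached_time_s == 0.0
        assert cells[0].state == CellState.CONTACT

    def test_stall_guard_raises_when_fully_wedged(self, rng):
        """A suspended cell boxed in a closed 1x2 column can never move;
        the guard turns the silent non-termination into an error."""
        cfg = SimulationConfig(lateral_boundary="closed", stall_guard_steps=5)
        lattice, cells = _build(1, 2, [_attached(0, 0), _suspended(1, 0, 1)])
        with pytest.raises(StallError):
            run_sedimentation_phase(cfg, lattice, cells, rng)

    def test_net_drift_is_three_sevenths_down(self, rng):
        """Mean vertical displacement per step with all neighbors free."""
        lattice, cmap = _build(9, 9, [_suspended(0, 4, 4)])
        n = 30_000
        total = 0
        for _ in range(n):
            out = sample_target(cmap[0], lattice, LADDER, rng)
            total += {"down": 1, "up": -1}.get(out.direction, 0)
        mean = total / n
        # Var = 5/7 - (3/7)^2 = 26/49
        se = np.sqrt(26 / 49 / n)
        assert abs(mean - 3 / 7) < 3 * se

    def test_single_cell_column_matches_birth_death_absorption_time(self, rng):
        """One cell in a closed 1-column domain is a birth-death chain with
        renormalized moves (up 1/5, down 4/5; down with certainty at the
        top; absorbing substrate). The mean simulated attachment time must
        match the exact absorption time from the linear system."""
        height = 8
        expected = _exact_absorption_steps(height)
        n_runs = 4000
        cfg = SimulationConfig(
            grid_width_sites=1,
            grid_height_sites=height,
            n_cells=1,
            lateral_boundary="closed",
            dt_sedimentation_s=1.0,
        )
        samples = _column_absorption_samples(cfg, height, n_runs, rng)
        mean = samples.mean()
        se = samples.std(ddof=1) / np.sqrt(n_runs)
        assert abs(mean - expected) < 3 * se


def _exact_absorption_steps(height: int) -> float:
    """Solve T_r = 1 + p_up T_{r+1} + p_down T_{r-1}, T_0 = 0, with the
    top row forced downward, by direct linear algebra."""
    n = height - 1  # transient states rows 1..height-1
    A = np.zeros((n, n))
    b = np.ones(n)
    for i, row in enumerate(range(1, height)):
        A[i, i] = 1.0
        if row == height - 1:
            if row - 1 >= 1:
                A[i, i - 1] -= 1.0  # down with certainty
        else:
            A[i, i + 1] -= 1 / 5
            if row - 1 >= 1:
                A[i, i - 1] -= 4 / 5
    return float(np.linalg.solve(A, b)[height - 2])


def _column_absorption_samples(cfg, height, n_runs, rng):
    out = np.empty(n_runs)
    for i in range(n_runs):
        lattice, cells = generate_fixture("column", height=height)
        stats = run_sedimentation_phase(cfg, lattice, cells, rng)
        out[i] = stats.all_attached_time_s
    return out
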