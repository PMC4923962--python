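"""Descent engine: gravity-biased random walk of suspended cells.

Each iteration (0.5 s of culture time by default) every suspended cell
draws a destination among its four axial neighbors with the ladder
probabilities, restricted to admissible targets — free in-domain sites,
plus lateral off-grid moves when the lateral boundary is open (the cell
then leaves the population). Probabilities are renormalized over the
admissible set, which is equivalent in distribution to redrawing until a
free position is found but always terminates. A cell with no admissible
target keeps its place for the step. Reaching row 0 attaches the cell to
the substrate, irreversibly.

Cells are processed once per iteration in a fresh random order; sequential
updating within the step guarantees the exclusion constraint without a
separate conflict-resolution pass. The cumulative-probability order used
for sampling is fixed as (down, left, right, up) so that seeded runs are
bit-reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .kinetics import ProbabilityLadder
from .model_core import (
    CellAgent,
    CellState,
    ContractError,
    Event,
    EventKind,
    Lattice,
    Site,
    StallError,
    advance_state,
)

#: Fixed sampling order of the cumulative-probability partition.
CDF_ORDER = ("down", "left", "right", "up")

_DELTAS = {"up": (0, 1), "left": (-1, 0), "right": (1, 0), "down": (0, -1)}


class MoveKind(str, enum.Enum):
    MOVED = "MOVED"
    STAYED = "STAYED"
    EXITED = "EXITED"
    ATTACHED = "ATTACHED"


@dataclass(frozen=True)
class MoveOutcome:
    kind: MoveKind
    target: Optional[Site]
    direction: Optional[str] = None

    def __post_init__(self):
        has_target = self.target is not None
        if self.kind in (MoveKind.MOVED, MoveKind.ATTACHED) and not has_target:
            raise ContractError(f"{self.kind} outcome requires a target")
        if self.kind in (MoveKind.STAYED, MoveKind.EXITED) and has_target:
            raise ContractError(f"{self.kind} outcome carries no target")


def admissible_moves(
    cell: CellAgent,
    lattice: Lattice,
    ladder: ProbabilityLadder,
    lateral_boundary: str = "open_exit",
) -> list[tuple[str, Optional[Site], object]]:
    """Admissible (direction, target, weight) triples in CDF order.

    A target is admissible if it is a free in-domain site, or a lateral
    off-grid position under the open-exit boundary (``target=None``,
    meaning the cell leaves the domain). The top edge is reflective: an
    off-grid upward move is never admissible. Weights are the exact
    per-position ladder probabilities, unnormalized.
    """
    up, left, right, down = ladder.per_position
    weight = {"up": up, "left": left, "right": right, "down": down}
    col, row = cell.site
    out: list[tuple[str, Optional[Site], object]] = []
    for d in CDF_ORDER:
        dc, dr = _DELTAS[d]
        t = Site(col + dc, row + dr)
        if lattice.in_bounds(t):
            if lattice.is_free(t):
                out.append((d, t, weight[d]))
        elif d in ("left", "right") and lateral_boundary == "open_exit":
            out.append((d, None, weight[d]))
    return out


def sample_target(
    cell: CellAgent,
    lattice: Lattice,
    ladder: ProbabilityLadder,
    rng,
    lateral_boundary: str = "open_exit",
) -> MoveOutcome:
    """Draw one destination for a suspended cell.

    Consumes exactly one uniform variate from ``rng``. The conditional
    probability of each admissible target is its ladder weight
    renormalized over the admissible set.
    """
    if cell.state != CellState.SUSPENDED:
        raise ContractError(f"cell {cell.id} is {cell.state.name}, not SUSPENDED")
    moves = admissible_moves(cell, lattice, ladder, lateral_boundary)
    if not moves:
        return MoveOutcome(MoveKind.STAYED, None)
    total = sum(w for _, _, w in moves)
    u = rng.random()
    acc = 0.0
    direction, target = moves[-1][0], moves[-1][1]
    for d, t, w in moves:
        acc += float(w / total)
        if u < acc:
            direction, target = d, t
            break
    if target is None:
        return MoveOutcome(MoveKind.EXITED, None, direction)
    if target.row == 0:
        return MoveOutcome(MoveKind.ATTACHED, target, direction)
    return MoveOutcome(MoveKind.MOVED, target, direction)


def surface_contact_ids(lattice: Lattice, cells: dict[int, CellAgent]) -> set[int]:
    """Cells currently in contact with at least one surface.

    A cell satisfies the predicate if it sits on the substrate (state >=
    CONTACT), is axially adjacent to an attached cell, or rests directly
    on a settled stack — a chain of suspended cells standing, in one
    column, on an attached cell.
    """
    settled: set[int] = set()
    for col in range(lattice.width):
        base = lattice.occupant(Site(col, 0))
        if base is None or cells[base].state < CellState.CONTACT:
            continue
        row = 1
        while row < lattice.height:
            occ = lattice.occupant(Site(col, row))
            if occ is None or cells[occ].state != CellState.SUSPENDED:
                break
            settled.add(occ)
            row += 1

    result: set[int] = set()
    for cid, cell in cells.items():
        if cell.state >= CellState.CONTACT:
            result.add(cid)
            continue
        col, row = cell.site
        for dc, dr in _DELTAS.values():
            occ = lattice.occupant(Site(col + dc, row + dr))
            if occ is not None and cells[occ].state >= CellState.CONTACT:
                result.add(cid)
                break
        else:
            below = lattice.occupant(Site(col, row - 1)) if row > 0 else None
            if below is not None and below in settled:
                result.add(cid)
    return result


def _flag_surface_contacts(
    lattice: Lattice,
    cells: dict[int, CellAgent],
    time_s: float,
    events: Optional[list[Event]],
) -> list[int]:
    newly = []
    for cid in sorted(surface_contact_ids(lattice, cells)):
        cell = cells[cid]
        if not cell.surface_contact:
            cell.surface_contact = True
            newly.append(cid)
            if events is not None:
                events.append(Event(time_s, EventKind.SURFACE_CONTACT, cid))
    return newly


@dataclass
class StepReport:
    n_moved: int = 0
    attached: list[int] = field(default_factory=list)
    exited: list[int] = field(default_factory=list)
    newly_surface: list[int] = field(default_factory=list)


def sedimentation_step(
    lattice: Lattice,
    cells: dict[int, CellAgent],
    ladder: ProbabilityLadder,
    time_s: float,
    rng,
    lateral_boundary: str = "open_exit",
    events: Optional[list[Event]] = None,
) -> StepReport:
    """One synchronized descent iteration.

    Every suspended cell is processed exactly once, in a fresh random
    permutation. Attachments (row-0 arrivals) become CONTACT immediately;
    lateral exits remove the cell from the population.
    """
    report = StepReport()
    suspended = [cid for cid, c in cells.items() if c.state == CellState.SUSPENDED]
    order = [suspended[i] for i in rng.permutation(len(suspended))] if suspended else []
    for cid in order:
        cell = cells[cid]
        outcome = sample_target(cell, lattice, ladder, rng, lateral_boundary)
        if outcome.kind == MoveKind.MOVED:
            lattice.move(cell.site, outcome.target, cid)
            cell.footprint = [outcome.target]
            report.n_moved += 1
        elif outcome.kind == MoveKind.ATTACHED:
            lattice.move(cell.site, outcome.target, cid)
            cell.footprint = [outcome.target]
            advance_state(cell, CellState.CONTACT, time_s, events)
            report.attached.append(cid)
            report.n_moved += 1
        elif outcome.kind == MoveKind.EXITED:
            lattice.vacate(cell.site)
            del cells[cid]
            report.exited.append(cid)
            if events is not None:
                events.append(Event(time_s, EventKind.EXIT, cid, outcome.direction or ""))
            report.n_moved += 1
    report.newly_surface = _flag_surface_contacts(lattice, cells, time_s, events)
    return report


@dataclass
class SedimentationStats:
    first_contact_time_s: Optional[float] = None
    all_surface_contact_time_s: Optional[float] = None
    all_attached_time_s: Optional[float] = None
    end_time_s: float = 0.0
    n_steps: int = 0
    n_exited: int = 0


def run_sedimentation_phase(
    config,
    lattice: Lattice,
    cells: dict[int, CellAgent],
    rng,
    events: Optional[list[Event]] = None,
    recorder=None,
) -> SedimentationStats:
    """Iterate descent steps until no suspended cell remains (or t_max_s).

    Suspended cells already sitting on row 0 attach in a pre-pass at t=0.
    ``recorder``, if given, is called with the current time after the
    pre-pass and after every step, for time-series capture.

    Raises :class:`StallError` if no cell changes site for
    ``config.stall_guard_steps`` consecutive iterations while suspended
    cells remain — impossible while upward moves are admissible, so the
    guard only documents the termination argument.
    """
    ladder = _default_ladder()
    stats = SedimentationStats()
    t = 0.0

    for cid in sorted(cells):
        cell = cells[cid]
        if cell.state == CellState.SUSPENDED and cell.site.row == 0:
            advance_state(cell, CellState.CONTACT, t, events)
            if stats.first_contact_time_s is None:
                stats.first_contact_time_s = t
                if events is not None:
                    events.append(Event(t, EventKind.FIRST_CONTACT, cid))
    _flag_surface_contacts(lattice, cells, t, events)
    _update_completion(stats, cells, t)
    if recorder is not None:
        recorder(t)

    stall = 0
    while any(c.state == CellState.SUSPENDED for c in cells.values()):
        if t + config.dt_sedimentation_s > config.t_max_s:
            break
        t += config.dt_sedimentation_s
        report = sedimentation_step(
            lattice, cells, ladder, t, rng, config.lateral_boundary, events
        )
        stats.n_steps += 1
        stats.n_exited += len(report.exited)
        if report.attached and stats.first_contact_time_s is None:
            stats.first_contact_time_s = t
            if events is not None:
                events.append(Event(t, EventKind.FIRST_CONTACT, report.attached[0]))
        _update_completion(stats, cells, t)
        if recorder is not None:
            recorder(t)
        stall = 0 if report.n_moved else stall + 1
        if stall >= config.stall_guard_steps:
            raise StallError(
                f"no movement for {stall} consecutive steps with suspended cells remaining"
            )
    stats.end_time_s = t
    return stats


def _update_completion(stats: SedimentationStats, cells, t: float) -> None:
    if not cells:
        return
    if stats.all_surface_contact_time_s is None and all(
        c.surface_contact for c in cells.values()
    ):
        stats.all_surface_contact_time_s = t
    if stats.all_attached_time_s is None and all(
        c.state >= CellState.CONTACT for c in cells.values()
    ):
        stats.all_attached_time_s = t


def _default_ladder() -> ProbabilityLadder:
    from .kinetics import compute_level_probabilities

    return compute_level_probabilities()
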