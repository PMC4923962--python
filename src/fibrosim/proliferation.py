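"""Division engine: anchorage-dependent, contact-inhibited proliferation.

Only fully spread cells divide. After a cell-cycle delay the neighborhood
of the spread cell is searched for two contiguous free substrate sites
flanking its footprint; if such a pair exists the cell duplicates and the
daughter is born spread into that pair. If no complete free pair exists
the cell is flagged contact-inhibited; the flag is re-checked every step
and reverts to division eligibility should space ever free up.
"""

from __future__ import annotations

from typing import Optional

from .model_core import (
    CellAgent,
    CellState,
    ContractError,
    Event,
    EventKind,
    Lattice,
    Site,
    advance_state,
)

_TIME_EPS = 1e-9


def find_division_slot(
    cell: CellAgent, lattice: Lattice, rng
) -> Optional[tuple[Site, Site]]:
    """A free pair of contiguous row-0 sites flanking a spread cell.

    The two candidate pairs are the two sites immediately left of the
    footprint's left end and the two immediately right of its right end.
    Pairs truncated by the domain edge are not free. When both pairs are
    free one is chosen uniformly at random; ``None`` when neither is.
    """
    if cell.state not in (CellState.SPREAD, CellState.INHIBITED):
        raise ContractError(f"cell {cell.id} is {cell.state.name}, cannot divide")
    if len(cell.footprint) != 2:
        raise ContractError(
            f"cell {cell.id} footprint has {len(cell.footprint)} sites (2 required)"
        )
    columns = sorted(s.column for s in cell.footprint)
    left_pair = (Site(columns[0] - 2, 0), Site(columns[0] - 1, 0))
    right_pair = (Site(columns[1] + 1, 0), Site(columns[1] + 2, 0))
    free = [
        pair
        for pair in (left_pair, right_pair)
        if lattice.is_free(pair[0]) and lattice.is_free(pair[1])
    ]
    if not free:
        return None
    if len(free) == 2:
        return free[0] if rng.random() < 0.5 else free[1]
    return free[0]


def attempt_division(
    cell: CellAgent,
    lattice: Lattice,
    time_s: float,
    rng,
    t_cycle_s: float,
    new_id: int,
    events: Optional[list[Event]] = None,
) -> Optional[CellAgent]:
    """Divide a spread cell whose cycle clock has elapsed, space permitting.

    The clock runs from spread completion, or from the last division. On
    success the daughter is created already spread into the free flanking
    pair, both clocks reset, and a DIVISION event is logged. Without a
    free pair the cell is marked INHIBITED (population unchanged); the
    INHIBITED flag flips back to SPREAD as soon as a later attempt finds
    space. Returns the daughter, or ``None``.
    """
    if cell.state not in (CellState.SPREAD, CellState.INHIBITED):
        raise ContractError(f"cell {cell.id} is {cell.state.name}, cannot divide")
    if cell.cycle_start_time_s is None:
        raise ContractError(f"cell {cell.id} has no cycle clock (never spread)")
    if time_s - cell.cycle_start_time_s < t_cycle_s - _TIME_EPS:
        return None
    slot = find_division_slot(cell, lattice, rng)
    if slot is None:
        if cell.state == CellState.SPREAD:
            advance_state(cell, CellState.INHIBITED, time_s, events)
        return None
    if cell.state == CellState.INHIBITED:
        advance_state(cell, CellState.SPREAD, time_s, events)
    daughter = CellAgent(
        id=new_id,
        footprint=list(slot),
        state=CellState.SPREAD,
        state_entry_time_s=time_s,
        attach_time_s=time_s,
        spread_complete_time_s=time_s,
        cycle_start_time_s=time_s,
        parent_id=cell.id,
    )
    for site in slot:
        lattice.place(site, new_id)
    cell.cycle_start_time_s = time_s
    if events is not None:
        events.append(
            Event(time_s, EventKind.DIVISION, cell.id, f"daughter={new_id}")
        )
    return daughter
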