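"""Adhesion engine: timed progression from substrate contact to spreading.

A cell that has touched the substrate keeps its rounded shape while the
first anchoring link (focal adhesion) matures, then spreads by claiming a
second contiguous substrate site. Both transitions are driven by per-cell
timers measured from the moment of substrate contact: ``t_focal_s`` to the
focal state (~100 min with defaults) and ``t_spread_s`` to full spreading
(~180 min). Spreading requires a free lateral site on the substrate row;
if both sides are occupied the cell stays focal and retries each step.
"""

from __future__ import annotations

from typing import Optional

from .model_core import (
    CellAgent,
    CellState,
    ContractError,
    Event,
    Lattice,
    Site,
    advance_state,
)

_TIME_EPS = 1e-9


def attempt_focal(
    cell: CellAgent,
    time_s: float,
    t_focal_s: float,
    events: Optional[list[Event]] = None,
) -> bool:
    """Advance CONTACT -> FOCAL once the focal-adhesion timer has elapsed.

    The timer runs from substrate contact. Returns True if the cell
    advanced. Cells in any other state are left untouched.
    """
    if cell.state != CellState.CONTACT:
        return False
    if time_s - cell.attach_time_s >= t_focal_s - _TIME_EPS:
        advance_state(cell, CellState.FOCAL, time_s, events)
        return True
    return False


def attempt_spread(
    cell: CellAgent,
    lattice: Lattice,
    time_s: float,
    t_spread_s: float,
    rng,
    events: Optional[list[Event]] = None,
) -> bool:
    """Advance FOCAL -> SPREAD by claiming a free lateral substrate site.

    The spreading timer runs from substrate contact (not from the focal
    transition). When both flanking row-0 sites are free one is chosen
    uniformly at random; when neither is free the cell remains FOCAL and
    the attempt is repeated on later steps. Returns True if the cell
    spread.
    """
    if cell.state != CellState.FOCAL:
        return False
    if cell.site.row != 0:
        raise ContractError(f"focal cell {cell.id} off the substrate row: {cell.site}")
    if time_s - cell.attach_time_s < t_spread_s - _TIME_EPS:
        return False
    col = cell.site.column
    options = [
        s
        for s in (Site(col - 1, 0), Site(col + 1, 0))
        if lattice.is_free(s)
    ]
    if not options:
        return False
    if len(options) == 2:
        claimed = options[0] if rng.random() < 0.5 else options[1]
    else:
        claimed = options[0]
    lattice.place(claimed, cell.id)
    cell.footprint = [cell.site, claimed]
    advance_state(cell, CellState.SPREAD, time_s, events)
    return True
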