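"""Core domain types for the on-lattice cell population model.

The simulated system is a 2D vertical cross-section of a culture vessel,
discretized into square sites of one cell diameter. Row 0 is the substrate
at the bottom edge; a cell "falls" by decreasing its row index. At most one
cell may claim a site at any time (exclusion), and every cell advances
through an irreversible life cycle: suspended in the medium, in contact
with the substrate, focally adhered, spread over two contiguous substrate
sites, and (reversibly) contact-inhibited once no space remains to divide
into.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import NamedTuple, Optional


class ConfigError(ValueError):
    """A configuration value violates its documented invariant."""


class ContractError(ValueError):
    """An operation was called outside its preconditions."""


class InvariantError(RuntimeError):
    """A model invariant (exclusion, irreversibility, footprint) was broken."""


class StallError(RuntimeError):
    """The descent phase made no progress for too many consecutive steps."""


class CellState(enum.IntEnum):
    """Life-cycle states, ordered; transitions may only move forward,
    except for the SPREAD <-> INHIBITED pair which flags the availability
    of division space around an already-spread cell."""

    SUSPENDED = 0
    CONTACT = 1
    FOCAL = 2
    SPREAD = 3
    INHIBITED = 4


_ALLOWED_TRANSITIONS = frozenset(
    {
        (CellState.SUSPENDED, CellState.CONTACT),
        (CellState.CONTACT, CellState.FOCAL),
        (CellState.FOCAL, CellState.SPREAD),
        (CellState.SPREAD, CellState.INHIBITED),
        (CellState.INHIBITED, CellState.SPREAD),
    }
)


class EventKind(str, enum.Enum):
    FIRST_CONTACT = "FIRST_CONTACT"
    SURFACE_CONTACT = "SURFACE_CONTACT"
    SUBSTRATE_ATTACH = "SUBSTRATE_ATTACH"
    SPREAD_COMPLETE = "SPREAD_COMPLETE"
    DIVISION = "DIVISION"
    EXIT = "EXIT"


class Site(NamedTuple):
    """Lattice coordinate: (column, row), 0-based, row 0 = substrate."""

    column: int
    row: int


@dataclass(frozen=True)
class Event:
    time_s: float
    kind: EventKind
    cell_id: int
    detail: str = ""


@dataclass
class CellAgent:
    """One cell: its footprint on the lattice, life-cycle state and timers.

    ``footprint`` holds 1 site, or 2 contiguous row-0 sites once spread.
    ``attach_time_s`` is the moment of substrate contact and anchors the
    focal-adhesion and spreading timers; ``cycle_start_time_s`` anchors the
    division clock (set at spread completion, reset at each division).
    """

    id: int
    footprint: list[Site]
    state: CellState = CellState.SUSPENDED
    state_entry_time_s: float = 0.0
    attach_time_s: Optional[float] = None
    spread_complete_time_s: Optional[float] = None
    cycle_start_time_s: Optional[float] = None
    parent_id: Optional[int] = None
    surface_contact: bool = False

    @property
    def site(self) -> Site:
        """Primary (first) footprint site."""
        return self.footprint[0]


def advance_state(
    cell: CellAgent,
    new_state: CellState,
    time_s: float,
    events: Optional[list[Event]] = None,
) -> CellAgent:
    """Advance a cell along the life cycle, enforcing irreversibility.

    Adhesion is not reversible: the only backward edge is INHIBITED ->
    SPREAD, which merely re-flags division eligibility. Entering CONTACT
    emits a SUBSTRATE_ATTACH event; entering SPREAD (from FOCAL) requires a
    2-site footprint and emits SPREAD_COMPLETE.
    """
    if (cell.state, new_state) not in _ALLOWED_TRANSITIONS:
        raise InvariantError(
            f"illegal transition {cell.state.name} -> {new_state.name} "
            f"for cell {cell.id}"
        )
    if new_state >= CellState.CONTACT and any(s.row != 0 for s in cell.footprint):
        raise InvariantError(
            f"cell {cell.id} entering {new_state.name} with footprint off row 0"
        )
    if new_state == CellState.SPREAD and cell.state == CellState.FOCAL:
        if len(cell.footprint) != 2:
            raise InvariantError(
                f"cell {cell.id} entering SPREAD with footprint of "
                f"{len(cell.footprint)} sites (2 required)"
            )
        cell.spread_complete_time_s = time_s
        cell.cycle_start_time_s = time_s
        if events is not None:
            events.append(Event(time_s, EventKind.SPREAD_COMPLETE, cell.id))
    if new_state == CellState.CONTACT:
        cell.attach_time_s = time_s
        if events is not None:
            events.append(Event(time_s, EventKind.SUBSTRATE_ATTACH, cell.id))
    cell.state = new_state
    cell.state_entry_time_s = time_s
    return cell


class Lattice:
    """Exclusive site-occupancy map of the rectangular grid.

    Stores ``Site -> cell id``; a missing key means the site is free. The
    bidirectional consistency with each cell's footprint can be audited
    with :meth:`validate_against`.
    """

    def __init__(self, width: int, height: int):
        if width <= 0 or height <= 0:
            raise ConfigError(f"lattice dimensions must be positive, got {width}x{height}")
        self.width = int(width)
        self.height = int(height)
        self._occupancy: dict[Site, int] = {}

    def in_bounds(self, site: Site) -> bool:
        return 0 <= site.column < self.width and 0 <= site.row < self.height

    def occupant(self, site: Site) -> Optional[int]:
        return self._occupancy.get(site)

    def is_free(self, site: Site) -> bool:
        """In-domain and unoccupied. Out-of-domain sites are never free."""
        return self.in_bounds(site) and site not in self._occupancy

    def place(self, site: Site, cell_id: int) -> None:
        if not self.in_bounds(site):
            raise ContractError(f"site {site} outside {self.width}x{self.height} lattice")
        if site in self._occupancy:
            raise InvariantError(
                f"exclusion violated: {site} already held by cell {self._occupancy[site]}"
            )
        self._occupancy[site] = cell_id

    def vacate(self, site: Site) -> None:
        if site not in self._occupancy:
            raise InvariantError(f"vacating free site {site}")
        del self._occupancy[site]

    def move(self, old: Site, new: Site, cell_id: int) -> None:
        if self._occupancy.get(old) != cell_id:
            raise InvariantError(f"cell {cell_id} does not hold {old}")
        self.vacate(old)
        self.place(new, cell_id)

    @property
    def occupancy(self) -> dict[Site, int]:
        """Copy of the occupancy mapping (Site -> cell id)."""
        return dict(self._occupancy)

    def occupied_in_row(self, row: int) -> int:
        return sum(1 for s in self._occupancy if s.row == row)

    def validate_against(self, cells: dict[int, "CellAgent"]) -> None:
        """Assert lattice <-> footprint bidirectional consistency."""
        seen: dict[Site, int] = {}
        for cid, cell in cells.items():
            for s in cell.footprint:
                if s in seen:
                    raise InvariantError(f"cells {seen[s]} and {cid} both claim {s}")
                seen[s] = cid
                if self._occupancy.get(s) != cid:
                    raise InvariantError(
                        f"cell {cid} lists {s} but lattice holds {self._occupancy.get(s)}"
                    )
        extra = set(self._occupancy) - set(seen)
        if extra:
            raise InvariantError(f"lattice holds sites with no owning cell: {sorted(extra)}")


_DIRECTIONS = ("up", "left", "right", "down")
_DELTAS = {"up": (0, 1), "left": (-1, 0), "right": (1, 0), "down": (0, -1)}


def neighbors_von_neumann(
    site: Site, lattice: Lattice
) -> list[tuple[str, Optional[Site]]]:
    """The four axial neighbors (up, left, right, down) of a site.

    Diagonal moves are excluded by construction. Neighbors falling outside
    the grid are reported with ``None`` in place of the site.
    """
    if not lattice.in_bounds(site):
        raise ContractError(f"site {site} outside lattice")
    out: list[tuple[str, Optional[Site]]] = []
    for d in _DIRECTIONS:
        dc, dr = _DELTAS[d]
        t = Site(site.column + dc, site.row + dr)
        out.append((d, t if lattice.in_bounds(t) else None))
    return out


def discretize_domain(
    length_um: float = 1000.0, height_um: float = 500.0, site_um: float = 15.0
) -> tuple[int, int]:
    """Grid dimensions (width, height in sites) for a rectangular domain
    meshed with square sites of one cell diameter.

    The default 1 mm x 0.5 mm window at 15 um per site gives 67 x 33.
    """
    if length_um <= 0 or height_um <= 0 or site_um <= 0:
        raise ConfigError("domain and site sizes must be positive")
    return round(length_um / site_um), round(height_um / site_um)


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of one run.

    Geometry defaults come from the 1 mm x 0.5 mm culture window at one
    15-um site per cell diameter. The descent phase advances 0.5 s per
    iteration; once every cell is attached the clock coarsens to
    ``dt_attached_s``. ``t_focal_s`` and ``t_spread_s`` are measured from
    substrate contact (focal adhesion at ~100 min, full spreading by ~180
    min); ``t_cycle_s`` is the division clock of a spread cell (24 h
    population doubling).
    """

    grid_width_sites: int = 67
    grid_height_sites: int = 33
    site_size_um: float = 15.0
    n_cells: int = 50
    dt_sedimentation_s: float = 0.5
    dt_attached_s: float = 20.0
    t_focal_s: float = 6000.0
    t_spread_s: float = 10800.0
    t_cycle_s: float = 86400.0
    lateral_boundary: str = "open_exit"
    t_max_s: float = 604800.0
    seed: int = 0
    stall_guard_steps: int = 10000

    def __post_init__(self):
        for name in ("grid_width_sites", "grid_height_sites"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in (
            "site_size_um",
            "dt_sedimentation_s",
            "dt_attached_s",
            "t_focal_s",
            "t_spread_s",
            "t_cycle_s",
            "t_max_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_cells < 0:
            raise ConfigError(f"n_cells must be non-negative, got {self.n_cells}")
        if self.n_cells > self.grid_width_sites * self.grid_height_sites:
            raise ConfigError(
                f"n_cells={self.n_cells} exceeds grid capacity "
                f"{self.grid_width_sites * self.grid_height_sites}"
            )
        if self.t_focal_s > self.t_spread_s:
            raise ConfigError(
                f"t_focal_s={self.t_focal_s} must not exceed t_spread_s={self.t_spread_s}"
            )
        if self.lateral_boundary not in ("open_exit", "closed"):
            raise ConfigError(
                f"lateral_boundary must be 'open_exit' or 'closed', "
                f"got {self.lateral_boundary!r}"
            )
        if self.stall_guard_steps <= 0:
            raise ConfigError("stall_guard_steps must be positive")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(cls.__dataclass_fields__)


def census(cells: dict[int, CellAgent], lattice: Lattice) -> dict:
    """State counts, population and confluence (occupied row-0 fraction)."""
    counts = {s: 0 for s in CellState}
    for cell in cells.values():
        counts[cell.state] += 1
    return {
        "n_suspended": counts[CellState.SUSPENDED],
        "n_contact": counts[CellState.CONTACT],
        "n_focal": counts[CellState.FOCAL],
        "n_spread": counts[CellState.SPREAD],
        "n_inhibited": counts[CellState.INHIBITED],
        "population": len(cells),
        "confluence": lattice.occupied_in_row(0) / lattice.width,
    }
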