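"""Orchestration: phases on one global clock, replicates, summaries.

A run advances a single clock in seconds. While any cell is suspended the
step is ``dt_sedimentation_s`` (0.5 s per descent iteration); once the
whole population is attached the clock coarsens to ``dt_attached_s`` and
each step runs, in order, focal/spreading attempts and then division
attempts, each over a fresh random permutation of the cells. Because
nothing changes between timer deadlines in the attached phase, the engine
advances directly to the next step time at which any timer can fire; the
skipped steps are provably no-ops, so the realized trajectory is one a
step-by-step schedule could also produce (a test checks a fully forced
instance).

A run ends at steady state — no suspended cells, no timer that can still
fire, no free division slot (substrate space is never released, so these
conditions are absorbing) — or at the hard cap ``t_max_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .attachment import attempt_focal, attempt_spread
from .model_core import (
    CellAgent,
    CellState,
    ConfigError,
    Event,
    EventKind,
    Lattice,
    SimulationConfig,
    Site,
    census,
)
from .proliferation import attempt_division
from .sedimentation import SedimentationStats, run_sedimentation_phase


@dataclass
class SimulationResult:
    """Complete record of one seeded run."""

    config: SimulationConfig
    seed: int
    events: list[Event]
    series: list[dict]
    final_lattice: Lattice
    cells: dict[int, CellAgent]
    key_times: dict[str, Optional[float]]
    sedimentation: SedimentationStats


@dataclass
class ReplicateSummary:
    """Aggregate over independent seeded replicates."""

    n_replicates: int
    key_time_stats: dict[str, dict[str, float]]
    final_population: dict[str, float]
    population_quantiles: dict[str, list[float]]
    key_time_samples: dict[str, list[float]] = field(default_factory=dict)


KEY_TIME_NAMES = (
    "first_contact_time_s",
    "all_surface_contact_time_s",
    "all_attached_time_s",
    "all_spread_or_inhibited_time_s",
)


def initialize(config: SimulationConfig, rng) -> tuple[Lattice, dict[int, CellAgent]]:
    """Place ``n_cells`` suspended cells uniformly at random, no overlap.

    Cells start in suspension, so sites are drawn without replacement from
    the rows strictly above the substrate (rows 1..H-1). Identical seeds
    give identical placements.
    """
    lattice = Lattice(config.grid_width_sites, config.grid_height_sites)
    region = [
        Site(col, row)
        for row in range(1, lattice.height)
        for col in range(lattice.width)
    ]
    if config.n_cells > len(region):
        raise ConfigError(
            f"n_cells={config.n_cells} exceeds the {len(region)} sites "
            f"available above the substrate"
        )
    chosen = rng.choice(len(region), size=config.n_cells, replace=False)
    cells: dict[int, CellAgent] = {}
    for cid, idx in enumerate(chosen):
        site = region[int(idx)]
        cells[cid] = CellAgent(id=cid, footprint=[site])
        lattice.place(site, cid)
    return lattice, cells


def _has_free_flanking_pair(cell: CellAgent, lattice: Lattice) -> bool:
    columns = sorted(s.column for s in cell.footprint)
    for pair in (
        (Site(columns[0] - 2, 0), Site(columns[0] - 1, 0)),
        (Site(columns[1] + 1, 0), Site(columns[1] + 2, 0)),
    ):
        if lattice.is_free(pair[0]) and lattice.is_free(pair[1]):
            return True
    return False


def _focal_is_blocked(cell: CellAgent, lattice: Lattice) -> bool:
    col = cell.site.column
    return not (
        lattice.is_free(Site(col - 1, 0)) or lattice.is_free(Site(col + 1, 0))
    )


def _next_deadline(
    cells: dict[int, CellAgent], lattice: Lattice, config: SimulationConfig, now: float
) -> Optional[float]:
    """Earliest future-or-due time at which any timer can still fire.

    ``None`` means the run has reached steady state: substrate occupancy
    only ever grows, so a focal cell with both sides blocked and a spread
    cell with no free flanking pair are permanently stuck.
    """
    deadlines = []
    for cell in cells.values():
        if cell.state == CellState.CONTACT:
            deadlines.append(cell.attach_time_s + config.t_focal_s)
        elif cell.state == CellState.FOCAL:
            due = cell.attach_time_s + config.t_spread_s
            if due > now or not _focal_is_blocked(cell, lattice):
                deadlines.append(due)
        elif cell.state in (CellState.SPREAD, CellState.INHIBITED):
            if _has_free_flanking_pair(cell, lattice):
                deadlines.append(cell.cycle_start_time_s + config.t_cycle_s)
    return min(deadlines) if deadlines else None


def _attached_step(
    lattice: Lattice,
    cells: dict[int, CellAgent],
    t: float,
    rng,
    config: SimulationConfig,
    events: list[Event],
    next_id: int,
) -> int:
    """One attached-phase step: adhesion attempts, then division attempts."""
    ids = sorted(cells)
    for i in rng.permutation(len(ids)):
        cell = cells[ids[int(i)]]
        attempt_focal(cell, t, config.t_focal_s, events)
        attempt_spread(cell, lattice, t, config.t_spread_s, rng, events)
    ids = sorted(cells)
    for i in rng.permutation(len(ids)):
        cell = cells[ids[int(i)]]
        if cell.state in (CellState.SPREAD, CellState.INHIBITED):
            daughter = attempt_division(
                cell, lattice, t, rng, config.t_cycle_s, next_id, events
            )
            if daughter is not None:
                cells[next_id] = daughter
                next_id += 1
    return next_id


def run_simulation(
    config: SimulationConfig,
    seed: Optional[int] = None,
    until: str = "steady",
) -> SimulationResult:
    """Run one seeded simulation.

    ``until='sedimentation'`` stops once no cell is suspended (descent
    phase only); ``until='steady'`` continues through adhesion and
    proliferation to steady state or ``t_max_s``. Identical (config,
    seed) pairs give identical results.
    """
    if until not in ("steady", "sedimentation"):
        raise ConfigError(f"unknown run mode {until!r}")
    run_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    lattice, cells = initialize(config, rng)
    events: list[Event] = []
    series: list[dict] = []

    def record(t: float) -> None:
        series.append({"time_s": t, **census(cells, lattice)})

    sed = run_sedimentation_phase(config, lattice, cells, rng, events, record)
    key_times: dict[str, Optional[float]] = {
        "first_contact_time_s": sed.first_contact_time_s,
        "all_surface_contact_time_s": sed.all_surface_contact_time_s,
        "all_attached_time_s": sed.all_attached_time_s,
        "all_spread_or_inhibited_time_s": None,
    }

    if until == "steady" and cells:
        t = sed.end_time_s
        dt = config.dt_attached_s
        next_id = max(cells) + 1
        while t < config.t_max_s:
            deadline = _next_deadline(cells, lattice, config, t)
            if deadline is None:
                break
            k = max(1, math.ceil((deadline - t) / dt - 1e-9))
            t_step = t + k * dt
            if t_step > config.t_max_s:
                break
            t = t_step
            next_id = _attached_step(lattice, cells, t, rng, config, events, next_id)
            record(t)
            if key_times["all_spread_or_inhibited_time_s"] is None and all(
                c.state >= CellState.SPREAD for c in cells.values()
            ):
                key_times["all_spread_or_inhibited_time_s"] = t

    return SimulationResult(
        config=config,
        seed=run_seed,
        events=events,
        series=series,
        final_lattice=lattice,
        cells=cells,
        key_times=key_times,
        sedimentation=sed,
    )


def summarize(result: SimulationResult) -> dict:
    """Key times, final population, confluence and spread fraction."""
    final = census(result.cells, result.final_lattice)
    population = final["population"]
    spread = final["n_spread"] + final["n_inhibited"]
    out = dict(result.key_times)
    out.update(
        {
            "final_population": population,
            "confluence": final["confluence"],
            "spread_fraction": (spread / population) if population else 0.0,
            "n_divisions": sum(
                1 for e in result.events if e.kind == EventKind.DIVISION
            ),
            "n_exits": sum(1 for e in result.events if e.kind == EventKind.EXIT),
        }
    )
    return out


def replicate_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed: first word of SeedSequence([base, i])."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def run_replicates(
    config: SimulationConfig,
    n: int,
    base_seed: int,
    until: str = "steady",
) -> ReplicateSummary:
    """Run ``n`` independent seeded replicates and aggregate key times.

    Replicate seeds derive deterministically from ``base_seed``, so the
    summary is reproducible for fixed (config, n, base_seed).
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    samples: dict[str, list[float]] = {name: [] for name in KEY_TIME_NAMES}
    final_pops: list[int] = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n):
        result = run_simulation(config, seed=replicate_seed(base_seed, i), until=until)
        for name in KEY_TIME_NAMES:
            value = result.key_times[name]
            if value is not None:
                samples[name].append(value)
        final_pops.append(len(result.cells))
        times = np.array([row["time_s"] for row in result.series])
        pops = np.array([row["population"] for row in result.series])
        curves.append((times, pops))

    key_time_stats = {}
    for name, values in samples.items():
        if values:
            arr = np.asarray(values, dtype=float)
            key_time_stats[name] = {
                "n": int(arr.size),
                "min": float(arr.min()),
                "median": float(np.median(arr)),
                "mean": float(arr.mean()),
                "max": float(arr.max()),
                "std": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "q05": float(np.quantile(arr, 0.05)),
                "q95": float(np.quantile(arr, 0.95)),
            }
        else:
            key_time_stats[name] = {"n": 0}

    pops_arr = np.asarray(final_pops, dtype=float)
    final_population = {
        "min": float(pops_arr.min()),
        "median": float(np.median(pops_arr)),
        "mean": float(pops_arr.mean()),
        "max": float(pops_arr.max()),
    }

    t_end = max(float(times[-1]) for times, _ in curves)
    grid = np.linspace(0.0, t_end, 101)
    stacked = np.empty((len(curves), grid.size))
    for j, (times, pops) in enumerate(curves):
        idx = np.searchsorted(times, grid, side="right") - 1
        stacked[j] = pops[np.clip(idx, 0, len(pops) - 1)]
    population_quantiles = {
        "time_s": grid.tolist(),
        "q05": np.quantile(stacked, 0.05, axis=0).tolist(),
        "q50": np.quantile(stacked, 0.50, axis=0).tolist(),
        "q95": np.quantile(stacked, 0.95, axis=0).tolist(),
    }

    return ReplicateSummary(
        n_replicates=n,
        key_time_stats=key_time_stats,
        final_population=final_population,
        population_quantiles=population_quantiles,
        key_time_samples=samples,
    )
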