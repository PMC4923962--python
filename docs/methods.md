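# Methods

## Model

fibrosim simulates a population of anchorage-dependent cells in a 2D
vertical cross-section of a stationary culture vessel. Space is a regular
lattice of square sites whose edge equals one cell diameter (15 µm), with
67 columns and 33 rows for the default 1 mm × 0.5 mm window
(`discretize_domain` rounds the physical extents to whole sites).
Coordinates are 0-based `(column, row)` with row 0 the substrate at the
bottom, so "falling" means the row index decreases — a convention chosen
to make the descent direction impossible to confuse. Each cell occupies
exactly one site (two once spread), and at most one cell may hold a site
at any time (an exclusion process).

Each cell advances through an irreversible life cycle:

SUSPENDED → CONTACT → FOCAL → SPREAD (↔ INHIBITED)

SUSPENDED cells drift in the medium; CONTACT cells have touched the
substrate and retain their spherical shape; FOCAL cells have formed the
initial anchoring link; SPREAD cells have extended onto a second
contiguous substrate site; INHIBITED is a re-checkable flag on spread
cells that found no room to divide, not a distinct morphology — it
reverts to SPREAD eligibility whenever a later check finds space, because
inhibition is a condition of the surroundings rather than of the cell.
The only backward edge in the state machine is that flag pair; attempted
regressions raise an error.

### Sedimentation

Gravity is the only driver: the medium is stationary and undisturbed.
Physically, a 15 µm sphere slightly denser than the medium settles at the
Stokes terminal velocity v = (2/9) r_c² (ρ_c − ρ_m) g / η, obtained by
balancing the drag F = 6πRηv against the apparent weight; both formulas
are implemented as reporting utilities (`stokes_velocity`, `stokes_drag`)
with g = 9.8 m/s². The automaton itself moves cells by a discrete,
gravity-biased rule: the von Neumann neighborhood is split into three
levels — one position above (probability a/2), two lateral (a total), one
below (2a) — and normalization a/2 + a + 2a = 1 fixes a = 2/7, giving
level probabilities 1/7, 2/7, 4/7. The lateral total is split equally
(1/7 each side) since nothing distinguishes left from right. The two
descriptions are deliberately decoupled: the ladder's net drift is 3/7 of
a site per iteration (≈ 12.9 µm/s at 0.5 s per step and 15 µm sites), a
scale fixed by the rule itself and not calibrated to any particular
(ρ_c, ρ_m, η) combination. No ladder or time-step parameter is fitted to
a target velocity.

Per iteration (0.5 s), every suspended cell draws a destination:

* The admissible targets are the free in-domain axial neighbors, plus a
  lateral off-grid "exit" when the lateral boundary is open. The top edge
  is reflective (an off-grid upward move is never admissible); no cell
  ever enters from outside.
* Ladder probabilities are renormalized over the admissible set. This is
  equivalent in distribution to redrawing until a free position is found
  (each redraw is independent, so conditioning on landing in the
  admissible set is exactly renormalization) while always terminating.
  With no admissible target the cell keeps its place for that step.
* Sampling inverts the cumulative distribution in the fixed order (down,
  left, right, up), consuming exactly one uniform variate, so seeded runs
  are bit-reproducible.
* Cells are processed once each, in a fresh random permutation per
  iteration. Sequential updating within the iteration preserves exclusion
  without a separate conflict-resolution pass: when two cells contest a
  site, the first one processed takes it and the second renormalizes over
  what remains — the same re-search behavior, realized without rejection
  loops.

A cell whose draw lands on row 0 attaches (CONTACT) immediately and
irreversibly; suspended cells resting on top of others keep sampling
moves until they find substrate. Cells drawing a lateral off-grid move
under the open boundary leave the population (EXIT); a `closed` mode
(lateral moves renormalized away at the walls) exists for the
absorption-time oracle tests. A stall guard aborts if no cell moves for
`stall_guard_steps` consecutive iterations; since upward moves are
admissible whenever the site above is free this cannot trigger in an open
column, and the guard mostly documents the termination argument.

Three milestone statistics are recorded. *First substrate contact*: time
of the first attachment. *All-surface contact*: first time every
surviving cell is on the substrate, axially adjacent to an attached cell,
or resting directly on a settled stack (a same-column chain of suspended
cells standing on an attached cell) — contact with "a surface", which
precedes full attachment. The flag is sticky per cell. *All attached*:
time the last surviving cell reaches row 0. Only row-0 arrival starts
adhesion; touching a stack does not, which keeps the two later milestones
distinct.

### Adhesion

No rate law is available for the maturation of adhesions, only milestone
times, so the simplest consistent mechanism is used: deterministic
per-cell timers measured from the moment of substrate contact.
At `t_focal_s` the cell becomes FOCAL (still one site, now anchored); at
`t_spread_s` it attempts to spread by claiming one free flanking row-0
site, chosen uniformly when both sides are free. If both flanks are
occupied the cell stays FOCAL and retries every step — on a crowded
substrate it may remain round indefinitely, which is exactly the crowding
phenotype. Spread cells occupy two contiguous row-0 sites and never
regress to one.

### Proliferation

Division is anchorage-dependent: only spread cells divide (cells in
suspension do not). After `t_cycle_s` on the cycle clock (started at
spread completion, reset on each division for both parent and daughter —
no refractory period beyond the cycle itself), the cell examines the two
pairs of contiguous row-0 sites flanking its footprint: the two sites
immediately left of its left end and the two immediately right of its
right end. Pairs truncated by the domain edge are not free. If a free
pair exists (uniform choice between two), the daughter is born SPREAD
into it — the rule allocates exactly those two side positions, so
daughters skip sedimentation and adhesion. Otherwise the cell is flagged
INHIBITED. Since attached cells never move, die or detach, substrate
space is never released, divisions monotonically consume it, and the
population reaches a steady state; at most ⌊width/2⌋ cells can ever be
spread, so a 67-site substrate holds at most 33 spread cells regardless
of how many settled.

## Parameters

| name | meaning | unit | default | rationale |
|---|---|---|---|---|
| `grid_width_sites` × `grid_height_sites` | domain | sites | 67 × 33 | 1 mm × 0.5 mm at 15 µm/site |
| `site_size_um` | site edge = cell diameter | µm | 15 | fibroblast in suspension |
| `n_cells` | initial population | – | 50 | leaves free substrate for spreading |
| `dt_sedimentation_s` | descent iteration | s | 0.5 | descent-phase clock |
| `dt_attached_s` | attached-phase iteration | s | 20 | ≈ 240 iterations per 80 min |
| `t_focal_s` | contact → focal timer | s | 6000 | first elongations ≈ 100 min after settling |
| `t_spread_s` | contact → spread timer | s | 10800 | spreading complete ≈ 180 min |
| `t_cycle_s` | division clock | s | 86400 | 24 h population doubling |
| `lateral_boundary` | `open_exit` / `closed` | – | open_exit | cells may leave; none enter |
| `t_max_s` | hard cap | s | 604800 | safety bound, 7 days |
| `seed` | RNG seed | – | 0 | reproducibility |

The attached-phase step is genuinely ambiguous: the source timeline maps
240 iterations to ≈ 80 min (20 s each) but 540 iterations to ≈ 145 min
(≈ 16 s each). We default to 20 s and keep it configurable; because all
timers are stored in seconds, results are robust to the step size up to
quantization of event times onto the step grid.

## Initial placement

Runs start with `n_cells` distinct sites drawn uniformly without
replacement from the rows strictly above the substrate (rows 1..H−1):
cells begin *in suspension*, so none is pre-attached at t = 0. Externally
constructed placements that do put a suspended cell on row 0 are attached
by a pre-pass at time 0. The fixture generator (`generate_fixture`)
provides the deterministic placements the tests build on: a single-column
domain for the absorption-time oracle, a packed substrate row for
inhibition tests, evenly spaced spread cells for division tests, and a
seeded uniform placement for integration tests.

What the generator emulates is the geometry of a dilute seeding event:
independent positions, uniform in the window, one cell per site. It does
not emulate cell-size variability, aggregates in suspension, medium flow,
or the 3D depth of a real flask (the window is one cross-section, and the
open lateral boundary only lets cells leave). Passing tests therefore
validate the automaton's rules and their stated statistics, not agreement
with any particular wet-lab culture.

## Orchestration and numerics

One global clock advances in seconds: 0.5 s steps while any cell is
suspended, `dt_attached_s` afterwards. Each attached-phase step runs all
focal/spreading attempts (fresh random permutation), then all division
attempts (fresh permutation, daughters joining from the next step).
Because nothing can change between timer deadlines, the engine jumps
directly to the next step time at which some timer can fire; skipped
steps are provably no-ops (substrate occupancy only grows, so a blocked
focal or inhibited cell cannot unblock spontaneously), and the same
absorbing argument defines steady-state termination. Timer comparisons
use a 1 ns tolerance so a deadline falling exactly on a step boundary
fires on that step. Ladder probabilities are exact `Fraction`s; they are
converted to floats only inside the one-uniform CDF inversion.

Replicates derive their seeds as the first output word of
`numpy.random.SeedSequence([base_seed, index])`, making any replicate
reproducible in isolation. Summaries report per-milestone n, min, median,
mean, max, standard deviation and the central 90% interval, plus
population-curve quantiles on a common time grid (step-function
interpolation).

`scripts/acceptance.py` recomputes the three descent milestones from 200
replicates of the default configuration — a desk-scale choice that keeps
the whole computation under a minute while putting the standard error of
each median well below the grid's 0.5 s time resolution.

## Known limitations

* **The discrete walk is slower than the continuum estimate.** The
  ladder's net drift (3/7 site per 0.5 s ≈ 12.9 µm/s) is the model's
  intrinsic settling speed; published continuum estimates for comparable
  cells (∼10⁻⁵–10⁻⁴ m/s) are faster. Milestone medians under the
  default geometry — first contact ≈ 0.5 s, all-surface contact ≈ 45 s,
  all attached ≈ 95 s over 200 replicates — are therefore on the slow
  side of single-realization reports for comparable setups, and the
  all-attached time has a heavy right tail: the last cells often land on
  occupied columns and must random-walk laterally (at conditional
  probability ⅓ per free direction once their downward site is blocked)
  to find free substrate. We report the dispersion rather than calibrate
  the ladder, which is part of the model's definition.
* **Not every cell can spread on a crowded substrate.** 50 cells × 2
  sites > 67 sites, so full spreading of a default population is
  geometrically impossible; runs report the spread fraction and
  confluence instead of assuming completion.
* **No detachment, death, migration of adhered cells, or nutrient
  limitation**; contact inhibition is purely geometric. Cell-cell
  adhesion in suspension and aggregate formation are out of scope, as are
  continuous cell shapes and adhesion mechanics.
* Whether an inhibited cell may divide if space frees is not empirically
  settled; the model allows it (the flag re-checks), though under the
  current rule set space never frees once consumed.
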