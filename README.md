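# fibrosim

A seeded, testable cellular-automaton simulator of how anchorage-dependent
cells (3T3 murine fibroblasts are the motivating system) settle out of
suspension, adhere to a substrate, spread, and proliferate until contact
inhibition stops them.

The model is a 2D vertical cross-section of a culture vessel — a 1 mm ×
0.5 mm window meshed into 15 µm square sites (67 × 33), one site per cell
diameter, row 0 being the substrate. It runs in three coupled phases on a
single clock:

1. **Sedimentation.** Each suspended cell performs a gravity-biased random
   walk on its von Neumann neighborhood (no diagonal moves). The four
   axial positions are grouped into three levels — above, lateral, below —
   with probabilities a/2, a, 2a; normalization a/2 + a + 2a = 1 gives
   a = 2/7, hence per-position probabilities (up, left, right, down) =
   (1/7, 1/7, 1/7, 4/7). Occupied targets are excluded and the remaining
   probabilities renormalized (equivalent to redrawing until a free
   position is found); a fully boxed-in cell keeps its place. Cells
   leaving through the open lateral boundary exit the population. One
   iteration is 0.5 s. The library also provides the Stokes terminal
   velocity v = (2/9) r_c² (ρ_c − ρ_m) g / η as a reporting utility; the
   walk uses the ladder, not v.
2. **Adhesion.** A cell reaching row 0 attaches irreversibly. Per-cell
   timers measured from contact drive the morphological sequence: focal
   adhesion (round, anchored) at `t_focal_s` (default 6000 s ≈ 100 min)
   and spreading at `t_spread_s` (default 10800 s = 180 min), realized as
   claiming one free flanking substrate site so the footprint becomes two
   contiguous sites.
3. **Proliferation.** A spread cell with a cell-cycle clock elapsed
   (default 24 h) searches the two site-pairs flanking its footprint; if
   one is completely free the cell divides and the daughter is born spread
   into that pair. Otherwise the cell is contact-inhibited — a flag that
   is re-checked and would lift if space ever freed. A confluent substrate
   therefore reaches a steady state with no further divisions.

Every run is driven by one integer seed and is bit-reproducible; the
result is an event log (attachments, spread completions, divisions,
exits), a per-step state-count time series, and the final lattice.

## Worked example

One default run (67×33 grid, 50 cells, seed 1), from the shell:

```bash
$ fibrosim simulate --seed 1 --out-dir out/
first_contact_time_s: 0.5
all_surface_contact_time_s: 47.0
all_attached_time_s: 77.5
all_spread_or_inhibited_time_s: None
final_population: 49
confluence: 0.9850746268656716
spread_fraction: 0.3469387755102041
n_divisions: 3
n_exits: 4
outputs written to out/
```

Reading: the first of the 50 cells touched the substrate after 0.5 s; by
47 s every surviving cell was touching the substrate, an attached cell, or
a settled stack; by 77.5 s all of them sat on the substrate. During the
descent 4 cells drifted out through the open lateral boundary. In the
attached phase the 46 survivors compete for the 67 substrate sites: 17
managed to spread onto two sites (spread fraction 0.35 of the final 49),
3 of those found room to divide, and the run ended at 98.5% confluence
with the remainder stuck as round, focally adhered cells. The output
directory holds `timeseries.csv`, `events.csv`, `metadata.json` and a
plain-text `final_snapshot.txt` side view.

The settling-velocity utility, for a 15 µm cell in a water-like medium:

```bash
$ fibrosim stokes --cell-density 1050 --medium-density 1000 --viscosity 0.001
settling velocity: 6.125e-06 m/s
drag at terminal velocity: 8.65901e-13 N
```

Replicates with dispersion (descent phase only):

```bash
$ fibrosim replicates --n 20 --seed 1 --phase sedimentation --out-dir reps/
first_contact_time_s: median 0.5 s (90% interval 0.5-1, n=20)
all_surface_contact_time_s: median 45 s (90% interval 36.5-54.8, n=20)
all_attached_time_s: median 93 s (90% interval 59.6-253, n=20)
summary written to reps/replicate_summary.json
```

The same is available from Python:

```python
from fibrosim import SimulationConfig, run_simulation, summarize
result = run_simulation(SimulationConfig(), seed=1)
print(summarize(result))
```

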