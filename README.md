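# chondrosim

Centre-based (overlapping-spheres) simulation of clonal column formation in
embryonic cranial cartilage.

In growth plates of the embryonic skull, chondrocytes descended from a single
progenitor arrange into short transversal columns, packed side by side into a
flat cartilage sheet. `chondrosim` models how this order emerges: cells are
spheres whose midpoints move by overdamped mechanics under a repulsion-only
pair force, divide with oriented (or deliberately misoriented) division axes,
and are confined between rigid planes that stand in for the perichondrium.
The package is aimed at computational developmental biologists who want to
test, in silico, which cell behaviours are sufficient for columnar order —
division orientation, extracellular-matrix spacing, boundary distance, sheet
thickness, sequential proliferation, and column intercalation.

## Model

Cell midpoints **x**_i obey

    eta dx_i/dt = sum_{j != i} F_ij,
    F_ij = F(||r_ij||) r_ij / ||r_ij||,
    F(r) = -mu (1 - r/s)^2  for r <= s,  0 otherwise,

with friction coefficient eta, spring stiffness mu and rest length s (one
cell diameter d; no adhesive branch — proliferating chondrocytes are wrapped
in matrix and do not adhere to each other). The ODEs are integrated by
forward Euler with step dt; midpoints leaving the slab l <= z <= u are
projected back onto the violated plane.

Each cell's cycle is a fixed phase g1 plus an exponential phase with mean
g2 (drawn per cell at creation, which desynchronises divisions). At
division the mother is replaced by two daughters at +-(r0/2) along the
division direction: deterministic (0,0,1) (vertical), uniform on a spherical
cap of half-angle theta_max (cone, cos theta ~ U[cos theta_max, 1]), uniform
on the sphere, or a random lateral azimuth. A clone stops proliferating once
its clonal envelope (all descendants of one ancestor) holds n_max(t) cells;
the limit may step up over time to model sequential proliferative phases.

Order is quantified by the **envelope projection area**

    a = mean over envelopes E of (max_E x - min_E x)(max_E y - min_E y),

which is zero for a perfect transversal column and grows with lateral
spread of the clone.

Two initial configurations are built in: (i) a mesenchymal condensation —
96 proliferative cells on a perturbed honeycomb lattice (spacing c*s)
spread between the planes — and (ii) a pre-formed columnar sheet of
post-mitotic chondrocytes capped by perichondrial layers, in which
activated perichondrial cells divide once to seed new envelopes
(optionally into a deliberately carved column gap).

## Worked example

Run one seeded simulation of the default condensation with vertical
divisions and inspect the outcome:

```sh
$ chondrosim simulate --scenario fig5_oriented --seed 3 --out out/
fig5_oriented:oriented seed=3: N(T)=384, endpoint envelope projection area = 0.0326 d^2
```

The 96 ancestors each grew a 4-cell envelope (384 cells at T = 80 a.u.) and
the mean envelope projection area is 0.03 d^2 — essentially perfect columns
(a fully random division orientation gives ~1.3 d^2 instead). `out/` holds
the snapshot series, the division event log and the metric time series as
CSV; add `--vtk` for legacy-VTK point clouds viewable in ParaView.

The same from Python:

```python
from chondrosim import run, metric_series
from chondrosim.experiments import condensation_scenario

traj = run(condensation_scenario(seed=3, mode="vertical"))
print(traj.final_population.n_cells)        # 384
print(metric_series(traj).endpoint())       # 0.0326...
```

Full multi-seed experiments (8 seeds per arm, as in the study design):

```sh
$ chondrosim experiment run fig5_random --seeds 8 --out out/
 experiment    arm subset  endpoint_mean  endpoint_sd  n_seeds
fig5_random random    all       1.360751     0.087065        8
```

Registered experiments: `fig5_random`, `fig5_oriented`, `fig6_cone`,
`fig7_spacing`, `fig8_boundary`, `fig9_thickness`, `fig10_sequential`,
`fig11_insertion`, `fig12_gap` (see `chondrosim experiment run --help`).

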