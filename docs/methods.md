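# Methods

## Model

Cells are spheres of diameter d = 1 identified by their midpoints; the
population state is the set of midpoints plus per-cell lineage and cycle
state. Midpoints follow overdamped dynamics — at cellular scales drag
against the extracellular matrix dominates inertia — so velocity is
proportional to the net pairwise force:

    eta dx_i/dt = sum_{j != i} F_ij.

The pair force is repulsion-only and piecewise quadratic,
F(r) = -mu (1 - r/s)^2 for r <= s and 0 beyond, directed along the line of
centres. It derives from the pair potential U(r) = (mu s / 3)(1 - r/s)^3
(r <= s), so the division-free dynamics is a gradient flow and the total
pair potential decreases monotonically. The absence of an adhesive branch is
a biological statement: once chondrocyte differentiation starts, cells are
separated by matrix and express no cell-cell adhesion molecules. The exact
functional form is not critical in repulsion-dominated regimes; comparable
force laws (cubic, generalized linear spring) can be parameterised to match.

Cell division replaces the mother with two daughters at
mother +- (r0/2) * direction, so the mother's midpoint lies exactly between
them and the daughters start r0 = 0.3 d apart. Division timing is a
two-phase cycle: fixed g1 = 3 a.u. plus an exponential phase with mean
g2 = 10 a.u., drawn independently per cell at creation. The exponential
phase desynchronises neighbouring divisions, and the fixed phase puts a
floor between successive divisions on one lineage; both help keep the
dynamics quasistatic. Cell volume does not change over the cycle.

A clonal envelope is the set of descendants of one initial ancestor. Cells
stop dividing when their envelope holds n_max cells (a stand-in for
chondrocyte maturation; default 4). The limit is a right-continuous step
function of time, so sequential proliferative phases (e.g. 4 cells until
t_w = 50 a.u., then 6) are expressed as a schedule. Because each division is
net +1 cell, a clone of size n_max - 1 may still divide; envelopes reach the
limit exactly and freeze.

Rigid planes at z = l and z = u model the mechanical influence of the
perichondrium: after each Euler update any midpoint outside [l, u] is
projected back onto the violated plane. The projection acts on midpoints
only; sphere surfaces may protrude. There are no lateral boundaries — the
friction term and the absence of lateral external forces limit spreading.

## Order metric

Order is measured by the envelope projection area: per envelope, the product
of its x- and y-extents over member midpoints, averaged over envelopes.
Perfect transversal columns give 0; laterally spreading clones give values
of order d^2. Perichondrial cells never count as envelope members. For
insertion experiments the average can be restricted to envelopes seeded by
activated perichondrial cells (`inserted_only`), which is how inserted
columns are compared against columns grown from a condensation. An external
table of cell centres grouped by clone can be scored with the same metric
(`chondrosim score-points`).

## Initial configurations

Configuration (i), mesenchymal condensation: n_x * n_y = 96 proliferative
cells on a honeycomb lattice (rows offset by half the spacing, row
separation (sqrt(3)/2) c s, nearest-neighbour distance c*s = 1.075 d,
centred at the origin), each founding its own envelope, with z drawn
uniformly in (l, u) = (0, 3.5) (variants: pinned at the lower plane or the
midplane). Larger c means more matrix between progenitors.

Configuration (ii), pre-formed sheet: the same lateral lattice, each site
carrying a transversal column of four post-mitotic chondrocytes at
z = 1..4 plus perichondrial caps at z = 0 and z = 5, with l = 0, u = 5
(the vertical layout is not prescribed by the source geometry; unit-diameter
stacking inside the planes is this package's declared convention, keeping
the per-cell height of configuration (i)). A chosen number of perichondrial
cells (default 9, drawn uniformly across both layers) is activated; each
divides exactly once, parallel to the sheet, into one post-mitotic
perichondrial daughter and one chondrocyte daughter that founds a fresh
envelope (capped at n_max = 5, the ancestor not counting) and divides
vertically thereafter. The gap variant is a 5x5-column sub-sheet whose
central column of chondrocytes is deleted (the caps remain); the bottom cap
of the deleted column is the single activated cell and its seeding division
points transversally into the gap. Whether the seeding division of an
insertion should point laterally or into available space is not prescribed;
both modes are implemented (`peri_placement="lateral" |
"transversal_interior"`), with lateral the default for the full sheet and
interior-pointing the default for the gap scenario. Perichondrial daughters
are never re-activated.

Every initial midpoint is perturbed by an independent random displacement
with uniformly random direction and magnitude ~ Uniform[0, p_max]
(p_max = 0.1 d). Two conventions were candidates — a one-sided per-coordinate
shift and this displacement vector — and the vector form is adopted because
it is the one consistent with the model's closed-form contact bound: each of
two nearest neighbours can move up to p_max toward the other, so the minimal
achievable initial distance is c*s - 2*p_max (0.8 d at c = 1.0, 0.9 d at
c = 1.1, hence a force ratio of exactly 4 between those packings, since
F(0.8)/F(0.9) = (0.2/0.1)^2). The same convention reproduces the reference
endpoint values of the order metric where the one-sided reading does not.

## Parameters

| symbol  | meaning                                   | default | units |
|---------|-------------------------------------------|---------|-------|
| T       | simulation end time                       | 80      | a.u.  |
| dt      | Euler time step                           | 0.0083333 | a.u.|
| eta     | friction coefficient                      | 1.0     | —     |
| n_x,n_y,n_z | lattice counts                        | 8, 12, 1| —     |
| p_max   | max initial midpoint displacement         | 0.1     | d     |
| u, l    | upper / lower plane                       | 3.5, 0  | d     |
| n_max   | envelope size limit                       | 4       | cells |
| s       | rest length                               | 1.0     | d     |
| mu      | repulsive stiffness                       | 20.0    | —     |
| g1      | fixed cycle phase                         | 3       | a.u.  |
| g2_mean | mean exponential cycle phase              | 10      | a.u.  |
| r0      | daughter separation                       | 0.3     | d     |
| c       | lateral lattice scaling                   | 1.075   | —     |

Only mu/eta matters for the relaxation timescale; the defaults put the
system deep in the quasistatic regime (mechanical relaxation much faster
than the ~13 a.u. mean cycle), which mirrors the biology: relaxation in
minutes versus a roughly daily cell cycle. `quasistatic_diagnostic` checks
this property on any trajectory by reporting the maximum per-step
displacement immediately preceding each division; after the last division
the per-step displacement decays below 1e-3 d within a few a.u., so the
end state is a mechanical equilibrium. theta_max, the cone half-angle of
perturbed vertical divisions, is specified in radians; the reference sweep
is {0, pi/128, pi/32, pi/8}.

## Numerics

* Forward Euler, synchronous update, forces evaluated at pre-update
  positions; step order is divisions -> mechanics -> z-projection. Forces
  are never re-evaluated mid-step after a division; daughters first
  contribute at the next step's force evaluation.
* Neighbour search: a numba linked-cell accumulator (uniform grid, bin width
  s) exploits the force's compact support; it visits exactly the same pair
  set as the all-pairs reference and accumulates each pair antisymmetrically
  (total internal force is exactly zero), but its floating-point summation
  order differs from plain ascending-id all-pairs. The all-pairs kernel and
  a pure-Python reference are kept and cross-checked to 1e-12. Populations
  spread over too many bins, or smaller than 64 cells, fall back to
  all-pairs inside the kernel.
* Event-driven stepping: division times are known at cell creation
  (birth + g1 + g2), so stretches with no division due, no schedule
  breakpoint and no snapshot boundary are integrated in one compiled block;
  the result is identical to stepping dt at a time (tested bitwise).
  Division-ready cells are processed in ascending cell-id order, and a
  same-clone sibling due in the same step is re-gated after the first
  division.
* Randomness: one generator per scenario, consumed in a fixed documented
  order (geometry, then per event: direction draw, then the two daughters'
  cycle draws). Identical scenario + seed reproduces trajectories bit for
  bit; multi-seed experiments derive per-run seeds from
  (base seed, arm index, replicate index).
* Coincident midpoints (< 1e-12 d apart) would make the force direction
  undefined; the policy substitutes a uniformly random unit direction at the
  contact magnitude mu. Daughters are always born r0 apart, so this is a
  safeguard, never a modelled regime. A daughter placed beyond a plane is
  pulled back by the same z-projection as any other midpoint at the end of
  its birth step.
* Non-finite positions abort the run with a diagnostic naming the cell and
  step.

## Accuracy of the integrator

At the default dt, the engine matches an adaptive high-accuracy ODE solution
to ~1e-4 d on lattice-grade overlaps (pair distances ~0.85 d) and tracks the
closed-form two-cell overlap decay 1 - r(t) = 1/(1/(1-r0) + 2 mu t / eta)
to better than 1e-3 d at unit-time checkpoints even from the harsh
post-division separation r0 = 0.3. Immediately after a division the Euler
transient is locally larger, but the contractive dynamics (1/w grows
linearly in time) erases it before the next division in the quasistatic
regime. Doubling dt leaves the endpoint equilibria intact.

## What the simulated conditions do and do not show

The reference conditions are those of the study design: 96-ancestor
condensations (8 x 12 x 1), T = 80 a.u., 8 independent seeds per condition,
envelope limits 4-8, and the experiment-specific settings listed in
`chondrosim.experiments` (boundary height scaled as u = (3.5/4) n_max when
the limit changes — the per-cell height convention; t_w = 50 a.u. for the
sequential schedule; 9 activated perichondrial cells for full-sheet
insertion; n_max = 5 for inserted envelopes). Endpoints are read at the
final recorded time.

The synthetic configurations emulate the geometry and proliferation
statistics of early cranial cartilage but deliberately omit: formation of
the condensation itself (recruitment/migration), explicit matrix particles
or spatially varying friction, volume growth over the cycle, adhesion,
chemotaxis or post-division daughter sliding, dynamic or non-planar
boundaries, and any biochemical signalling. Agreement of the in-silico
endpoints therefore speaks to the sufficiency of mechanics plus oriented
division for columnar order under these idealisations, not to molecular
mechanism. Envelope completion by T is stochastic: rarely a straggler cell's
exponential phase outlasts the run, leaving an envelope one short of the
limit; endpoints average over envelopes regardless.

## Known limitations

* The honeycomb lattice is rectangular in outline; non-rectangular sheet
  outlines and rod-like geometries are out of scope.
* The envelope projection area is axis-aligned by construction; it is not
  rotation-invariant in the lateral plane (extent products are compared in
  the lattice frame, as the metric is defined).
* Whether pre-existing sheet chondrocytes are permanently post-mitotic or
  merely at their envelope limit is not prescribed; they are post-mitotic
  here.
* The interval between recorded snapshots (default 1 a.u.) bounds the time
  resolution of metric curves; endpoints are insensitive to it because the
  end state is an equilibrium.
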