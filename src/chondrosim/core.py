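"""Core domain types and the pairwise mechanical force law.

Cells are represented as overlapping spheres identified by their midpoints
(a "centre-based" model). Midpoints obey overdamped dynamics,

    eta * dx_i/dt = sum_{j != i} F_ij,

so velocity, not acceleration, is proportional to force: at the length and
speed scales of embryonic tissue the Reynolds number is tiny and inertia is
negligible compared to drag against the extracellular matrix.

The pairwise force is repulsion-only and piecewise quadratic,

    F(r) = -mu * (1 - r/s)**2   for r <= s,   0 otherwise,

directed along the line connecting the two midpoints. ``s`` is the rest
length (one cell diameter, interpretable as the sum of two cell radii):
cells further apart than ``s`` do not interact at all. The absence of an
adhesive branch reflects chondrocyte biology -- proliferating chondrocytes
are wrapped in extracellular matrix and do not form adhesive cell-cell
bonds.

Lengths are measured in cell diameters ``d`` and times in arbitrary units
``a.u.`` throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "CHONDROCYTE",
    "PERICHONDRIAL",
    "COINCIDENCE_THRESHOLD",
    "ModelParams",
    "Cell",
    "Population",
    "force_magnitude",
    "pair_potential",
    "pairwise_force",
    "net_force",
    "net_forces",
    "minimal_initial_pair_distance",
    "worst_case_force_ratio",
]

CHONDROCYTE = "chondrocyte"
PERICHONDRIAL = "perichondrial"

KIND_CODE = {CHONDROCYTE: 0, PERICHONDRIAL: 1}
KIND_NAME = {0: CHONDROCYTE, 1: PERICHONDRIAL}

#: Pair distances below this (in d) are treated as coincident midpoints;
#: the force direction is then drawn uniformly at random (see pairwise_force).
COINCIDENCE_THRESHOLD = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Model and numerical parameters.

    Defaults are the reference parameterisation used by every experiment
    unless an experiment states otherwise.

    Attributes
    ----------
    T : float
        Simulation end time (a.u.).
    dt : float
        Forward-Euler time step (a.u.).
    eta : float
        Friction coefficient between cells and the surrounding matrix.
        Only the ratio mu/eta matters for the relaxation timescale.
    n_x, n_y, n_z : int
        Lattice counts of the initial configuration.
    p_max : float
        Maximum perturbation added (one-sided, Uniform[0, p_max]) to every
        coordinate of every initial midpoint (d).
    u, l : float
        z-coordinates of the upper and lower rigid boundary planes (d),
        modelling the mechanical influence of the perichondrium.
    n_max : int
        Cap on the number of cells per clonal envelope; stands in for
        chondrocyte maturation, which halts proliferation.
    s : float
        Rest length of the pair interaction (d).
    mu : float
        Repulsive spring stiffness.
    g1 : float
        Fixed duration of the first cell-cycle phase (a.u.).
    g2_mean : float
        Mean of the exponentially distributed second phase (a.u.).
    r0 : float
        Separation of the two daughters at a division event (d).
    c : float
        Lateral lattice scaling: in-plane nearest-neighbour spacing is c*s.
        Values above 1 represent extra extracellular matrix between
        progenitor cells.
    """

    T: float = 80.0
    dt: float = 0.0083333
    eta: float = 1.0
    n_x: int = 8
    n_y: int = 12
    n_z: int = 1
    p_max: float = 0.1
    u: float = 3.5
    l: float = 0.0
    n_max: int = 4
    s: float = 1.0
    mu: float = 20.0
    g1: float = 3.0
    g2_mean: float = 10.0
    r0: float = 0.3
    c: float = 1.075

    def __post_init__(self) -> None:
        if not self.l < self.u:
            raise ValueError(f"require l < u, got l={self.l}, u={self.u}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not 0 < self.r0 < self.s:
            raise ValueError(f"require 0 < r0 < s, got r0={self.r0}, s={self.s}")
        if self.p_max < 0:
            raise ValueError("p_max must be non-negative")
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise ValueError("lattice counts n_x, n_y, n_z must be >= 1")
        if self.g1 < 0 or self.g2_mean <= 0:
            raise ValueError("require g1 >= 0 and g2_mean > 0")
        if self.T < 0:
            raise ValueError("T must be non-negative")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - names
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        """Load parameters from a YAML config file.

        Keys are exactly the field names; either a flat mapping or a
        mapping with a top-level ``params`` section is accepted.
        """
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "params" in data and isinstance(data["params"], dict):
            data = data["params"]
        return cls.from_dict(data)


@dataclass
class Cell:
    """A single cell, identified by a unique integer id.

    ``age`` is time since creation; the cell becomes competent to divide
    once ``age >= g1 + g2`` (the envelope-size gate is checked separately).
    Perichondrial cells never count toward the envelope-size limit.
    """

    id: int
    position: np.ndarray
    clone_id: int
    kind: str = CHONDROCYTE
    age: float = 0.0
    g1: float = 3.0
    g2: float = 0.0
    proliferative: bool = True
    activated: bool = False
    counts_toward_envelope: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.g2 < 0:
            raise ValueError("g2 must be non-negative")
        if self.kind not in KIND_CODE:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.kind == PERICHONDRIAL and self.counts_toward_envelope:
            raise ValueError("perichondrial cells never count toward an envelope")


class Population:
    """A collection of cells with a clone registry and simulation clock.

    Storage is columnar (NumPy arrays, one row per cell, rows in ascending
    cell-id order) so the mechanics loop can operate on contiguous arrays;
    :class:`Cell` views are materialised on demand via :meth:`cell`.
    """

    def __init__(
        self,
        positions: np.ndarray,
        clone_ids: np.ndarray,
        kinds: np.ndarray,
        g1: np.ndarray,
        g2: np.ndarray,
        proliferative: np.ndarray,
        activated: np.ndarray,
        counts: np.ndarray,
        rng: np.random.Generator | None = None,
        time: float = 0.0,
    ) -> None:
        n = len(positions)
        self.pos = np.ascontiguousarray(positions, dtype=float).reshape(n, 3)
        self.ids = np.arange(n, dtype=np.int64)
        self.clone = np.asarray(clone_ids, dtype=np.int64).copy()
        self.kind = np.asarray(kinds, dtype=np.int8).copy()
        self.g1 = np.asarray(g1, dtype=float).copy()
        self.g2 = np.asarray(g2, dtype=float).copy()
        if np.any(self.g2 < 0):
            raise ValueError("g2 durations must be non-negative")
        self.proliferative = np.asarray(proliferative, dtype=bool).copy()
        self.activated = np.asarray(activated, dtype=bool).copy()
        self.counts = np.asarray(counts, dtype=bool).copy()
        if np.any(self.counts & (self.kind == KIND_CODE[PERICHONDRIAL])):
            raise ValueError("perichondrial cells never count toward an envelope")
        self.birth_time = np.zeros(n, dtype=float)
        self.time = float(time)
        self.step_index = 0
        self.rng = rng if rng is not None else np.random.default_rng()
        self._next_id = n
        self._next_clone = int(self.clone.max()) + 1 if n else 0
        self.inserted_clones: set[int] = set()
        self._clone_sizes: dict[int, int] = {}
        for cid in self.clone[self.counts]:
            cid = int(cid)
            self._clone_sizes[cid] = self._clone_sizes.get(cid, 0) + 1

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    @property
    def clone_sizes(self) -> dict[int, int]:
        """clone_id -> number of member cells that count toward the envelope."""
        return dict(self._clone_sizes)

    def recount_clones(self) -> dict[int, int]:
        """Recompute clone sizes from scratch (consistency oracle for tests)."""
        sizes: dict[int, int] = {}
        for cid in self.clone[self.counts]:
            cid = int(cid)
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes

    def new_clone_id(self) -> int:
        cid = self._next_clone
        self._next_clone += 1
        return cid

    def index_of(self, cell_id: int) -> int:
        idx = np.searchsorted(self.ids, cell_id)
        if idx >= len(self.ids) or self.ids[idx] != cell_id:
            raise KeyError(f"no cell with id {cell_id}")
        return int(idx)

    def __contains__(self, cell_id: int) -> bool:
        idx = np.searchsorted(self.ids, cell_id)
        return idx < len(self.ids) and self.ids[idx] == cell_id

    def cell(self, cell_id: int) -> Cell:
        """Materialise a read-only :class:`Cell` view of one row."""
        i = self.index_of(cell_id)
        return Cell(
            id=int(self.ids[i]),
            position=self.pos[i].copy(),
            clone_id=int(self.clone[i]),
            kind=KIND_NAME[int(self.kind[i])],
            age=self.time - float(self.birth_time[i]),
            g1=float(self.g1[i]),
            g2=float(self.g2[i]),
            proliferative=bool(self.proliferative[i]),
            activated=bool(self.activated[i]),
            counts_toward_envelope=bool(self.counts[i]),
        )

    def cells(self) -> Iterator[Cell]:
        for cid in self.ids:
            yield self.cell(int(cid))

    # -- mutation ------------------------------------------------------

    def replace_with_daughters(self, mother_id: int, d1: Cell, d2: Cell) -> tuple[int, int]:
        """Remove the mother and append the two daughters (fresh ids).

        The net effect of a division event is +1 cell. Daughters are born
        at the current population time with age zero.
        """
        i = self.index_of(mother_id)
        if self.counts[i]:
            c = int(self.clone[i])
            self._clone_sizes[c] -= 1
            if self._clone_sizes[c] == 0:
                del self._clone_sizes[c]
        keep = np.ones(self.n_cells, dtype=bool)
        keep[i] = False
        self._filter(keep)
        ids = []
        for d in (d1, d2):
            ids.append(self._append(d))
        return ids[0], ids[1]

    def _append(self, cell: Cell) -> int:
        cid = self._next_id
        self._next_id += 1
        self.pos = np.ascontiguousarray(np.vstack([self.pos, cell.position[None, :]]))
        self.ids = np.append(self.ids, cid)
        self.clone = np.append(self.clone, cell.clone_id)
        self.kind = np.append(self.kind, KIND_CODE[cell.kind])
        self.g1 = np.append(self.g1, cell.g1)
        self.g2 = np.append(self.g2, cell.g2)
        self.proliferative = np.append(self.proliferative, cell.proliferative)
        self.activated = np.append(self.activated, cell.activated)
        self.counts = np.append(self.counts, cell.counts_toward_envelope)
        self.birth_time = np.append(self.birth_time, self.time)
        self._next_clone = max(self._next_clone, cell.clone_id + 1)
        if cell.counts_toward_envelope:
            c = int(cell.clone_id)
            self._clone_sizes[c] = self._clone_sizes.get(c, 0) + 1
        return cid

    def _filter(self, keep: np.ndarray) -> None:
        self.pos = np.ascontiguousarray(self.pos[keep])
        self.ids = self.ids[keep]
        self.clone = self.clone[keep]
        self.kind = self.kind[keep]
        self.g1 = self.g1[keep]
        self.g2 = self.g2[keep]
        self.proliferative = self.proliferative[keep]
        self.activated = self.activated[keep]
        self.counts = self.counts[keep]
        self.birth_time = self.birth_time[keep]

    # -- export --------------------------------------------------------

    def to_frame(self):
        """Cell table as a pandas DataFrame (one row per cell)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.time,
                "cell_id": self.ids,
                "clone_id": self.clone,
                "kind": [KIND_NAME[int(k)] for k in self.kind],
                "activated": self.activated,
                "counts_toward_envelope": self.counts,
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "z": self.pos[:, 2],
            }
        )


# ---------------------------------------------------------------------------
# Force law
# ---------------------------------------------------------------------------


def force_magnitude(r, mu: float, s: float):
    """Signed magnitude of the pairwise force at separation ``r``.

    Returns ``-mu * (1 - r/s)**2`` for ``r <= s`` and 0 beyond the rest
    length. The value is always <= 0: applied along the unit vector from
    cell i toward cell j it pushes i away from j (pure repulsion). The
    force is continuous at ``r = s``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    out = np.where(r <= s, -mu * (1.0 - r / s) ** 2, 0.0)
    return out if out.ndim else float(out)

def pair_potential(r, mu: float, s: float):
    """Pair potential U(r) = (mu*s/3)(1 - r/s)^3 for r <= s, else 0.

    Satisfies dU/dr = force_magnitude(r); the total potential decreases
    monotonically under the overdamped dynamics and is the test oracle for
    the gradient structure of the force law.
    """
    r = np.asarray(r, dtype=float)
    out = np.where(r <= s, (mu * s / 3.0) * (1.0 - r / s) ** 3, 0.0)
    return out if out.ndim else float(out)


def pairwise_force(
    xi: np.ndarray,
    xj: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Force exerted on cell i (at ``xi``) by cell j (at ``xj``).

    Antisymmetric under swapping i and j. If the midpoints are closer than
    :data:`COINCIDENCE_THRESHOLD` the direction of the connecting line is
    undefined; a uniformly random unit direction with the contact magnitude
    ``force_magnitude(0) = -mu`` is substituted. Daughter cells are always
    created ``r0 > 0`` apart, so this branch is a numerical safeguard, not
    a modelled regime.
    """
    xi = np.asarray(xi, dtype=float).reshape(3)
    xj = np.asarray(xj, dtype=float).reshape(3)
    rij = xj - xi
    r = float(np.linalg.norm(rij))
    if r < COINCIDENCE_THRESHOLD:
        if rng is None:
            rng = np.random.default_rng()
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        return -params.mu * v
    return force_magnitude(r, params.mu, params.s) * (rij / r)


def net_force(
    cell_id: int,
    pop: Population,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sum of pairwise forces on one cell, in ascending cell-id order.

    Because the force has compact support, only neighbours within the rest
    length contribute; this is the sequential reference implementation the
    accelerated kernels are validated against.
    """
    i = pop.index_of(cell_id)
    xi = pop.pos[i]
    total = np.zeros(3)
    for j in range(pop.n_cells):
        if j == i:
            continue
        rij = pop.pos[j] - xi
        r = float(np.linalg.norm(rij))
        if r >= params.s and r >= COINCIDENCE_THRESHOLD:
            continue
        total += pairwise_force(xi, pop.pos[j], params, rng=rng if rng is not None else pop.rng)
    return total


def net_forces(
    pop: Population, params: ModelParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Net force on every cell (N, 3); pure-Python all-pairs reference."""
    n = pop.n_cells
    F = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            rij = pop.pos[j] - pop.pos[i]
            r = float(np.linalg.norm(rij))
            if r >= params.s:
                continue
            if r < COINCIDENCE_THRESHOLD:
                f = pairwise_force(pop.pos[i], pop.pos[j], params, rng=rng or pop.rng)
            else:
                f = force_magnitude(r, params.mu, params.s) * (rij / r)
            F[i] += f
            F[j] -= f
    return F


# ---------------------------------------------------------------------------
# Closed-form initial-contact bounds
# ---------------------------------------------------------------------------


def minimal_initial_pair_distance(c: float, s: float = 1.0, p_max: float = 0.1) -> float:
    """Worst-case closest initial pair distance on the perturbed lattice.

    Nearest lattice neighbours start ``c*s`` apart and each of the two cells
    may be displaced by up to ``p_max`` toward the other, so the distance is
    bounded below by ``c*s - 2*p_max``. At the defaults this gives 0.8 d for
    c = 1.0 and 0.9 d for c = 1.1.
    """
    return c * s - 2.0 * p_max


def worst_case_force_ratio(
    c_tight: float, c_loose: float, mu: float = 20.0, s: float = 1.0, p_max: float = 0.1
) -> float:
    """Ratio of worst-case initial force magnitudes between two lattice scalings.

    Evaluates the force law at the minimal achievable pair distances of the
    two configurations. For c = 1.0 vs c = 1.1 at the default parameters the
    ratio is exactly 4: the loosest packing cuts the maximal initial
    repulsion fourfold.
    """
    f_tight = abs(force_magnitude(minimal_initial_pair_distance(c_tight, s, p_max), mu, s))
    f_loose = abs(force_magnitude(minimal_initial_pair_distance(c_loose, s, p_max), mu, s))
    return f_tight / f_loose
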