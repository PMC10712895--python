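"""Initial configurations: mesenchymal condensation and pre-formed sheet.

Configuration (i) is a mesenchymal condensation: ``n_x * n_y * n_z`` cells
on a honeycomb (hexagonal-packing) lattice in the lateral x-y plane with
nearest-neighbour spacing ``c*s``, spread in z between the rigid boundary
planes. Every ancestor founds its own clonal envelope.

Configuration (ii) is a pre-existing columnar sheet: the same lateral
lattice, each site carrying a transversal column of chondrocytes capped by
one perichondrial cell below and one above, all between the rigid planes.
Sheet chondrocytes are post-mitotic; a chosen number of perichondrial cells
are "activated" and will each divide exactly once to seed a new clonal
envelope inside the sheet.

Both builders perturb every midpoint by an independent random displacement:
a uniformly random direction with magnitude drawn from Uniform[0, p_max].
The perturbation breaks the perfect lattice symmetry (whose exact force
cancellation would be a numerical artifact) and sets the worst-case initial
contact: two nearest neighbours can approach to c*s - 2*p_max, each cell
moving up to p_max toward the other, which is what makes the closed-form
initial-force bound (0.8 d minimal distance at c = 1.0, fourfold force
ratio between c = 1.0 and c = 1.1) attainable.

RNG draw order (fixed for reproducibility): z-coordinates (configuration (i)
with uniform z-mode only), then the perturbation block (directions, then
magnitudes), then (configuration (ii)) the activation choice, then one
exponential cycle draw per cell in id order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CHONDROCYTE, KIND_CODE, PERICHONDRIAL, ModelParams, Population

__all__ = [
    "CondensationSpec",
    "SheetSpec",
    "hex_lattice",
    "build_condensation",
    "build_sheet",
    "carve_subsheet_with_gap",
    "build_initial",
]

_Z_MODES = ("uniform", "at_lower_boundary", "at_midplane")


def _perturbation(rng: np.random.Generator, n: int, p_max: float) -> np.ndarray:
    """(n, 3) displacements: random direction, magnitude ~ Uniform[0, p_max]."""
    if p_max == 0.0:
        return np.zeros((n, 3))
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * rng.uniform(0.0, p_max, size=(n, 1))


@dataclass(frozen=True)
class CondensationSpec:
    """Configuration (i): mesenchymal condensation between the rigid planes."""

    params: ModelParams = field(default_factory=ModelParams)
    z_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_mode not in _Z_MODES:
            raise ValueError(f"z_mode must be one of {_Z_MODES}")


@dataclass(frozen=True)
class SheetSpec:
    """Configuration (ii): pre-formed columnar sheet with perichondrial caps.

    The sheet has ``n_chondro_layers + 2`` layers; the lowest and highest
    are perichondrial. Layers sit at ``l + k * layer_spacing``; the upper
    plane must leave room for the top layer.
    """

    params: ModelParams = field(default_factory=lambda: ModelParams(u=5.0, n_max=5))
    n_chondro_layers: int = 4
    n_activated: int = 9
    layer_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chondro_layers < 1:
            raise ValueError("need at least one chondrocyte layer")
        if self.layer_spacing <= 0:
            raise ValueError("layer_spacing must be positive")
        if self.n_activated < 0:
            raise ValueError("n_activated must be non-negative")
        top = self.params.l + (self.n_chondro_layers + 1) * self.layer_spacing
        if top > self.params.u + 1e-9:
            raise ValueError(
                f"upper boundary u={self.params.u} leaves no room for the top layer at z={top}"
            )


def hex_lattice(n_x: int, n_y: int, spacing: float) -> np.ndarray:
    """(n_x * n_y, 2) lateral lattice with nearest-neighbour distance ``spacing``.

    Rows are offset by half the spacing and separated by (sqrt(3)/2)*spacing
    (hexagonal packing); the lattice is centred at the origin. Row-major
    order: site (ix, iy) has index iy * n_x + ix.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("lattice counts must be >= 1")
    ix = np.arange(n_x)
    iy = np.arange(n_y)
    X = ix[None, :] * spacing + (iy[:, None] % 2) * (spacing / 2.0)
    Y = np.broadcast_to(iy[:, None] * (np.sqrt(3.0) / 2.0 * spacing), (n_y, n_x))
    pts = np.column_stack([X.ravel(), Y.ravel()]).astype(float)
    pts -= pts.mean(axis=0)
    return pts


def build_condensation(
    spec: CondensationSpec, rng: np.random.Generator | None = None
) -> Population:
    """Build configuration (i).

    Each of the ``n_x * n_y * n_z`` chondrocytes receives a unique clone id
    and is proliferative. z placement follows ``spec.z_mode``: uniform
    draws in (l, u), pinned at the lower plane, or pinned at the midplane.
    """
    p = spec.params
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lat = hex_lattice(p.n_x, p.n_y, p.c * p.s)
    n_site = len(lat)
    n = n_site * p.n_z
    pos = np.zeros((n, 3))
    pos[:, :2] = np.tile(lat, (p.n_z, 1))
    if spec.z_mode == "uniform":
        pos[:, 2] = rng.uniform(p.l, p.u, size=n)
    elif spec.z_mode == "at_lower_boundary":
        pos[:, 2] = p.l
    else:  # at_midplane
        pos[:, 2] = 0.5 * (p.u + p.l)
    pos += _perturbation(rng, n, p.p_max)
    g2 = rng.exponential(p.g2_mean, size=n)
    return Population(
        positions=pos,
        clone_ids=np.arange(n),
        kinds=np.full(n, KIND_CODE[CHONDROCYTE], dtype=np.int8),
        g1=np.full(n, p.g1),
        g2=g2,
        proliferative=np.ones(n, dtype=bool),
        activated=np.zeros(n, dtype=bool),
        counts=np.ones(n, dtype=bool),
        rng=rng,
    )


def _sheet_arrays(spec: SheetSpec):
    p = spec.params
    lat = hex_lattice(p.n_x, p.n_y, p.c * p.s)
    n_site = len(lat)
    n_layers = spec.n_chondro_layers + 2
    n = n_site * n_layers
    pos = np.zeros((n, 3))
    kinds = np.empty(n, dtype=np.int8)
    # id order: per lattice site, bottom layer to top layer
    for site in range(n_site):
        for layer in range(n_layers):
            i = site * n_layers + layer
            pos[i, :2] = lat[site]
            pos[i, 2] = p.l + layer * spec.layer_spacing
            is_peri = layer == 0 or layer == n_layers - 1
            kinds[i] = KIND_CODE[PERICHONDRIAL] if is_peri else KIND_CODE[CHONDROCYTE]
    return pos, kinds, n_site, n_layers


def build_sheet(spec: SheetSpec, rng: np.random.Generator | None = None) -> Population:
    """Build configuration (ii).

    Sheet chondrocytes are post-mitotic singletons (each with its own clone
    id); perichondrial caps never count toward any envelope. ``n_activated``
    perichondrial cells, drawn uniformly at random across both perichondrial
    layers, are flagged to divide once and seed new envelopes.
    """
    p = spec.params
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pos, kinds, n_site, n_layers = _sheet_arrays(spec)
    n = len(pos)
    pos += _perturbation(rng, n, p.p_max)
    peri_idx = np.flatnonzero(kinds == KIND_CODE[PERICHONDRIAL])
    if spec.n_activated > len(peri_idx):
        raise ValueError(
            f"n_activated={spec.n_activated} exceeds perichondrial count {len(peri_idx)}"
        )
    activated = np.zeros(n, dtype=bool)
    if spec.n_activated:
        chosen = rng.choice(peri_idx, size=spec.n_activated, replace=False)
        activated[chosen] = True
    g2 = rng.exponential(p.g2_mean, size=n)
    return Population(
        positions=pos,
        clone_ids=np.arange(n),
        kinds=kinds,
        g1=np.full(n, p.g1),
        g2=g2,
        proliferative=activated.copy(),
        activated=activated,
        counts=(kinds == KIND_CODE[CHONDROCYTE]),
        rng=rng,
    )


@dataclass(frozen=True)
class GapSheetSpec:
    """A 5x5-column sub-sheet with its central column deleted.

    The chondrocytes of the most central column are removed (its
    perichondrial caps remain), and exactly one perichondrial cell at the
    gap -- the bottom cap of the deleted column -- is activated to divide
    into the available space.
    """

    sheet: SheetSpec = field(
        default_factory=lambda: SheetSpec(
            params=ModelParams(n_x=5, n_y=5, u=5.0, n_max=5), n_activated=0
        )
    )

    def __post_init__(self) -> None:
        if self.sheet.params.n_x != 5 or self.sheet.params.n_y != 5:
            raise ValueError("the gap experiment uses a 5x5-column sub-sheet")


def carve_subsheet_with_gap(
    spec: SheetSpec | GapSheetSpec, rng: np.random.Generator | None = None
) -> Population:
    """Build the gap configuration: 5x5 columns, central column deleted."""
    sheet_spec = spec.sheet if isinstance(spec, GapSheetSpec) else spec
    p = sheet_spec.params
    if p.n_x != 5 or p.n_y != 5:
        raise ValueError("the gap experiment uses a 5x5-column sub-sheet")
    if rng is None:
        rng = np.random.default_rng(sheet_spec.seed)
    pos, kinds, n_site, n_layers = _sheet_arrays(sheet_spec)
    n = len(pos)
    pos += _perturbation(rng, n, p.p_max)
    central_site = (p.n_y // 2) * p.n_x + (p.n_x // 2)
    base = central_site * n_layers
    keep = np.ones(n, dtype=bool)
    keep[base + 1 : base + n_layers - 1] = False  # chondrocytes of the column
    activated = np.zeros(n, dtype=bool)
    activated[base] = True  # bottom perichondrial cap of the deleted column
    g2 = rng.exponential(p.g2_mean, size=n)
    return Population(
        positions=pos[keep],
        clone_ids=np.arange(n)[keep],
        kinds=kinds[keep],
        g1=np.full(keep.sum(), p.g1),
        g2=g2[keep],
        proliferative=activated[keep],
        activated=activated[keep],
        counts=(kinds[keep] == KIND_CODE[CHONDROCYTE]),
        rng=rng,
    )


def build_initial(spec, rng: np.random.Generator | None = None) -> Population:
    """Dispatch on the spec type (used by the engine)."""
    if isinstance(spec, CondensationSpec):
        return build_condensation(spec, rng)
    if isinstance(spec, GapSheetSpec):
        return carve_subsheet_with_gap(spec, rng)
    if isinstance(spec, SheetSpec):
        return build_sheet(spec, rng)
    raise TypeError(f"unknown initial-configuration spec {type(spec).__name__}")
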