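"""Cell-cycle timing, division-direction sampling, daughter placement, gating.

The cell cycle has two phases: a fixed first phase of duration ``g1`` and a
second phase whose duration is drawn, independently per cell at creation,
from an exponential distribution with mean ``g2_mean``. The exponential
phase desynchronises divisions (neighbours do not divide simultaneously,
preserving the quasistatic regime) while the fixed phase enforces a refractory
floor between successive divisions on one lineage.

At a division event the mother is removed and two daughters are placed at
``mother +- (r0/2) * direction`` so that the mother's midpoint lies exactly
between them. Division *orientation* is sampled according to a
:class:`DivisionRule`:

``vertical``
    deterministic (0, 0, 1): division transversal to the sheet.
``cone``
    a perturbed vertical direction: the polar angle satisfies
    cos(theta) ~ Uniform[cos(theta_max), 1] with uniform azimuth, which
    distributes endpoints uniformly on the spherical cap of half-angle
    theta_max.
``random_sphere``
    uniform on the unit sphere (the cone with theta_max = pi).
``lateral``
    a uniformly random azimuth in the x-y plane (used by perichondrial
    cells, which divide parallel to the sheet).

Proliferation is gated by the clonal-envelope size: a cell may divide only
while its envelope holds fewer than ``n_max(t)`` counting members, where the
limit may step up over time (:class:`NmaxSchedule`) to model sequential
proliferative phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CHONDROCYTE, PERICHONDRIAL, Cell, Population

__all__ = [
    "DivisionRule",
    "NmaxSchedule",
    "draw_cycle_durations",
    "sample_division_direction",
    "divide_cell",
    "divide_perichondrial",
    "can_divide",
]

_MODES = ("vertical", "cone", "random_sphere", "lateral")

#: tolerance on |age - (g1+g2)| when deciding division readiness
AGE_TOL = 1e-9


@dataclass(frozen=True)
class DivisionRule:
    """Division orientation mode, cone half-angle (radians) and daughter separation."""

    mode: str = "vertical"
    theta_max: float = 0.0
    r0: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not 0.0 <= self.theta_max <= np.pi:
            raise ValueError("theta_max must lie in [0, pi] radians")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


@dataclass(frozen=True)
class NmaxSchedule:
    """Piecewise-constant, right-continuous envelope-size limit n_max(t).

    ``breakpoints`` is an ordered sequence of (time, limit) pairs starting at
    t = 0; limits must be non-decreasing (envelopes never shrink).
    """

    breakpoints: tuple = ((0.0, 4),)

    def __post_init__(self) -> None:
        bps = tuple((float(t), int(m)) for t, m in self.breakpoints)
        object.__setattr__(self, "breakpoints", bps)
        if not bps or bps[0][0] != 0.0:
            raise ValueError("first breakpoint must be at t = 0")
        times = [t for t, _ in bps]
        limits = [m for _, m in bps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(m2 < m1 for m1, m2 in zip(limits, limits[1:])):
            raise ValueError("limits must be non-decreasing in time")
        if limits[0] < 1:
            raise ValueError("limits must be >= 1")

    @classmethod
    def constant(cls, n_max: int) -> "NmaxSchedule":
        return cls(((0.0, int(n_max)),))

    def limit_at(self, t: float) -> int:
        limit = self.breakpoints[0][1]
        for bt, bm in self.breakpoints:
            if t >= bt:
                limit = bm
            else:
                break
        return limit


def draw_cycle_durations(
    g1: float, g2_mean: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Return (g1, g2) for a newly created cell.

    The first phase is fixed; the second is an independent exponential draw
    with mean ``g2_mean``.
    """
    if g1 < 0:
        raise ValueError("g1 must be non-negative")
    if g2_mean <= 0:
        raise ValueError("g2_mean must be positive")
    return float(g1), float(rng.exponential(g2_mean))


def sample_division_direction(rule: DivisionRule, rng: np.random.Generator) -> np.ndarray:
    """Draw a unit division direction according to ``rule``."""
    if rule.mode == "vertical":
        return np.array([0.0, 0.0, 1.0])
    if rule.mode == "lateral":
        phi = rng.uniform(0.0, 2.0 * np.pi)
        return np.array([np.cos(phi), np.sin(phi), 0.0])
    theta_max = np.pi if rule.mode == "random_sphere" else rule.theta_max
    cos_theta = rng.uniform(np.cos(theta_max), 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    return np.array([sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta])


def _check_unit(direction: np.ndarray) -> np.ndarray:
    direction = np.asarray(direction, dtype=float).reshape(3)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("division direction must be a unit vector")
    return direction


def divide_cell(
    mother: Cell,
    direction: np.ndarray,
    r0: float,
    rng: np.random.Generator,
    g1: float | None = None,
    g2_mean: float = 10.0,
) -> tuple[Cell, Cell]:
    """Split a chondrocyte into two daughters along ``direction``.

    Daughters sit at ``mother.position +- (r0/2) * direction`` (separation
    exactly ``r0``, mother's midpoint in the middle), inherit the mother's
    clone, and each redraws its own cycle durations with age reset to zero.
    Ids are assigned by the population when the daughters are inserted.
    """
    direction = _check_unit(direction)
    if g1 is None:
        g1 = mother.g1
    half = 0.5 * r0 * direction
    daughters = []
    for sign in (+1.0, -1.0):
        g1_d, g2_d = draw_cycle_durations(g1, g2_mean, rng)
        daughters.append(
            Cell(
                id=-1,
                position=mother.position + sign * half,
                clone_id=mother.clone_id,
                kind=CHONDROCYTE,
                age=0.0,
                g1=g1_d,
                g2=g2_d,
                proliferative=True,
                activated=False,
                counts_toward_envelope=True,
            )
        )
    return daughters[0], daughters[1]


def divide_perichondrial(
    mother: Cell,
    rule: DivisionRule,
    rng: np.random.Generator,
    new_clone_id: int,
    g1: float | None = None,
    g2_mean: float = 10.0,
    direction: np.ndarray | None = None,
) -> tuple[Cell, Cell]:
    """Asymmetric division of an activated perichondrial cell.

    Produces one perichondrial daughter (keeps the mother's clone label,
    never divides again) and one chondrocyte daughter that founds a fresh
    clonal envelope (``new_clone_id``) and subsequently divides with the
    chondrocyte rule. The perichondrial ancestor and its perichondrial
    daughter never count toward the envelope limit.

    ``direction`` overrides the sampled direction (used for the
    interior-pointing seeding mode); by default a lateral azimuth is drawn
    from ``rule``. The chondrocyte daughter is placed on the +direction
    side.
    """
    if mother.kind != PERICHONDRIAL:
        raise ValueError("divide_perichondrial requires a perichondrial mother")
    if not mother.activated:
        raise ValueError("only activated perichondrial cells divide")
    if direction is None:
        direction = sample_division_direction(rule, rng)
    direction = _check_unit(direction)
    if g1 is None:
        g1 = mother.g1
    half = 0.5 * rule.r0 * direction
    g1_c, g2_c = draw_cycle_durations(g1, g2_mean, rng)
    chondro = Cell(
        id=-1,
        position=mother.position + half,
        clone_id=new_clone_id,
        kind=CHONDROCYTE,
        age=0.0,
        g1=g1_c,
        g2=g2_c,
        proliferative=True,
        activated=False,
        counts_toward_envelope=True,
    )
    g1_p, g2_p = draw_cycle_durations(g1, g2_mean, rng)
    peri = Cell(
        id=-1,
        position=mother.position - half,
        clone_id=mother.clone_id,
        kind=PERICHONDRIAL,
        age=0.0,
        g1=g1_p,
        g2=g2_p,
        proliferative=False,
        activated=False,
        counts_toward_envelope=False,
    )
    return peri, chondro


def can_divide(cell: Cell, pop: Population, schedule: NmaxSchedule, t: float) -> bool:
    """Division gate: proliferative, cycle complete, envelope below its limit.

    A clone of size ``n_max - 1`` may still divide (each event is net +1
    cell), so envelopes reach exactly the limit and then freeze. For a
    perichondrial cell the envelope gate is vacuous: its chondrocyte
    daughter founds a brand-new envelope.
    """
    if not cell.proliferative:
        return False
    if cell.age + AGE_TOL < cell.g1 + cell.g2:
        return False
    if cell.kind == PERICHONDRIAL:
        return True
    size = pop.clone_sizes.get(cell.clone_id, 0)
    return size < schedule.limit_at(t)
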