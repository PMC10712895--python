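"""The simulation loop: division events, forward-Euler mechanics, boundaries.

Each time step advances the population in the order

1. cell state: all ages advance by ``dt``; every cell whose cycle is
   complete and whose envelope gate is open divides (mothers processed in
   ascending cell-id order; a same-clone sibling due in the same step is
   re-gated after the first division);
2. mechanics: one synchronous forward-Euler update
   ``x_new = x_old + (dt/eta) * sum_j F_ij`` with forces evaluated at the
   pre-update positions;
3. boundaries: any midpoint with z outside [l, u] is projected back onto
   the violated plane (midpoints only; sphere surfaces may protrude).

Because division times are known at cell creation (``birth + g1 + g2``),
the loop runs event-driven: stretches with no division due, no envelope
limit change and no snapshot boundary are integrated in a single compiled
block. The trajectory this produces is identical to stepping one ``dt`` at
a time.

Randomness is consumed from one generator per scenario in a fixed order:
initial geometry first, then per division event the direction draw followed
by the two daughters' cycle draws, events in processing order. Identical
scenario + seed therefore reproduces the trajectory bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _kernels
from .core import (
    CHONDROCYTE,
    KIND_CODE,
    PERICHONDRIAL,
    ModelParams,
    Population,
    net_forces,
)
from .geometry import CondensationSpec, GapSheetSpec, SheetSpec, build_initial
from .proliferation import (
    AGE_TOL,
    DivisionRule,
    NmaxSchedule,
    divide_cell,
    divide_perichondrial,
    sample_division_direction,
)

__all__ = [
    "Scenario",
    "DivisionEvent",
    "Trajectory",
    "SimulationError",
    "step",
    "run",
    "quasistatic_diagnostic",
]

_PERI = KIND_CODE[PERICHONDRIAL]


class SimulationError(RuntimeError):
    """Raised when the integration produces non-finite positions."""


@dataclass(frozen=True)
class Scenario:
    """Everything needed to reproduce one simulation run."""

    params: ModelParams = field(default_factory=ModelParams)
    initial: Union[CondensationSpec, SheetSpec, GapSheetSpec] = field(
        default_factory=CondensationSpec
    )
    chondro_rule: DivisionRule = field(default_factory=DivisionRule)
    peri_rule: DivisionRule = field(default_factory=lambda: DivisionRule(mode="lateral"))
    #: "lateral" draws a random in-plane azimuth for the perichondrial
    #: seeding division; "transversal_interior" points it at the sheet
    #: interior (+z from the lower cap, -z from the upper cap).
    peri_placement: str = "lateral"
    schedule: Optional[NmaxSchedule] = None
    record_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peri_placement not in ("lateral", "transversal_interior"):
            raise ValueError("peri_placement must be 'lateral' or 'transversal_interior'")
        rec = self.record_interval / self.params.dt
        if self.record_interval <= 0 or abs(rec - round(rec)) > 1e-3 * max(rec, 1.0):
            raise ValueError("record_interval must be a positive multiple of dt")

    def effective_schedule(self) -> NmaxSchedule:
        return self.schedule if self.schedule is not None else NmaxSchedule.constant(
            self.params.n_max
        )


@dataclass
class DivisionEvent:
    time: float
    step: int
    mother_id: int
    mother_position: np.ndarray
    mother_kind: str
    clone_id: int
    daughter_ids: tuple[int, int]
    direction: np.ndarray


@dataclass
class Trajectory:
    """Timestamped snapshots plus per-step displacement and event logs."""

    times: list[float]
    snapshots: list[dict]
    max_step_displacement: np.ndarray
    events: list[DivisionEvent]
    params: ModelParams
    seed: int
    inserted_clones: set[int]
    final_population: Population

    def frame(self, i: int):
        """Snapshot ``i`` as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(self.snapshots[i])


def _snapshot(pop: Population, t: float) -> dict:
    return {
        "t": np.full(pop.n_cells, t),
        "cell_id": pop.ids.copy(),
        "clone_id": pop.clone.copy(),
        "kind": pop.kind.copy(),
        "activated": pop.activated.copy(),
        "counts": pop.counts.copy(),
        "x": pop.pos[:, 0].copy(),
        "y": pop.pos[:, 1].copy(),
        "z": pop.pos[:, 2].copy(),
    }


def _division_due(pop: Population, t: float) -> np.ndarray:
    """Row mask: proliferative cells whose cycle completed by time t."""
    return pop.proliferative & (pop.birth_time + pop.g1 + pop.g2 <= t + AGE_TOL)


def _gate_open(pop: Population, limit: int) -> np.ndarray:
    """Row mask: envelope gate open (vacuously true for perichondrial cells)."""
    sizes = pop._clone_sizes
    open_ = np.empty(pop.n_cells, dtype=bool)
    for i in range(pop.n_cells):
        if pop.kind[i] == _PERI:
            open_[i] = True
        else:
            open_[i] = sizes.get(int(pop.clone[i]), 0) < limit
    return open_


def _next_event_step(pop: Population, schedule: NmaxSchedule, j: int, dt: float, n_total: int) -> int:
    """First step index > j at which a division could fire or the limit changes."""
    t_now = j * dt
    limit = schedule.limit_at(t_now)
    mask = pop.proliferative & _gate_open(pop, limit)
    cand = n_total + 1
    if mask.any():
        t_div = float(np.min(pop.birth_time[mask] + pop.g1[mask] + pop.g2[mask]))
        cand = max(j + 1, int(math.ceil(t_div / dt - 1e-9)))
    for bt, _ in schedule.breakpoints:
        if bt > t_now + AGE_TOL:
            cand = min(cand, max(j + 1, int(math.ceil(bt / dt - 1e-9))))
            break
    return cand


def _process_divisions(pop: Population, scenario: Scenario, j: int, events: list) -> None:
    """Carry out every due, gated division at step ``j`` (ascending id order)."""
    p = scenario.params
    dt = p.dt
    t = j * dt
    schedule = scenario.effective_schedule()
    limit = schedule.limit_at(t)
    due_ids = [int(cid) for cid in pop.ids[_division_due(pop, t)]]
    for cid in due_ids:
        i = pop.index_of(cid)
        if not pop.proliferative[i]:
            continue
        kind = int(pop.kind[i])
        mother = pop.cell(cid)
        if kind == _PERI:
            if scenario.peri_placement == "transversal_interior":
                mid = 0.5 * (p.l + p.u)
                sign = 1.0 if mother.position[2] < mid else -1.0
                direction = np.array([0.0, 0.0, sign])
            else:
                direction = sample_division_direction(scenario.peri_rule, pop.rng)
            new_clone = pop.new_clone_id()
            d1, d2 = divide_perichondrial(
                mother,
                scenario.peri_rule,
                pop.rng,
                new_clone_id=new_clone,
                g1=p.g1,
                g2_mean=p.g2_mean,
                direction=direction,
            )
            pop.inserted_clones.add(new_clone)
            clone_of_event = new_clone
        else:
            # re-gate: an earlier division this step may have filled the clone
            if pop._clone_sizes.get(int(pop.clone[i]), 0) >= limit:
                continue
            direction = sample_division_direction(scenario.chondro_rule, pop.rng)
            d1, d2 = divide_cell(
                mother,
                direction,
                scenario.chondro_rule.r0,
                pop.rng,
                g1=p.g1,
                g2_mean=p.g2_mean,
            )
            clone_of_event = int(pop.clone[i])
        ids = pop.replace_with_daughters(cid, d1, d2)
        events.append(
            DivisionEvent(
                time=t,
                step=j,
                mother_id=cid,
                mother_position=mother.position.copy(),
                mother_kind=mother.kind,
                clone_id=clone_of_event,
                daughter_ids=ids,
                direction=np.asarray(direction, dtype=float),
            )
        )


def _mechanics_steps(
    pop: Population, p: ModelParams, n_steps: int, maxdisp: np.ndarray, offset: int
) -> None:
    """Advance ``n_steps`` mechanics-only steps, handling coincident pairs."""
    dt_eta = p.dt / p.eta
    done = 0
    while done < n_steps:
        k, status = _kernels.integrate_block(
            pop.pos, n_steps - done, dt_eta, p.mu, p.s, p.l, p.u, maxdisp, offset + done
        )
        done += k
        if status == _kernels.STATUS_COINCIDENT:
            # coincident midpoints: redo this one step in Python with the
            # randomised-direction policy, then resume the compiled path
            F = net_forces(pop, p, rng=pop.rng)
            delta = dt_eta * F
            pop.pos += delta
            np.clip(pop.pos[:, 2], p.l, p.u, out=pop.pos[:, 2])
            maxdisp[offset + done] = float(np.abs(delta).max()) if len(delta) else 0.0
            done += 1
        if not np.isfinite(pop.pos).all():
            bad = int(np.flatnonzero(~np.isfinite(pop.pos).all(axis=1))[0])
            raise SimulationError(
                f"non-finite position for cell id {int(pop.ids[bad])} "
                f"after step {pop.step_index + done} (t={pop.time:.4f})"
            )


def step(pop: Population, scenario: Scenario, events: list | None = None) -> Population:
    """Advance the population by one time step ``dt`` (in place).

    Division events first, then the synchronous Euler update with forces
    from the pre-update positions, then the z-projection onto the planes.
    """
    p = scenario.params
    if pop.time + p.dt > p.T + 1e-9:
        raise ValueError("stepping past the simulation end time T")
    j = pop.step_index + 1
    pop.time = j * p.dt
    _process_divisions(pop, scenario, j, events if events is not None else [])
    scratch = np.zeros(1)
    _mechanics_steps(pop, p, 1, scratch, 0)
    pop.step_index = j
    return pop


def run(scenario: Scenario) -> Trajectory:
    """Integrate a scenario from t = 0 to t = T.

    Snapshots are recorded at t = 0 and every ``record_interval`` thereafter
    (plus the final state). The run is seed-deterministic.
    """
    p = scenario.params
    rng = np.random.default_rng(scenario.seed)
    pop = build_initial(scenario.initial, rng)
    pop.rng = rng
    schedule = scenario.effective_schedule()

    n_total = int(round(p.T / p.dt))
    rec = max(1, int(round(scenario.record_interval / p.dt)))
    maxdisp = np.zeros(n_total)
    events: list[DivisionEvent] = []
    times = [0.0]
    snapshots = [_snapshot(pop, 0.0)]

    j = 0
    while j < n_total:
        j_evt = _next_event_step(pop, schedule, j, p.dt, n_total)
        j_snap = (j // rec + 1) * rec
        j_next = min(n_total, j_evt, j_snap)
        block = j_next - j - 1
        if block > 0:
            _mechanics_steps(pop, p, block, maxdisp, j)
        # step j_next: divisions (if due), one mechanics step, snapshot
        pop.time = j_next * p.dt
        if j_next == j_evt:
            _process_divisions(pop, scenario, j_next, events)
        _mechanics_steps(pop, p, 1, maxdisp, j_next - 1)
        pop.step_index = j = j_next
        if j % rec == 0 or j == n_total:
            times.append(j * p.dt)
            snapshots.append(_snapshot(pop, j * p.dt))

    return Trajectory(
        times=times,
        snapshots=snapshots,
        max_step_displacement=maxdisp,
        events=events,
        params=p,
        seed=scenario.seed,
        inserted_clones=set(pop.inserted_clones),
        final_population=pop,
    )


def quasistatic_diagnostic(traj: Trajectory, tol: float = 1e-3):
    """Check that the tissue relaxes mechanically between division events.

    For each division event, reports the maximum per-cell displacement in
    the step immediately preceding the event and flags events where it
    exceeds ``tol`` (meaning the tissue was still moving when the division
    fired). Events in the very first step have no preceding step and report
    NaN, unflagged.
    """
    import pandas as pd

    rows = []
    prev_time: dict[int, float] = {}
    last_event_time = -np.inf
    for ev in sorted(traj.events, key=lambda e: e.step):
        if ev.step >= 2:
            disp = float(traj.max_step_displacement[ev.step - 2])
            flagged = disp > tol
        else:
            disp, flagged = float("nan"), False
        rows.append(
            {
                "time": ev.time,
                "step": ev.step,
                "mother_id": ev.mother_id,
                "preceding_step_displacement": disp,
                "exceeds_tol": flagged,
                "time_since_previous_event": ev.time - last_event_time,
            }
        )
        last_event_time = ev.time
    return pd.DataFrame(
        rows,
        columns=[
            "time",
            "step",
            "mother_id",
            "preceding_step_displacement",
            "exceeds_tol",
            "time_since_previous_event",
        ],
    )
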