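"""Named, seeded reproductions of the in-silico experiments.

Each experiment is a set of *arms* (parameter settings) run over several
independent seeds (8 by default, matching the protocol of averaging over 8
random seeds) and scored with the envelope-projection-area metric. The
registered experiments:

================= ==========================================================
fig5_random       configuration (i), divisions uniform on the sphere
fig5_oriented     configuration (i), strictly vertical divisions
fig6_cone         cone-perturbed vertical divisions,
                  theta_max in {0, pi/128, pi/32, pi/8} radians
fig7_spacing      lateral lattice scaling c in {1.0, 1.075, 1.1}
fig8_boundary     initial z placement: uniform / at the lower plane /
                  at the midplane
fig9_thickness    envelope limit n_max in {4, 6, 8}, upper plane scaled as
                  u = (3.5/4) * n_max to keep the per-cell height ratio
fig10_sequential  stepwise limit 4 -> 6 at t_w = 50 vs constant 6
fig11_insertion   configuration (ii): 9 activated perichondrial cells seed
                  envelopes (n_max = 5) into a full sheet; compared against
                  5-cell columns grown directly from a condensation
fig12_gap         5x5-column sheet with the central column deleted; one
                  perichondrial cell at the gap seeds a column into the
                  space; same initial-growth comparison
================= ==========================================================

Seeds are derived deterministically from ``(base_seed, arm index, replicate
index)`` and recorded in the outputs, so every aggregate is reproducible
bit for bit from the stored per-seed series.
"""

from __future__ import annotations

import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .core import ModelParams
from .engine import Scenario, Trajectory, run
from .geometry import CondensationSpec, GapSheetSpec, SheetSpec
from .metrics import MetricSeries, metric_series
from .proliferation import DivisionRule, NmaxSchedule

__all__ = [
    "Arm",
    "ArmResult",
    "ExperimentResult",
    "EXPERIMENTS",
    "experiment_names",
    "derive_seed",
    "run_experiment",
    "summarize",
]

DEFAULT_N_SEEDS = 8
#: waiting time before the envelope limit steps from 4 to 6 cells
T_WAIT = 50.0
#: default upper-plane height per envelope cell (u = 3.5 at n_max = 4)
HEIGHT_PER_CELL = 3.5 / 4.0


def derive_seed(base_seed: int, arm_index: int, replicate: int) -> int:
    """Deterministic per-run seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(arm_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Scenario factories
# ---------------------------------------------------------------------------


def condensation_scenario(
    seed: int,
    mode: str = "vertical",
    theta_max: float = 0.0,
    z_mode: str = "uniform",
    schedule: Optional[NmaxSchedule] = None,
    params: Optional[ModelParams] = None,
    **param_overrides,
) -> Scenario:
    p = params if params is not None else ModelParams()
    if param_overrides:
        p = p.replace(**param_overrides)
    return Scenario(
        params=p,
        initial=CondensationSpec(params=p, z_mode=z_mode, seed=seed),
        chondro_rule=DivisionRule(mode=mode, theta_max=theta_max, r0=p.r0),
        schedule=schedule,
        seed=seed,
    )


def sheet_scenario(
    seed: int,
    n_activated: int = 9,
    peri_placement: str = "lateral",
    params: Optional[ModelParams] = None,
    **param_overrides,
) -> Scenario:
    p = params if params is not None else ModelParams(u=5.0, n_max=5)
    if param_overrides:
        p = p.replace(**param_overrides)
    return Scenario(
        params=p,
        initial=SheetSpec(params=p, n_activated=n_activated, seed=seed),
        chondro_rule=DivisionRule(mode="vertical", r0=p.r0),
        peri_rule=DivisionRule(mode="lateral", r0=p.r0),
        peri_placement=peri_placement,
        seed=seed,
    )


def gap_scenario(
    seed: int,
    peri_placement: str = "transversal_interior",
    params: Optional[ModelParams] = None,
    **param_overrides,
) -> Scenario:
    p = params if params is not None else ModelParams(n_x=5, n_y=5, u=5.0, n_max=5)
    if param_overrides:
        p = p.replace(**param_overrides)
    return Scenario(
        params=p,
        initial=GapSheetSpec(sheet=SheetSpec(params=p, n_activated=0, seed=seed)),
        chondro_rule=DivisionRule(mode="vertical", r0=p.r0),
        peri_rule=DivisionRule(mode="lateral", r0=p.r0),
        peri_placement=peri_placement,
        seed=seed,
    )


def initial_growth_scenario(seed: int, n_max: int = 5, **param_overrides) -> Scenario:
    """Columns of ``n_max`` cells grown directly from a condensation.

    The comparison curve for the insertion experiments: same seeds, envelope
    limit ``n_max`` and the upper plane scaled to keep the per-cell height.
    """
    return condensation_scenario(
        seed, mode="vertical", n_max=n_max, u=HEIGHT_PER_CELL * n_max, **param_overrides
    )


# ---------------------------------------------------------------------------
# Experiment registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Arm:
    label: str
    factory: Callable[..., Scenario]
    kwargs: dict = field(default_factory=dict)
    subset: str = "all"

    def scenario(self, seed: int, overrides: dict | None = None) -> Scenario:
        kwargs = dict(self.kwargs)
        if overrides:
            kwargs.update(overrides)
        return self.factory(seed, **kwargs)


def _theta_label(theta: float) -> str:
    if theta == 0.0:
        return "theta_0"
    frac = int(round(np.pi / theta))
    return f"theta_pi_{frac}"


EXPERIMENTS: dict[str, list[Arm]] = {
    "fig5_random": [Arm("random", condensation_scenario, {"mode": "random_sphere"})],
    "fig5_oriented": [Arm("oriented", condensation_scenario, {"mode": "vertical"})],
    "fig6_cone": [
        Arm(_theta_label(th), condensation_scenario, {"mode": "cone", "theta_max": th})
        for th in (0.0, np.pi / 128, np.pi / 32, np.pi / 8)
    ],
    "fig7_spacing": [
        Arm(f"c_{c}", condensation_scenario, {"c": c}) for c in (1.0, 1.075, 1.1)
    ],
    "fig8_boundary": [
        Arm(zm, condensation_scenario, {"z_mode": zm})
        for zm in ("uniform", "at_lower_boundary", "at_midplane")
    ],
    "fig9_thickness": [
        Arm(
            f"nmax_{m}",
            condensation_scenario,
            {"n_max": m, "u": HEIGHT_PER_CELL * m},
        )
        for m in (4, 6, 8)
    ],
    "fig10_sequential": [
        Arm(
            "sequential",
            condensation_scenario,
            {
                "n_max": 6,
                "u": HEIGHT_PER_CELL * 6,
                "schedule": NmaxSchedule(((0.0, 4), (T_WAIT, 6))),
            },
        ),
        Arm("continuous", condensation_scenario, {"n_max": 6, "u": HEIGHT_PER_CELL * 6}),
    ],
    "fig11_insertion": [
        Arm("insertion", sheet_scenario, {}, subset="inserted_only"),
        Arm("initial_growth", initial_growth_scenario, {}),
    ],
    "fig12_gap": [
        Arm("gap_insertion", gap_scenario, {}, subset="inserted_only"),
        Arm("initial_growth", initial_growth_scenario, {}),
    ],
}


def experiment_names() -> list[str]:
    return list(EXPERIMENTS)


# ---------------------------------------------------------------------------
# Running and aggregating
# ---------------------------------------------------------------------------


@dataclass
class ArmResult:
    label: str
    subset: str
    seeds: list[int]
    series: pd.DataFrame  # columns: time, seed<k>...
    aggregate: pd.DataFrame  # columns: time, mean, sd
    endpoint_mean: float
    endpoint_sd: float
    runtime_s: float
    per_seed: list[MetricSeries] = field(default_factory=list)
    trajectories: list[Trajectory] | None = None

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)


@dataclass
class ExperimentResult:
    name: str
    arms: list[ArmResult]

    def arm(self, label: str) -> ArmResult:
        for a in self.arms:
            if a.label == label:
                return a
        raise KeyError(f"no arm {label!r} in experiment {self.name!r}")

    def endpoint_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "experiment": self.name,
                    "arm": a.label,
                    "subset": a.subset,
                    "endpoint_mean": a.endpoint_mean,
                    "endpoint_sd": a.endpoint_sd,
                    "n_seeds": a.n_seeds,
                    "runtime_s": a.runtime_s,
                }
                for a in self.arms
            ]
        )


def _run_arm(
    name: str,
    arm_index: int,
    arm: Arm,
    n_seeds: int,
    base_seed: int,
    overrides: dict | None,
    keep_trajectories: bool,
) -> ArmResult:
    t0 = _time.perf_counter()
    seeds = [derive_seed(base_seed, arm_index, k) for k in range(n_seeds)]
    series_list: list[MetricSeries] = []
    trajs: list[Trajectory] = []
    for seed in seeds:
        traj = run(arm.scenario(seed, overrides))
        series_list.append(metric_series(traj, subset=arm.subset))
        if keep_trajectories:
            trajs.append(traj)
    times = series_list[0].times
    wide = pd.DataFrame({"time": times})
    for k, ms in enumerate(series_list):
        wide[f"seed{k}"] = ms.area_mean
    values = wide.drop(columns="time").to_numpy()
    with warnings.catch_warnings():
        # times before the first insertion event have no envelopes (all NaN)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        agg = pd.DataFrame(
            {
                "time": times,
                "mean": np.nanmean(values, axis=1) if n_seeds else np.nan,
                "sd": np.nanstd(values, axis=1, ddof=1) if n_seeds > 1 else 0.0,
            }
        )
    endpoints = values[-1, :]
    return ArmResult(
        label=arm.label,
        subset=arm.subset,
        seeds=seeds,
        series=wide,
        aggregate=agg,
        endpoint_mean=float(np.nanmean(endpoints)),
        endpoint_sd=float(np.nanstd(endpoints, ddof=1)) if n_seeds > 1 else 0.0,
        runtime_s=_time.perf_counter() - t0,
        per_seed=series_list,
        trajectories=trajs if keep_trajectories else None,
    )


def run_experiment(
    name: str,
    n_seeds: int = DEFAULT_N_SEEDS,
    base_seed: int = 0,
    overrides: dict | None = None,
    arms: list[str] | None = None,
    out_dir: str | Path | None = None,
    keep_trajectories: bool = False,
) -> ExperimentResult:
    """Run one named experiment over ``n_seeds`` independent seeds per arm.

    ``overrides`` are forwarded to every arm's scenario factory (model
    parameters such as ``T`` for shortened runs). ``arms`` optionally
    restricts to a subset of arm labels. With ``out_dir`` set, per-seed
    metric CSVs, per-arm aggregates and an endpoint summary are written
    under ``out_dir/<name>/``.
    """
    if name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {name!r}; valid names: {', '.join(EXPERIMENTS)}"
        )
    selected = EXPERIMENTS[name]
    if arms is not None:
        known = {a.label for a in selected}
        bad = set(arms) - known
        if bad:
            raise KeyError(f"unknown arm labels {sorted(bad)}; valid: {sorted(known)}")
        selected = [a for a in selected if a.label in arms]
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    results = [
        _run_arm(name, EXPERIMENTS[name].index(arm), arm, n_seeds, base_seed, overrides,
                 keep_trajectories)
        for arm in selected
    ]
    result = ExperimentResult(name=name, arms=results)
    if out_dir is not None:
        _write_experiment(result, Path(out_dir))
    return result


def _write_experiment(result: ExperimentResult, out_dir: Path) -> None:
    root = out_dir / result.name
    for arm in result.arms:
        arm_dir = root / arm.label
        for k, ms in enumerate(arm.per_seed):
            seed_dir = arm_dir / f"seed{k}"
            seed_dir.mkdir(parents=True, exist_ok=True)
            frame = ms.to_frame()
            frame.insert(1, "seed", arm.seeds[k])
            frame.to_csv(seed_dir / "metrics.csv", index=False)
        arm_dir.mkdir(parents=True, exist_ok=True)
        arm.aggregate.to_csv(arm_dir / "aggregate.csv", index=False)
    root.mkdir(parents=True, exist_ok=True)
    result.endpoint_summary().to_csv(root / "endpoint_summary.csv", index=False)


def summarize(results) -> pd.DataFrame:
    """One row per experiment arm: endpoint mean +- sd, seed count, runtime."""
    results = list(results)
    if not results:
        raise ValueError("no experiment results to summarize")
    return pd.concat(
        [r.endpoint_summary() for r in results], ignore_index=True
    )
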