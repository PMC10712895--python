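"""Order metric for clonal envelopes: the envelope projection area.

A clonal envelope is the set of all descendants of one ancestor cell of the
initial configuration. Its projection area is the product of its lateral
extents,

    a_E = (max_E x - min_E x) * (max_E y - min_E y),

computed on cell midpoints; the population-level metric ``a`` is the mean
over envelopes. A perfect transversal column has zero area; laterally
spreading, disordered clones have areas of order one cell diameter squared.
The metric ignores z entirely, so it measures column-ness, not column
length.

Only cells that count toward the envelope limit are members (perichondrial
ancestors and their perichondrial daughters are excluded, matching the
proliferation gate). The ``inserted_only`` subset restricts the average to
envelopes seeded by activated perichondrial cells, which is how insertion
experiments are scored against columns grown from a condensation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Population

__all__ = [
    "ClonalEnvelope",
    "MetricSeries",
    "envelope_projection_area",
    "projection_area",
    "mean_projection_area",
    "metric_series",
    "areas_from_table",
]

_SUBSETS = ("all", "inserted_only")


@dataclass(frozen=True)
class ClonalEnvelope:
    """One clonal envelope: clone label and the member midpoints (n, 3)."""

    clone_id: int
    member_positions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.member_positions, dtype=float))
        if arr.shape[0] == 0:
            raise ValueError("a clonal envelope cannot be empty")
        object.__setattr__(self, "member_positions", arr)


def projection_area(points: np.ndarray) -> float:
    """Lateral bounding-rectangle area of a point set (first two columns)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("empty point set")
    dx = pts[:, 0].max() - pts[:, 0].min()
    dy = pts[:, 1].max() - pts[:, 1].min()
    return float(dx * dy)


def envelope_projection_area(env: ClonalEnvelope) -> float:
    """Projection area of one envelope (d^2); zero for singletons and columns."""
    return projection_area(env.member_positions)


def _areas_by_clone(clone: np.ndarray, x: np.ndarray, y: np.ndarray):
    """(clone ids, areas) for each distinct clone among the given members."""
    if len(clone) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    order = np.argsort(clone, kind="stable")
    c, xs, ys = clone[order], x[order], y[order]
    starts = np.flatnonzero(np.r_[True, c[1:] != c[:-1]])
    xmax = np.maximum.reduceat(xs, starts)
    xmin = np.minimum.reduceat(xs, starts)
    ymax = np.maximum.reduceat(ys, starts)
    ymin = np.minimum.reduceat(ys, starts)
    return c[starts], (xmax - xmin) * (ymax - ymin)


def _member_arrays(source, subset: str, inserted: set[int] | None):
    if isinstance(source, Population):
        clone = source.clone[source.counts]
        x = source.pos[source.counts, 0]
        y = source.pos[source.counts, 1]
        if inserted is None:
            inserted = source.inserted_clones
    else:  # snapshot dict from a trajectory
        counts = source["counts"]
        clone = source["clone_id"][counts]
        x = source["x"][counts]
        y = source["y"][counts]
    if subset == "inserted_only":
        keep = np.isin(clone, np.fromiter(inserted or (), dtype=np.int64))
        clone, x, y = clone[keep], x[keep], y[keep]
    return clone, x, y


def mean_projection_area(
    pop: Population | dict,
    subset: str = "all",
    inserted: set[int] | None = None,
) -> float:
    """Mean envelope projection area over the chosen subset of envelopes."""
    if subset not in _SUBSETS:
        raise ValueError(f"subset must be one of {_SUBSETS}")
    clone, x, y = _member_arrays(pop, subset, inserted)
    _, areas = _areas_by_clone(clone, x, y)
    if len(areas) == 0:
        raise ValueError(f"no envelopes in subset {subset!r}")
    return float(areas.mean())


@dataclass
class MetricSeries:
    """Mean envelope projection area sampled at every recorded snapshot.

    Times with no envelope in the subset (e.g. before any insertion event)
    carry NaN. ``per_envelope`` holds the individual envelope areas per
    snapshot for across-envelope spread.
    """

    times: np.ndarray
    area_mean: np.ndarray
    n_envelopes: np.ndarray
    area_sd: np.ndarray
    subset_label: str
    per_envelope: list[np.ndarray]

    def endpoint(self) -> float:
        return float(self.area_mean[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "subset": self.subset_label,
                "n_envelopes": self.n_envelopes,
                "area_mean": self.area_mean,
                "area_sd_across_envelopes": self.area_sd,
            }
        )


def metric_series(traj, subset: str = "all") -> MetricSeries:
    """Evaluate the order metric at every snapshot of a trajectory."""
    if subset not in _SUBSETS:
        raise ValueError(f"subset must be one of {_SUBSETS}")
    if not traj.snapshots:
        raise ValueError("empty trajectory")
    inserted = traj.inserted_clones
    times = np.asarray(traj.times, dtype=float)
    means = np.empty(len(times))
    sds = np.empty(len(times))
    counts = np.empty(len(times), dtype=np.int64)
    per_env = []
    for k, snap in enumerate(traj.snapshots):
        clone, x, y = _member_arrays(snap, "all", None)
        if subset == "inserted_only":
            keep = np.isin(clone, np.fromiter(inserted or (), dtype=np.int64))
            clone, x, y = clone[keep], x[keep], y[keep]
        _, areas = _areas_by_clone(clone, x, y)
        per_env.append(areas)
        counts[k] = len(areas)
        if len(areas):
            means[k] = areas.mean()
            sds[k] = areas.std(ddof=1) if len(areas) > 1 else 0.0
        else:
            means[k] = np.nan
            sds[k] = np.nan
    return MetricSeries(
        times=times,
        area_mean=means,
        n_envelopes=counts,
        area_sd=sds,
        subset_label=subset,
        per_envelope=per_env,
    )


def areas_from_table(table: pd.DataFrame) -> pd.Series:
    """Projection areas per clone from an external point table.

    The table needs columns ``clone_id, x, y`` (``z`` is ignored), one row
    per cell, so externally measured cell centres grouped by clone can be
    scored with the same metric.
    """
    required = {"clone_id", "x", "y"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    clones, areas = _areas_by_clone(
        table["clone_id"].to_numpy(),
        table["x"].to_numpy(dtype=float),
        table["y"].to_numpy(dtype=float),
    )
    return pd.Series(areas, index=pd.Index(clones, name="clone_id"), name="projection_area")
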