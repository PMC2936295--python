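"""Time-course preprocessing.

Expression compendia mix experiments sampled on different time grids.
Directed-information estimation needs replicated series on one common,
equidistant grid, so this module selects the experiments that fit a
required grid (e.g. 0/30/60/90 min) and rescues experiments that miss
only the final point but measured a later one, by cubic-spline
interpolation of the missing value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentSeries",
    "TimeCourseDataset",
    "RawExpression",
    "EmptyDatasetError",
    "ExpressionFormatError",
    "select_equidistant",
    "spline_interpolate",
]


class EmptyDatasetError(ValueError):
    """No experiment satisfies the required time grid."""


class ExpressionFormatError(ValueError):
    """Malformed expression table or annotation."""


@dataclass(frozen=True)
class ExperimentSeries:
    """One experiment's expression matrix: genes x time points."""

    experiment_id: str
    values: np.ndarray  # shape (n_genes, n_times)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ExpressionFormatError(
                f"experiment {self.experiment_id!r}: values must be 2-D"
            )


@dataclass(frozen=True)
class TimeCourseDataset:
    """Replicated expression series sharing one equidistant time grid.

    Each experiment holds a genes x time matrix; all experiments share
    ``gene_ids`` (rows) and ``time_grid`` (columns, minutes, constant
    spacing).
    """

    gene_ids: tuple[str, ...]
    experiments: tuple[ExperimentSeries, ...]
    time_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "experiments", tuple(self.experiments))
        object.__setattr__(self, "time_grid", tuple(float(t) for t in self.time_grid))
        grid = np.asarray(self.time_grid)
        if grid.size < 2:
            raise ValueError("time grid needs at least 2 points")
        steps = np.diff(grid)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError(f"time grid {self.time_grid} is not equidistant")
        n_genes, n_times = len(self.gene_ids), grid.size
        for exp in self.experiments:
            if exp.values.shape != (n_genes, n_times):
                raise ExpressionFormatError(
                    f"experiment {exp.experiment_id!r}: shape {exp.values.shape} "
                    f"does not match ({n_genes}, {n_times})"
                )
            if not np.all(np.isfinite(exp.values)):
                raise ExpressionFormatError(
                    f"experiment {exp.experiment_id!r}: non-finite expression values"
                )

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_grid)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def gene_series(self, gene_id: str) -> np.ndarray:
        """Return an (n_experiments, n_timepoints) matrix for one gene."""
        i = self.gene_index(gene_id)
        return np.stack([exp.values[i] for exp in self.experiments])


@dataclass
class RawExpression:
    """Unfiltered expression table with per-array annotations.

    ``values``: genes x arrays DataFrame (index = gene ids, columns =
    array ids). ``annotation``: one row per array with columns
    ``array_id``, ``experiment_id``, ``time_min``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"array_id", "experiment_id", "time_min"}
        missing = required - set(self.annotation.columns)
        if missing:
            raise ExpressionFormatError(f"annotation missing columns: {sorted(missing)}")
        unknown = set(self.annotation["array_id"]) - set(self.values.columns)
        if unknown:
            raise ExpressionFormatError(
                f"annotation references unknown arrays: {sorted(unknown)[:5]}"
            )
        dupes = self.annotation.duplicated(subset=["experiment_id", "time_min"])
        if dupes.any():
            bad = self.annotation.loc[dupes, ["experiment_id", "time_min"]]
            raise ExpressionFormatError(
                f"duplicate (experiment, time) annotations: {bad.values.tolist()}"
            )


def spline_interpolate(times, values, target_time: float) -> float:
    """Interpolate a single value on a cubic not-a-knot spline.

    With fewer than 4 points a cubic spline is under-determined, so the
    function falls back to linear interpolation and warns.  Evaluation
    outside the observed time range is refused (extrapolating expression
    dynamics is not meaningful).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be 1-D and equally long")
    if np.unique(times).size != times.size:
        raise ValueError("duplicate time points")
    order = np.argsort(times)
    times, values = times[order], values[order]
    if not times[0] <= target_time <= times[-1]:
        raise ValueError(
            f"target time {target_time} outside observed range "
            f"[{times[0]}, {times[-1]}]: refusing to extrapolate"
        )
    if times.size < 4:
        warnings.warn(
            f"only {times.size} time points: falling back to linear interpolation",
            stacklevel=2,
        )
        return float(np.interp(target_time, times, values))
    spline = CubicSpline(times, values, bc_type="not-a-knot")
    return float(spline(target_time))


def select_equidistant(
    raw: RawExpression,
    required_times,
    interpolation_source: float | None = None,
) -> TimeCourseDataset:
    """Select experiments matching an equidistant time grid.

    An experiment is retained verbatim when it measured every required
    time.  When it misses exactly the final required time but measured
    ``interpolation_source`` (a later time) and has at least 4 points in
    total, the missing value is filled per gene by not-a-knot cubic
    spline through all of that experiment's time points.  All other
    experiments are dropped and logged.  Extra time points beyond the
    required grid are discarded after interpolation.
    """
    required = [float(t) for t in required_times]
    grid = np.asarray(required)
    if grid.size < 2 or not np.allclose(np.diff(grid), grid[1] - grid[0]):
        raise ValueError(f"required times {required} are not equidistant")

    gene_ids = tuple(raw.values.index)
    experiments: list[ExperimentSeries] = []
    for exp_id, group in raw.annotation.groupby("experiment_id", sort=True):
        times = group["time_min"].astype(float).to_numpy()
        arrays = group["array_id"].to_numpy()
        order = np.argsort(times)
        times, arrays = times[order], arrays[order]
        available = set(times)
        missing = [t for t in required if t not in available]
        mat = raw.values[list(arrays)].to_numpy(dtype=float)

        if not missing:
            cols = [list(times).index(t) for t in required]
            experiments.append(ExperimentSeries(str(exp_id), mat[:, cols]))
        elif (
            missing == [required[-1]]
            and interpolation_source is not None
            and float(interpolation_source) in available
            and times.size >= 4
        ):
            target = required[-1]
            spline = CubicSpline(times, mat, axis=1, bc_type="not-a-knot")
            filled = np.asarray(spline(target), dtype=float)
            cols = [list(times).index(t) for t in required[:-1]]
            values = np.column_stack([mat[:, cols], filled])
            logger.info(
                "experiment %s: interpolated t=%s from %s", exp_id, target, list(times)
            )
            experiments.append(ExperimentSeries(str(exp_id), values))
        else:
            logger.info(
                "experiment %s dropped: times %s incompatible with grid %s",
                exp_id,
                list(times),
                required,
            )

    if not experiments:
        raise EmptyDatasetError(
            f"no experiment satisfies the time grid {required} "
            f"(interpolation source: {interpolation_source})"
        )
    return TimeCourseDataset(gene_ids, tuple(experiments), tuple(required))
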