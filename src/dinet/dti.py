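"""Directed information between gene expression time courses.

For two processes X and Y observed over N equidistant time points in E
replicate experiments, directed information

    I(X^N -> Y^N) = sum_{n=2..N} I(X^n; Y_n | Y^{n-1})

quantifies the information flow from X into Y, conditioning on Y's own
past.  Algebraically each term equals I(X^n; Y^n) - I(X^n; 0Y^{n-1}),
where 0Y^{n-1} prepends a constant to Y's lagged segment — i.e. the
undirected dependence minus the dependence on Y shifted one step back.
Subtracting the shifted (Y-to-X-causal) association leaves the causal
X-to-Y dependency.

Because the grids are short (N = 4 in the motivating compendium), the
MI terms cannot be estimated per experiment.  The default "pooled" mode
therefore estimates each term from scalar pairs pooled across
experiments and time: the now-term at n pools (x_t, y_t) for t <= n,
the lag-term pools the shifted pairs (x_t, y_{t-1}) for 2 <= t <= n.
The alternative "vector" mode (histogram estimator only) treats each
experiment's segment as one vector-valued sample; in that mode the
plug-in estimate satisfies the conditional-MI identity above exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import (
    EstimatorConfig,
    bspline_bin_weights,
    estimate_mi,
    mi_from_weights,
    mi_histogram_plugin,
)
from .preprocessing import TimeCourseDataset

__all__ = ["ScoreMatrix", "dti_pair", "dti_matrix", "mi_matrix"]


@dataclass(frozen=True)
class ScoreMatrix:
    """Directed regulator x target association matrix (nats).

    Self-pairs are stored as NaN and excluded from all downstream null
    distributions.  ``kind`` records whether entries are directed
    information ("DTI") or plain mutual information ("MI"); only MI
    matrices are symmetric on shared ids.
    """

    regulator_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    scores: np.ndarray
    kind: str = "DTI"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulator_ids", tuple(self.regulator_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValueError(
                f"score shape {scores.shape} does not match id lists "
                f"({len(self.regulator_ids)}, {len(self.target_ids)})"
            )
        if self.kind not in ("DTI", "MI"):
            raise ValueError(f"kind must be 'DTI' or 'MI', got {self.kind!r}")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def _check_series(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"series shape mismatch: {x.shape} vs {y.shape}")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 time points for directed information")
    return x, y


def dti_pair(
    x,
    y,
    config: EstimatorConfig | None = None,
    *,
    include_zero_pad: bool = False,
    match_samples: bool = False,
    sample_mode: str = "pooled",
) -> float:
    """Directed information I(X -> Y) in nats from replicated series.

    ``x`` and ``y`` are (n_experiments, N) matrices on a shared
    equidistant grid.  Flags:

    * ``include_zero_pad`` — score the lag term on the literal 0Y^{n-1}
      concatenation, i.e. keep the (x_1, 0) padding pair instead of
      dropping it.
    * ``match_samples`` — restrict the now-term to t = 2..n so both
      terms use the same number of pooled pairs.
    * ``sample_mode`` — "pooled" (scalar pairs pooled over experiments
      and time) or "vector" (one vector-valued sample per experiment;
      histogram estimator only).

    The raw value is returned and may be negative under estimation
    noise; background correction is left to the CLR stage.
    """
    config = config or EstimatorConfig()
    x, y = _check_series(x, y)
    n_steps = x.shape[1]

    if sample_mode == "vector":
        if config.method != "histogram":
            raise ValueError("vector mode requires the histogram estimator")
        total = 0.0
        for n in range(2, n_steps + 1):
            xn = x[:, :n]
            yn = y[:, :n]
            y_prev = y[:, : n - 1]
            if include_zero_pad:
                y_prev = np.column_stack([np.zeros(y.shape[0]), y_prev])
            total += mi_histogram_plugin(xn, yn) - mi_histogram_plugin(xn, y_prev)
        return total
    if sample_mode != "pooled":
        raise ValueError(f"unknown sample_mode {sample_mode!r}")

    total = 0.0
    for n in range(2, n_steps + 1):
        t0 = 1 if match_samples else 0
        mi_now = estimate_mi(x[:, t0:n].ravel(), y[:, t0:n].ravel(), config)
        x_lag = x[:, 1:n].ravel()
        y_lag = y[:, : n - 1].ravel()
        if include_zero_pad:
            x_lag = np.concatenate([x[:, 0], x_lag])
            y_lag = np.concatenate([np.zeros(x.shape[0]), y_lag])
        mi_lag = estimate_mi(x_lag, y_lag, config)
        total += mi_now - mi_lag
    return total


def _id_indices(dataset: TimeCourseDataset, ids) -> list[int]:
    return [dataset.gene_index(g) for g in ids]


def _stacked(dataset: TimeCourseDataset) -> np.ndarray:
    # (n_genes, n_experiments, n_times)
    return np.stack([exp.values for exp in dataset.experiments], axis=1)


def dti_matrix(
    dataset: TimeCourseDataset,
    regulators,
    targets,
    config: EstimatorConfig | None = None,
    *,
    include_zero_pad: bool = False,
    match_samples: bool = False,
) -> ScoreMatrix:
    """Directed-information scores for every regulator -> target pair.

    Entry (i, j) equals ``dti_pair`` on regulator i's and target j's
    series; self-pairs are NaN.
    """
    config = config or EstimatorConfig()
    regulators = list(regulators)
    targets = list(targets)
    cube = _stacked(dataset)
    reg_idx = _id_indices(dataset, regulators)
    tgt_idx = _id_indices(dataset, targets)
    scores = np.full((len(regulators), len(targets)), np.nan)

    if config.method == "bspline" and not include_zero_pad:
        # B-spline bin weights depend only on (gene, time range), so they
        # are shared across all pairs; arithmetic is identical to the
        # dti_pair path (same weights feed mi_from_weights).
        n_steps = dataset.n_timepoints
        cache: dict[tuple[int, int, int], np.ndarray | None] = {}

        def weights(g: int, start: int, stop: int):
            key = (g, start, stop)
            if key not in cache:
                v = cube[g][:, start:stop].ravel()
                cache[key] = (
                    None
                    if v.max() == v.min()
                    else bspline_bin_weights(v, config.bins, config.spline_order)
                )
            return cache[key]

        def term(gx: int, gy: int, sx: int, sy: int, stop_x: int, stop_y: int) -> float:
            wx = weights(gx, sx, stop_x)
            wy = weights(gy, sy, stop_y)
            if wx is None or wy is None:
                return 0.0
            return mi_from_weights(wx, wy)

        for i, ri in enumerate(reg_idx):
            for j, tj in enumerate(tgt_idx):
                if ri == tj:
                    continue
                t0 = 1 if match_samples else 0
                total = 0.0
                for n in range(2, n_steps + 1):
                    total += term(ri, tj, t0, t0, n, n)
                    total -= term(ri, tj, 1, 0, n, n - 1)
                scores[i, j] = total
    else:
        for i, ri in enumerate(reg_idx):
            for j, tj in enumerate(tgt_idx):
                if ri == tj:
                    continue
                scores[i, j] = dti_pair(
                    cube[ri],
                    cube[tj],
                    config,
                    include_zero_pad=include_zero_pad,
                    match_samples=match_samples,
                )
    meta = {
        "estimator": config.method,
        "bins": config.bins,
        "spline_order": config.spline_order,
        "include_zero_pad": include_zero_pad,
        "match_samples": match_samples,
    }
    return ScoreMatrix(tuple(regulators), tuple(targets), scores, kind="DTI", meta=meta)


def mi_matrix(
    dataset: TimeCourseDataset,
    regulators,
    targets,
    config: EstimatorConfig | None = None,
) -> ScoreMatrix:
    """Plain MI scores from all pooled same-time pairs; symmetric."""
    config = config or EstimatorConfig()
    regulators = list(regulators)
    targets = list(targets)
    cube = _stacked(dataset)
    reg_idx = _id_indices(dataset, regulators)
    tgt_idx = _id_indices(dataset, targets)
    scores = np.full((len(regulators), len(targets)), np.nan)
    for i, ri in enumerate(reg_idx):
        for j, tj in enumerate(tgt_idx):
            if ri == tj:
                continue
            scores[i, j] = estimate_mi(cube[ri].ravel(), cube[tj].ravel(), config)
    meta = {"estimator": config.method, "bins": config.bins, "spline_order": config.spline_order}
    return ScoreMatrix(tuple(regulators), tuple(targets), scores, kind="MI", meta=meta)
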