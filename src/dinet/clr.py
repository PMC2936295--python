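"""Context likelihood of relatedness (CLR) background correction.

Raw association scores are not comparable across regulators and
targets: promiscuous genes show elevated scores against everything.
CLR assumes most pairs do not interact, so the empirical distribution
of a regulator's scores over all targets (its matrix row), and of a
target's scores over all regulators (its column), serve as null
distributions.  Each entry receives a row z-score and a column
z-score, negatives are clamped to zero, and the two are combined into
a cumulative z-score by their quadratic mean.  All z-scores are
computed within the TF x gene matrix only, never the full gene x gene
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dti import ScoreMatrix

__all__ = ["ZScoreMatrix", "clr_zscores", "combine_z"]


@dataclass(frozen=True)
class ZScoreMatrix:
    """Cumulative CLR z-scores; same shape and exclusions as the source."""

    regulator_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    z: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulator_ids", tuple(self.regulator_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValueError("z shape does not match id lists")
        valid = z[~np.isnan(z)]
        if valid.size and valid.min() < 0:
            raise ValueError("cumulative z-scores must be nonnegative")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.z)


def combine_z(z_row: float, z_col: float) -> float:
    """Cumulative z: quadratic mean of the two clamped component z-scores."""
    zr = max(float(z_row), 0.0)
    zc = max(float(z_col), 0.0)
    return float(np.sqrt((zr * zr + zc * zc) / 2.0))


def clr_zscores(scores: ScoreMatrix) -> ZScoreMatrix:
    """CLR cumulative z-scores for every valid entry of a score matrix.

    Row and column statistics use the sample standard deviation
    (ddof=1) over the valid (non-self, non-NaN) entries.  A row or
    column with fewer than two valid entries, or with zero spread,
    contributes a component z of 0 for all its entries.
    """
    s = scores.scores
    if s.size == 0:
        raise ValueError("empty score matrix")
    valid = ~np.isnan(s)
    if not valid.any():
        raise ValueError("score matrix has no valid entries")

    z = np.full(s.shape, np.nan)
    row_stats = [_null_stats(s[i, valid[i]]) for i in range(s.shape[0])]
    col_stats = [_null_stats(s[valid[:, j], j]) for j in range(s.shape[1])]
    for i in range(s.shape[0]):
        rm, rs = row_stats[i]
        for j in range(s.shape[1]):
            if not valid[i, j]:
                continue
            cm, cs = col_stats[j]
            z_row = (s[i, j] - rm) / rs if rs > 0 else 0.0
            z_col = (s[i, j] - cm) / cs if cs > 0 else 0.0
            z[i, j] = combine_z(z_row, z_col)
    provenance = {"kind": scores.kind, **scores.meta}
    return ZScoreMatrix(scores.regulator_ids, scores.target_ids, z, provenance)


def _null_stats(vals: np.ndarray) -> tuple[float, float]:
    if vals.size < 2:
        return 0.0, 0.0
    return float(vals.mean()), float(vals.std(ddof=1))
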