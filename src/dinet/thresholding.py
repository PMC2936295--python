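"""Edge selection and precision calibration against a reference network.

Edges can be selected at a fixed z threshold, as a fixed number of
top-ranked interactions, or — the calibrated mode — at the smallest
threshold whose edge set reaches a target precision.  Precision is the
fraction of inferred edges that are known, evaluated on the *reduced
graph*: because reference databases are incomplete, only edges whose
regulator has at least one known target and whose target has at least
one known regulator are informative, and all others are excluded from
the precision computation (the returned network still keeps them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clr import ZScoreMatrix

__all__ = [
    "ReferenceNetwork",
    "Interaction",
    "UndefinedPrecisionError",
    "UnreachablePrecisionError",
    "reduced_graph",
    "precision",
    "edges_at_threshold",
    "edges_top_k",
    "threshold_at_precision",
]


class UndefinedPrecisionError(ValueError):
    """Precision requested on an empty reduced graph."""


class UnreachablePrecisionError(ValueError):
    """No threshold achieves the requested precision."""


@dataclass(frozen=True)
class ReferenceNetwork:
    """Known regulator -> target interactions (a RegulonDB-style extract)."""

    known_edges: frozenset[tuple[str, str]]

    def __init__(self, known_edges) -> None:
        object.__setattr__(self, "known_edges", frozenset(tuple(e) for e in known_edges))

    @property
    def regulators_with_targets(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.known_edges)

    @property
    def targets_with_regulators(self) -> frozenset[str]:
        return frozenset(t for _, t in self.known_edges)

    def is_known(self, regulator: str, target: str) -> bool:
        return (regulator, target) in self.known_edges


@dataclass(frozen=True, order=True)
class Interaction:
    """One inferred edge with its ranking statistic and reference status."""

    regulator: str
    target: str
    z: float
    known: bool
    operon_derived: bool = False


def _annotate(regulator: str, target: str, z: float, reference: ReferenceNetwork) -> Interaction:
    return Interaction(regulator, target, float(z), reference.is_known(regulator, target))


def reduced_graph(edges, reference: ReferenceNetwork) -> list[Interaction]:
    """Edges whose TF has known targets and whose gene has known regulators."""
    regs = reference.regulators_with_targets
    tgts = reference.targets_with_regulators
    return [e for e in edges if e.regulator in regs and e.target in tgts]


def precision(edges, reference: ReferenceNetwork) -> float:
    """Fraction of known interactions among the reduced-graph edges."""
    reduced = reduced_graph(edges, reference)
    if not reduced:
        raise UndefinedPrecisionError(
            "precision undefined: no edge survives the reduced-graph restriction"
        )
    known = sum(1 for e in reduced if reference.is_known(e.regulator, e.target))
    return known / len(reduced)


def _valid_entries(zmat: ZScoreMatrix):
    rows, cols = np.nonzero(zmat.valid_mask)
    for i, j in zip(rows.tolist(), cols.tolist()):
        yield zmat.regulator_ids[i], zmat.target_ids[j], float(zmat.z[i, j])


def edges_at_threshold(
    zmat: ZScoreMatrix, tau: float, reference: ReferenceNetwork
) -> list[Interaction]:
    """All entries with z >= tau, annotated known/unknown."""
    return [
        _annotate(r, t, z, reference) for r, t, z in _valid_entries(zmat) if z >= tau
    ]


def edges_top_k(zmat: ZScoreMatrix, k: int, reference: ReferenceNetwork) -> list[Interaction]:
    """The k highest-z entries; boundary ties broken lexicographically.

    Ordering is deterministic: z descending, then (regulator, target)
    ascending.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    entries = sorted(_valid_entries(zmat), key=lambda e: (-e[2], e[0], e[1]))
    return [_annotate(r, t, z, reference) for r, t, z in entries[:k]]


def threshold_at_precision(
    zmat: ZScoreMatrix, reference: ReferenceNetwork, target_precision: float
) -> tuple[float, list[Interaction]]:
    """Smallest observed-z threshold reaching the target precision.

    Candidate thresholds are the observed z values (smallest first, so
    the returned network is the largest one meeting the target).  The
    returned edge set is the full set at that threshold; its
    reduced-graph precision is >= ``target_precision`` by construction.
    """
    if not 0.0 < target_precision <= 1.0:
        raise ValueError("target precision must be in (0, 1]")
    entries = sorted(_valid_entries(zmat), key=lambda e: e[2])
    if not entries:
        raise UnreachablePrecisionError("empty z-score matrix")
    regs = reference.regulators_with_targets
    tgts = reference.targets_with_regulators

    # sweep thresholds from largest down, accumulating reduced/known
    # counts, then pick the smallest qualifying threshold
    n_reduced = 0
    n_known = 0
    best_tau = None
    idx = len(entries) - 1
    for tau in sorted({z for _, _, z in entries}, reverse=True):
        while idx >= 0 and entries[idx][2] >= tau:
            r, t, _ = entries[idx]
            if r in regs and t in tgts:
                n_reduced += 1
                if reference.is_known(r, t):
                    n_known += 1
            idx -= 1
        if n_reduced > 0 and n_known / n_reduced >= target_precision:
            best_tau = tau
    if best_tau is None:
        raise UnreachablePrecisionError(
            f"no threshold reaches precision {target_precision:.3f}"
        )
    return best_tau, edges_at_threshold(zmat, best_tau, reference)
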