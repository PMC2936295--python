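"""Sequence-level validation of inferred regulatory edges.

An inferred TF -> gene edge gains independent support when the target's
promoter (a 400-bp window upstream of the start site, supplied already
oriented) contains a region resembling the TF's known binding sites,
and that region is phylogenetically conserved.  Known aligned sites are
summarised as a position weight matrix (PWM); the promoter is scanned
on both strands with the PWM's log-odds score; the best hit above a
score threshold is then intersected with conserved intervals, and the
edge is accepted only if conserved sequence covers strictly more than
50% of the hit.  Accepted edges whose target leads an operon can be
propagated to the downstream operon members, which share the promoter.

Coordinates throughout are window-local, 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .thresholding import Interaction

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "GenomicInterval",
    "ValidationRecord",
    "build_pwm",
    "pwm_information_content",
    "scan_sequence",
    "best_hit",
    "conservation_fraction",
    "validate_interaction",
    "operon_expand",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position base probabilities of a binding-site model.

    ``probs`` has shape (width, 4) over A, C, G, T; every row sums to
    1.  The aligned source sites are retained so that the default scan
    threshold (the weakest training site's own score) can be derived.
    """

    probs: np.ndarray
    pseudocount: float
    sites: tuple[str, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "sites", tuple(self.sites))
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if probs.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM occurrence on a promoter window."""

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid hit interval")


@dataclass(frozen=True)
class GenomicInterval:
    """Window-local conserved interval, 0-based half-open."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )


@dataclass(frozen=True)
class ValidationRecord:
    """Outcome of sequence-level validation for one edge."""

    edge: Interaction
    accepted: bool
    hit: MotifHit | None
    conservation: float
    reason: str  # "ok" | "no_site" | "not_conserved"


def build_pwm(sites, pseudocount: float = 0.5) -> PositionWeightMatrix:
    """Build a PWM from aligned, equal-length ACGT site sequences.

    Per-position probability of base b is
    (count_b + pseudocount) / (n_sites + 4 * pseudocount).
    """
    sites = [str(s).upper() for s in sites]
    if len(sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError(f"sites have unequal lengths: {sorted({len(s) for s in sites})}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    counts = np.zeros((width, 4))
    for s in sites:
        for pos, base in enumerate(s):
            if base not in _BASE_INDEX:
                raise ValueError(f"non-ACGT character {base!r} in site {s!r}")
            counts[pos, _BASE_INDEX[base]] += 1
    probs = (counts + pseudocount) / (len(sites) + 4.0 * pseudocount)
    return PositionWeightMatrix(probs, pseudocount, tuple(sites))


def pwm_information_content(pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b p_b log2 p_b."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)


def _log_odds(pwm: PositionWeightMatrix, background) -> np.ndarray:
    q = np.asarray(background, dtype=float)
    if q.shape != (4,) or not np.isclose(q.sum(), 1.0) or np.any(q <= 0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    return np.log(pwm.probs / q)


def _encode(seq: str, label: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=int)
    bad = []
    for i, base in enumerate(seq.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            bad.append(base)
        else:
            codes[i] = idx
    if bad:
        warnings.warn(
            f"{label}: {len(bad)} non-ACGT characters scored as background",
            stacklevel=3,
        )
    return codes


def score_site(pwm: PositionWeightMatrix, site: str, background=UNIFORM_BACKGROUND) -> float:
    """Log-odds score (nats) of one full-width sequence against the PWM."""
    if len(site) != pwm.width:
        raise ValueError("site length must equal PWM width")
    lo = _log_odds(pwm, background)
    codes = _encode(site, "site")
    return float(sum(lo[i, c] for i, c in enumerate(codes) if c >= 0))


def scan_sequence(
    pwm: PositionWeightMatrix,
    seq: str,
    sequence_id: str = "seq",
    background=UNIFORM_BACKGROUND,
) -> list[MotifHit]:
    """Score the PWM at every offset on both strands of a sequence.

    The minus strand scores the reverse complement of each window.
    Non-ACGT positions contribute zero log-odds (background-scored).
    Hits are returned sorted by score descending, ties by (start,
    strand with '+' before '-').
    """
    seq = str(seq).upper()
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence shorter ({len(seq)}) than PWM width ({w})")
    lo = _log_odds(pwm, background)
    codes = _encode(seq, sequence_id)
    n_offsets = len(seq) - w + 1

    hits: list[MotifHit] = []
    # minus strand: window reverse-complemented, i.e. position j of the
    # PWM reads the complement of the window base at w-1-j
    lo_rc = lo[::-1, ::-1]
    for strand, matrix in (("+", lo), ("-", lo_rc)):
        for start in range(n_offsets):
            window = codes[start : start + w]
            ok = window >= 0
            score = float(matrix[np.arange(w)[ok], window[ok]].sum())
            hits.append(MotifHit(sequence_id, start, start + w, strand, score))
    hits.sort(key=lambda h: (-h.score, h.start, 0 if h.strand == "+" else 1))
    return hits


def default_threshold(pwm: PositionWeightMatrix, background=UNIFORM_BACKGROUND) -> float:
    """Weakest training site's own log-odds score (so known sites pass)."""
    return min(score_site(pwm, s, background) for s in pwm.sites)


def best_hit(
    pwm: PositionWeightMatrix,
    seq: str,
    sequence_id: str = "seq",
    score_threshold: float | None = None,
    background=UNIFORM_BACKGROUND,
) -> MotifHit | None:
    """Highest-scoring hit if it reaches the threshold, else None."""
    if score_threshold is None:
        score_threshold = default_threshold(pwm, background)
    top = scan_sequence(pwm, seq, sequence_id, background)[0]
    return top if top.score >= score_threshold else None


def conservation_fraction(hit: MotifHit, conserved) -> float:
    """Fraction of the hit covered by the union of conserved intervals.

    Invariant to splitting a conserved interval into adjacent pieces.
    Intervals on other sequence ids are ignored.
    """
    spans = sorted(
        (iv.start, iv.end) for iv in conserved if iv.sequence_id == hit.sequence_id
    )
    covered = 0
    cursor = hit.start
    for start, end in spans:
        start = max(start, cursor, hit.start)
        end = min(end, hit.end)
        if end > start:
            covered += end - start
            cursor = end
    return covered / (hit.end - hit.start)


def validate_interaction(
    edge: Interaction,
    sites,
    promoter_seq: str,
    conserved,
    pseudocount: float = 0.5,
    score_threshold: float | None = None,
    background=UNIFORM_BACKGROUND,
) -> ValidationRecord:
    """Accept an edge iff a PWM hit exists and is >50% conserved (strict)."""
    pwm = sites if isinstance(sites, PositionWeightMatrix) else build_pwm(sites, pseudocount)
    hit = best_hit(pwm, promoter_seq, edge.target, score_threshold, background)
    if hit is None:
        return ValidationRecord(edge, False, None, 0.0, "no_site")
    frac = conservation_fraction(hit, conserved)
    if frac > 0.5:
        return ValidationRecord(edge, True, hit, frac, "ok")
    return ValidationRecord(edge, False, hit, frac, "not_conserved")


def operon_expand(accepted, operons, reference=None) -> list[Interaction]:
    """Propagate accepted edges across operons sharing the promoter.

    For an accepted edge (r, t) where t is the promoter-proximal
    (first) gene of an operon, edges (r, g) are added for every
    downstream member g, flagged ``operon_derived``.  Edges to genes in
    the middle of an operon are not expanded.  When a reference network
    is supplied, derived edges are annotated known/unknown against it;
    otherwise they are marked unknown.
    """
    downstream: dict[str, list[str]] = {}
    for operon in operons:
        genes = list(operon)
        if genes:
            downstream[genes[0]] = genes[1:]
    result = list(accepted)
    seen = {(e.regulator, e.target) for e in accepted}
    for edge in accepted:
        for gene in downstream.get(edge.target, []):
            if (edge.regulator, gene) in seen:
                continue
            seen.add((edge.regulator, gene))
            known = reference.is_known(edge.regulator, gene) if reference else False
            result.append(
                Interaction(edge.regulator, gene, edge.z, known, operon_derived=True)
            )
    return result
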