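"""Readers and writers for every on-disk dialect the pipeline uses.

All tabular formats are TSV; comment lines start with '#'.  Parsing is
strict: malformed rows raise :class:`FormatError` naming the file and
line.  Writing then reading reproduces in-memory values exactly for
TSV/BED and sequence-identically for FASTA.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clr import ZScoreMatrix
from .dti import ScoreMatrix
from .motifs import GenomicInterval
from .preprocessing import RawExpression, TimeCourseDataset
from .thresholding import Interaction, ReferenceNetwork

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_reference",
    "write_reference",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_operons",
    "write_operons",
    "read_edges",
    "write_edges",
    "write_decisions",
    "read_score_matrix",
    "write_score_matrix",
    "read_zscore_matrix",
    "write_zscore_matrix",
]


class FormatError(ValueError):
    """A file violated its expected dialect; message names file and line."""


def _fmt(v: float) -> str:
    return f"{v:.12g}"


# --- expression ---------------------------------------------------------


def read_expression(expr_path, annot_path) -> RawExpression:
    """Read a genes x arrays TSV plus its array annotation TSV."""
    expr_path, annot_path = Path(expr_path), Path(annot_path)
    values = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"{expr_path}: duplicate gene id {dup!r}")
    annotation = pd.read_csv(annot_path, sep="\t", comment="#")
    expected = ["array_id", "experiment_id", "time_min"]
    if list(annotation.columns) != expected:
        raise FormatError(
            f"{annot_path}: expected columns {expected}, got {list(annotation.columns)}"
        )
    if not np.issubdtype(annotation["time_min"].dtype, np.number):
        raise FormatError(f"{annot_path}: time_min must be numeric")
    try:
        return RawExpression(values, annotation)
    except ValueError as exc:
        raise FormatError(f"{expr_path}: {exc}") from exc


def write_expression(dataset: TimeCourseDataset, expr_path, annot_path) -> None:
    """Write a dataset as expression + annotation TSVs (round-trippable)."""
    columns, annot_rows = [], []
    data = {}
    for exp in dataset.experiments:
        for k, t in enumerate(dataset.time_grid):
            array_id = f"{exp.experiment_id}_t{int(t)}"
            columns.append(array_id)
            annot_rows.append((array_id, exp.experiment_id, t))
            data[array_id] = exp.values[:, k]
    frame = pd.DataFrame(data, index=list(dataset.gene_ids), columns=columns)
    frame.index.name = "gene_id"
    frame.to_csv(expr_path, sep="\t", float_format="%.12g")
    pd.DataFrame(annot_rows, columns=["array_id", "experiment_id", "time_min"]).to_csv(
        annot_path, sep="\t", index=False
    )


# --- reference network --------------------------------------------------


def read_reference(path) -> ReferenceNetwork:
    """Two-column regulator/target TSV (RegulonDB-style extract)."""
    path = Path(path)
    edges = set()
    for lineno, line in enumerate(_data_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{lineno}: expected 'regulator<TAB>target'")
        edges.add((parts[0], parts[1]))
    return ReferenceNetwork(frozenset(edges))


def write_reference(reference: ReferenceNetwork, path) -> None:
    with open(path, "w") as fh:
        for r, t in sorted(reference.known_edges):
            fh.write(f"{r}\t{t}\n")


# --- FASTA --------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered id -> sequence mapping; duplicate ids error."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --- BED ----------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """3-column BED with window-local, 0-based half-open coordinates."""
    path = Path(path)
    intervals = []
    for lineno, line in enumerate(_data_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not 0 <= start < end:
            raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        intervals.append(GenomicInterval(parts[0], start, end))
    return intervals


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.sequence_id}\t{iv.start}\t{iv.end}\n")


# --- operons ------------------------------------------------------------


def read_operons(path) -> list[list[str]]:
    """One operon per line: comma-separated ordered gene list."""
    path = Path(path)
    operons = []
    for lineno, line in enumerate(_data_lines(path), start=1):
        genes = [g.strip() for g in line.split(",")]
        if any(not g for g in genes):
            raise FormatError(f"{path}:{lineno}: empty gene id in operon")
        operons.append(genes)
    return operons


def write_operons(operons, path) -> None:
    with open(path, "w") as fh:
        for operon in operons:
            fh.write(",".join(operon) + "\n")


# --- edges & validation decisions ---------------------------------------

_EDGE_HEADER = "regulator\ttarget\tz\tknown"


def write_edges(edges, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(_EDGE_HEADER + "\n")
        for e in edges:
            fh.write(f"{e.regulator}\t{e.target}\t{_fmt(e.z)}\t{int(e.known)}\n")


def read_edges(path) -> list[Interaction]:
    path = Path(path)
    lines = list(_data_lines(path))
    if not lines or lines[0] != _EDGE_HEADER:
        raise FormatError(f"{path}: missing edge header {_EDGE_HEADER!r}")
    edges = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        try:
            edges.append(Interaction(parts[0], parts[1], float(parts[2]), bool(int(parts[3]))))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return edges


def write_decisions(records, path, header_comment: str | None = None) -> None:
    """Validation decisions TSV: one row per edge with hit details."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "regulator\ttarget\taccepted\thit_start\thit_end\tstrand\tscore"
            "\tconservation_fraction\treason\n"
        )
        for rec in records:
            hit = rec.hit
            fh.write(
                "\t".join(
                    [
                        rec.edge.regulator,
                        rec.edge.target,
                        str(int(rec.accepted)),
                        str(hit.start) if hit else ".",
                        str(hit.end) if hit else ".",
                        hit.strand if hit else ".",
                        _fmt(hit.score) if hit else ".",
                        _fmt(rec.conservation),
                        rec.reason,
                    ]
                )
                + "\n"
            )


# --- score / z-score matrices -------------------------------------------


def _write_matrix(path, regulator_ids, target_ids, values, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("regulator\t" + "\t".join(target_ids) + "\n")
        for rid, row in zip(regulator_ids, values):
            cells = ["nan" if np.isnan(v) else _fmt(v) for v in row]
            fh.write(rid + "\t" + "\t".join(cells) + "\n")


def _read_matrix(path) -> tuple[str, list[str], list[str], np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing matrix header comment")
    header = lines[0][1:].strip()
    cols = lines[1].split("\t")
    if cols[0] != "regulator":
        raise FormatError(f"{path}: first column must be 'regulator'")
    target_ids = cols[1:]
    regulator_ids, rows = [], []
    for lineno, line in enumerate(lines[2:], start=3):
        parts = line.split("\t")
        if len(parts) != len(target_ids) + 1:
            raise FormatError(f"{path}:{lineno}: wrong column count")
        regulator_ids.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return header, regulator_ids, target_ids, np.array(rows)


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    meta = " ".join(f"{k}={v}" for k, v in sorted(matrix.meta.items()))
    _write_matrix(
        path, matrix.regulator_ids, matrix.target_ids, matrix.scores,
        f"kind={matrix.kind} {meta}".strip(),
    )


def read_score_matrix(path) -> ScoreMatrix:
    header, regulator_ids, target_ids, values = _read_matrix(path)
    fields = dict(kv.split("=", 1) for kv in header.split() if "=" in kv)
    kind = fields.pop("kind", "DTI")
    return ScoreMatrix(tuple(regulator_ids), tuple(target_ids), values, kind, fields)


def write_zscore_matrix(zmat: ZScoreMatrix, path) -> None:
    meta = " ".join(f"{k}={v}" for k, v in sorted(zmat.provenance.items()))
    _write_matrix(
        path, zmat.regulator_ids, zmat.target_ids, zmat.z,
        f"zscore provenance: {meta}".strip(),
    )


def read_zscore_matrix(path) -> ZScoreMatrix:
    header, regulator_ids, target_ids, values = _read_matrix(path)
    return ZScoreMatrix(tuple(regulator_ids), tuple(target_ids), values, {"header": header})


def _data_lines(path: Path):
    if not os.path.exists(path):
        raise FormatError(f"{path}: file not found")
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith("#"):
                yield line
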