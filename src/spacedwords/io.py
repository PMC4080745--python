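"""FASTA, PHYLIP distance-matrix and pattern-file input/output."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .distances import DistanceMatrix
from .profiles import SequenceRecord, detect_alphabet

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_distance_matrix",
    "read_distance_matrix",
]


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Record ids are the first whitespace-delimited header tokens; residues
    are folded to upper case.  With ``alphabet=None`` the alphabet is
    auto-detected from the pooled residue content.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
    if alphabet is None:
        alphabet = detect_alphabet("".join(str(r.seq) for r in records))
    return [SequenceRecord(r.id, str(r.seq), alphabet) for r in records]


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _phylip_names(labels: Sequence[str], strict: bool) -> list[str]:
    """PHYLIP name fields: strict truncates to 10 characters, adding a
    numeric suffix where truncation collides; relaxed keeps full names."""
    if not strict:
        return [label.replace(" ", "_") for label in labels]
    names = []
    used: dict[str, int] = {}
    for label in labels:
        name = label.replace(" ", "_")[:10]
        if name in used:
            used[name] += 1
            suffix = str(used[name])
            name = name[: 10 - len(suffix)] + suffix
        used.setdefault(name, 0)
        names.append(name)
    return names


def write_distance_matrix(
    matrix: DistanceMatrix, path: str | Path, dialect: str = "phylip"
) -> None:
    """Write a distance matrix.

    Dialects: ``phylip`` (square format, names truncated to the standard
    10-character field), ``phylip-relaxed`` (full names, whitespace
    separated) and ``tsv`` (header row plus labeled rows).
    """
    labels, values = matrix.labels, matrix.values
    with open(path, "w") as fh:
        if dialect in ("phylip", "phylip-relaxed"):
            names = _phylip_names(labels, strict=dialect == "phylip")
            width = 10 if dialect == "phylip" else max(len(n) for n in names)
            fh.write(f"{len(labels)}\n")
            for name, row in zip(names, values):
                fh.write(name.ljust(width))
                fh.write("".join(f"  {v:.9f}" for v in row))
                fh.write("\n")
        elif dialect == "tsv":
            fh.write("\t" + "\t".join(labels) + "\n")
            for label, row in zip(labels, values):
                fh.write(label + "\t" + "\t".join(f"{v:.9f}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(path: str | Path, dialect: str = "phylip") -> DistanceMatrix:
    """Read a square distance matrix written by :func:`write_distance_matrix`."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if dialect == "tsv":
        labels = lines[0].lstrip("\t").split("\t")
        rows = [line.split("\t") for line in lines[1:]]
        values = np.array([[float(v) for v in row[1:]] for row in rows])
        return DistanceMatrix(tuple(r[0] for r in rows), values)
    n = int(lines[0].split()[0])
    labels, values = [], []
    for line in lines[1 : n + 1]:
        fields = line.split()
        labels.append(fields[0])
        values.append([float(v) for v in fields[1:]])
    return DistanceMatrix(tuple(labels), np.array(values))
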