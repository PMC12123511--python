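"""FASTA, GFF3/BED and CSV input/output.

Ambiguity policy: sequences are uppercased and split at every non-ACGT
IUPAC base (N, R, Y, ...) into independent scoring segments.  An
ambiguous base cannot be assigned an anti/syn conformation, so no
candidate may span one; segment offsets keep candidate coordinates on
the original sequence.  Characters outside the IUPAC nucleotide
alphabet (including U — this is a DNA tool) are rejected with the
offending position.
"""

from __future__ import annotations

import csv
import io as _io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .detect import CANDIDATE_COLUMNS, ZCandidate

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "write_candidates_csv",
]

IUPAC_AMBIGUOUS = set("NRYSWKMBDHV")
_ACGT_RUN = re.compile(r"[ACGT]+")


@dataclass
class SequenceRecord:
    """One FASTA record with its ACGT scoring segments.

    ``seq_id`` is the first whitespace-delimited token of the header;
    ``segments`` lists ``(offset, substring)`` pairs tiling the maximal
    ACGT runs of the uppercased sequence in order.
    """

    seq_id: str
    sequence: str
    segments: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = [(m.start(), m.group()) for m in _ACGT_RUN.finditer(self.sequence)]


def _validate_iupac(seq_id: str, sequence: str) -> None:
    for i, base in enumerate(sequence):
        if base not in "ACGT" and base not in IUPAC_AMBIGUOUS:
            raise ValueError(
                f"record {seq_id!r}: invalid character {base!r} at position {i} "
                "(IUPAC DNA alphabet expected)"
            )


def read_fasta(source: str | os.PathLike | _io.TextIOBase) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, path, or raw FASTA text."""
    if isinstance(source, _io.TextIOBase):
        handle = source
    elif isinstance(source, (str, os.PathLike)) and str(source).lstrip().startswith(">"):
        handle = _io.StringIO(str(source))
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"FASTA file not found: {path}")
        handle = path.open()
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper()
        _validate_iupac(rec.id, seq)
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(seq_id=rec.id, sequence=seq))
    if not records:
        raise ValueError("no FASTA records found in input")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n{rec.sequence}\n")


def read_intervals(
    path: str | os.PathLike, format: str, feature_type: str | None = None
) -> list[tuple[str, int, int, str, str]]:
    """Read BED or GFF3 intervals as unified 0-based half-open tuples.

    Returns ``(seq_id, start, end, strand, name)`` with strand in
    ``{+, -, .}``.  GFF coordinates (1-based inclusive) are converted to
    0-based half-open; BED is taken as-is.  For GFF, ``feature_type``
    (default ``gene``) restricts rows by column 3.
    """
    format = format.upper()
    if format not in ("BED", "GFF"):
        raise ValueError(f"format must be 'BED' or 'GFF', got {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interval file not found: {path}")
    out: list[tuple[str, int, int, str, str]] = []
    if format == "GFF":
        feature_type = feature_type or "gene"
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        for f in db.features_of_type(feature_type, order_by=("seqid", "start")):
            name = (f.attributes.get("Name") or f.attributes.get("ID") or ["."])[0]
            strand = f.strand if f.strand in ("+", "-", ".") else "."
            # gffutils keeps GFF 1-based inclusive coordinates
            out.append(_checked(path, f.id, f.seqid, f.start - 1, f.end, strand, name))
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            start, end = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            out.append(_checked(path, lineno, fields[0], start, end, strand, name))
    return out


def _checked(path, lineno, seq_id, start, end, strand, name):
    if end <= start:
        raise ValueError(f"{path}:{lineno}: empty interval after conversion ({start}, {end})")
    if strand not in ("+", "-", "."):
        raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
    return (seq_id, start, end, strand, name)


def write_candidates_csv(candidates: Sequence[ZCandidate], path: str | os.PathLike) -> None:
    """Write a candidate table (RFC-4180, UTF-8, '.' decimal separator)."""
    rows = [
        {
            "seq_id": c.seq_id,
            "start": c.start,
            "end": c.end,
            "length": c.length,
            "raw_score": c.raw_score,
            "display_score": c.display_score,
            "subsequence": c.subsequence,
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, encoding="utf-8", lineterminator="\n")
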