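"""Nearest-gene annotation with strand-aware TSS/TES distances.

Each candidate is assigned the gene minimizing the gap between interval
edges (0 when the intervals intersect; ties go to the smaller gene
start, i.e. the upstream gene).  Signed distances to the transcription
start and end sites are measured from the candidate midpoint in the
gene's reading direction: positive means the midpoint lies downstream
of the site.  On the '-' strand the TSS is the last base of the gene
interval and the axis is flipped.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detect import ZCandidate

__all__ = [
    "GeneRecord",
    "AnnotatedCandidate",
    "build_gene_index",
    "nearest_gene",
    "annotate_candidates",
    "annotated_to_frame",
]

NO_GENE = "."


@dataclass(frozen=True)
class GeneRecord:
    """One gene interval, 0-based half-open, strand mandatory."""

    seq_id: str
    start: int
    end: int
    strand: str
    gene_name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_name!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_name!r}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class AnnotatedCandidate:
    candidate: ZCandidate
    gene_name: str
    distance_to_gene: float  # 0 if overlapping, gap in bp otherwise
    distance_to_tss: float  # signed; + = midpoint downstream of TSS
    distance_to_tes: float


def build_gene_index(genes: Iterable[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Group genes by seq_id, sorted by (start, end)."""
    index: dict[str, list[GeneRecord]] = {}
    for g in genes:
        index.setdefault(g.seq_id, []).append(g)
    for seq_id in index:
        index[seq_id].sort(key=lambda g: (g.start, g.end))
    return index


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp between closest edges of two half-open intervals; 0 if they intersect."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def nearest_gene(
    candidate: ZCandidate, gene_index: Mapping[str, Sequence[GeneRecord]]
) -> AnnotatedCandidate:
    """Annotate one candidate against a sorted gene index.

    Binary search over sorted starts narrows the scan; since gene
    intervals on one sequence are typically short relative to their
    spacing, a bounded neighbourhood scan around the insertion point
    finds the minimal gap.  A missing chromosome yields the no-gene
    sentinel with NaN distances.
    """
    genes = gene_index.get(candidate.seq_id)
    if not genes:
        return AnnotatedCandidate(candidate, NO_GENE, float("nan"), float("nan"), float("nan"))
    starts = [g.start for g in genes]
    pivot = bisect_left(starts, candidate.start)
    best: GeneRecord | None = None
    best_gap = float("inf")
    # Scan right until gene starts can no longer beat the best gap, and
    # the whole left flank (ends are not sorted, so gaps to the left are
    # not monotone in start).
    for g in genes[pivot:]:
        if g.start - candidate.end > best_gap:
            break
        gap = _gap(candidate.start, candidate.end, g.start, g.end)
        if gap < best_gap or (gap == best_gap and best is not None and g.start < best.start):
            best, best_gap = g, gap
    for g in reversed(genes[:pivot]):
        gap = _gap(candidate.start, candidate.end, g.start, g.end)
        if gap < best_gap or (gap == best_gap and best is not None and g.start < best.start):
            best, best_gap = g, gap
    assert best is not None
    midpoint = (candidate.start + candidate.end) / 2
    sign = 1 if best.strand == "+" else -1
    return AnnotatedCandidate(
        candidate=candidate,
        gene_name=best.gene_name,
        distance_to_gene=float(best_gap),
        distance_to_tss=sign * (midpoint - best.tss),
        distance_to_tes=sign * (midpoint - best.tes),
    )


def annotate_candidates(
    candidates: Iterable[ZCandidate], genes: Iterable[GeneRecord]
) -> list[AnnotatedCandidate]:
    index = build_gene_index(genes)
    return [nearest_gene(c, index) for c in candidates]


def annotated_to_frame(annotated: Sequence[AnnotatedCandidate]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": a.candidate.seq_id,
            "start": a.candidate.start,
            "end": a.candidate.end,
            "length": a.candidate.length,
            "raw_score": a.candidate.raw_score,
            "display_score": a.candidate.display_score,
            "subsequence": a.candidate.subsequence,
            "gene_name": a.gene_name,
            "dist_gene": a.distance_to_gene,
            "dist_tss": a.distance_to_tss,
            "dist_tes": a.distance_to_tes,
        }
        for a in annotated
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "start",
            "end",
            "length",
            "raw_score",
            "display_score",
            "subsequence",
            "gene_name",
            "dist_gene",
            "dist_tss",
            "dist_tes",
        ],
    )
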