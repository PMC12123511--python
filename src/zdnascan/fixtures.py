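"""Synthetic FASTA/GFF/BED generators with known ground truth.

Everything downstream of the scorer is tested against data planted by
this module: random backgrounds verified motif-free by an exact
maximum-subarray check, Z-motifs inserted at known coordinates with
closed-form scores, and anchored interval sets whose expected
enrichment-profile peak position and height follow from the design.

Backgrounds default to a 60% A/T i.i.d. composition, which keeps the
chance of a spurious above-threshold subarray low; generation retries
with fresh draws and errors out if the background cannot be made clean.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SequenceRecord, write_fasta
from .scoring import ScoringParams, score_transitions, total_score

__all__ = ["PlantSpec", "make_scored_fasta", "make_anchored_intervals", "write_bed", "write_gff"]

DEFAULT_COMPOSITION = {"A": 0.3, "T": 0.3, "C": 0.2, "G": 0.2}

# Planted motifs are insulated by a run of INSULATOR_WIDTH identical
# bases chosen to form a mismatch step with the adjacent motif base.
# Six contiguous mismatches cost at least 3+6+...+18 = 63 under the
# default linear escalation, more than any sub-threshold background
# subarray (< 50) can pay back, so no candidate bridges the junction
# and detection recovers the planted interval exactly.
_INSULATOR = {"A": "A", "G": "A", "C": "C", "T": "C"}
INSULATOR_WIDTH = 6


@dataclass
class PlantSpec:
    """Recipe for one synthetic sequence with planted Z-motifs."""

    background_length: int
    planted_motifs: list[tuple[str, int]] = field(default_factory=list)  # (motif, position)
    background_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    seed: int = 0
    seq_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.background_composition.values()) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        for motif, pos in self.planted_motifs:
            if pos < INSULATOR_WIDTH or pos + len(motif) > self.background_length - INSULATOR_WIDTH:
                raise ValueError(
                    f"motif at {pos} (len {len(motif)}) must fit inside the "
                    f"background with {INSULATOR_WIDTH} insulating bases on each side"
                )


def _exact_max_subarray_sum(scores: np.ndarray) -> float:
    """Classic Kadane maximum over all contiguous non-empty windows."""
    if len(scores) == 0:
        return -math.inf
    best = -math.inf
    run = 0.0
    for x in scores:
        run = max(x, run + x)
        best = max(best, run)
    return best


def make_scored_fasta(
    spec: PlantSpec,
    params: ScoringParams | None = None,
    out_dir: str | os.PathLike | None = None,
    max_retries: int = 50,
) -> tuple[SequenceRecord, pd.DataFrame]:
    """Generate one sequence with planted motifs and its truth table.

    The raw background is redrawn until it contains no subarray
    reaching ``params.threshold`` (exact check).  Each planted motif is
    insulated by a mismatch run on each side whose cumulative penalty
    outweighs any sub-threshold background subarray, so the detected
    candidate coincides with the planted interval; the truth table
    lists per-motif coordinates and their transition-sum scores.
    """
    params = params or ScoringParams()
    rng = np.random.default_rng(spec.seed)
    bases = list(spec.background_composition)
    probs = [spec.background_composition[b] for b in bases]
    background = None
    for _ in range(max_retries):
        draw = "".join(rng.choice(bases, size=spec.background_length, p=probs))
        if _exact_max_subarray_sum(score_transitions(draw, params).scores) < params.threshold:
            background = draw
            break
    if background is None:
        raise RuntimeError(
            f"could not draw a motif-free background of length "
            f"{spec.background_length} in {max_retries} tries"
        )
    seq = list(background)
    rows = []
    occupied: list[tuple[int, int]] = []
    w = INSULATOR_WIDTH
    for motif, pos in spec.planted_motifs:
        motif = motif.upper()
        span = (pos - w, pos + len(motif) + w)  # motif plus insulators
        for s, e in occupied:
            if span[0] < e and s < span[1]:
                raise ValueError(f"planted motifs overlap near position {pos}")
        occupied.append(span)
        seq[pos : pos + len(motif)] = motif
        seq[pos - w : pos] = _INSULATOR[motif[0]] * w
        seq[pos + len(motif) : pos + len(motif) + w] = _INSULATOR[motif[-1]] * w
        rows.append(
            {
                "seq_id": spec.seq_id,
                "start": pos,
                "end": pos + len(motif),
                "motif": motif,
                "score": total_score(motif, params),
            }
        )
    record = SequenceRecord(seq_id=spec.seq_id, sequence="".join(seq))
    truth = pd.DataFrame(rows, columns=["seq_id", "start", "end", "motif", "score"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta([record], out_dir / f"{spec.seq_id}.fa")
        truth.to_csv(out_dir / f"{spec.seq_id}.truth.tsv", sep="\t", index=False)
    return record, truth


def make_anchored_intervals(
    n_anchors: int,
    offset: int,
    footprint: int,
    halfwidth: int,
    seed: int = 0,
    strands: str = "+",
) -> tuple[list[tuple], list[tuple], dict]:
    """Anchors with one motif planted at a fixed strand-aware offset.

    Returns ``(anchors, motifs, expected)`` where ``expected`` gives the
    designed profile peak position (= offset) and height
    ``(2*halfwidth + 1) / footprint`` (every anchor carries exactly one
    ``footprint``-bp motif, so the window mean is footprint / width per
    anchor).  ``strands`` is '+', '-' or 'mixed'.
    """
    if footprint <= 0 or n_anchors <= 0:
        raise ValueError("n_anchors and footprint must be positive")
    if abs(offset) + footprint > halfwidth:
        raise ValueError("|offset| + footprint must be <= halfwidth")
    rng = np.random.default_rng(seed)
    spacing = 2 * halfwidth + 100
    anchors: list[tuple] = []
    motifs: list[tuple] = []
    for i in range(n_anchors):
        pos = spacing * (i + 1)
        if strands == "mixed":
            strand = "+" if rng.integers(0, 2) == 0 else "-"
        else:
            strand = strands
        anchors.append(("chrS", pos, strand))
        if strand == "+":
            start = pos + offset
        else:
            # strand-aware: relative position r sits at genomic pos - r
            start = pos - offset - footprint + 1
        motifs.append(("chrS", start, start + footprint, "+", f"motif_{i}"))
    expected = {
        "peak_position": offset,
        "peak_height": (2 * halfwidth + 1) / footprint,
    }
    return anchors, motifs, expected


def write_bed(intervals, path: str | os.PathLike) -> None:
    """Write (seq_id, start, end[, strand, name]) tuples as 6-column BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            seq_id, start, end = iv[0], iv[1], iv[2]
            name = iv[4] if len(iv) > 4 else "."
            strand = iv[3] if len(iv) > 3 else "."
            fh.write(f"{seq_id}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def write_gff(genes, path: str | os.PathLike) -> None:
    """Write GeneRecord-like objects as a minimal GFF3 gene file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\tzdnascan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_name};Name={g.gene_name}\n"
            )
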