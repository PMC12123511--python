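"""Candidate extraction by maximum-scoring-subarray scanning.

A candidate Z-DNA interval is a contiguous window of the transition
score array whose sum is maximal within its scan window and reaches the
acceptance threshold.  The scan is a Kadane-style left-to-right pass
with an early-stopping rule: the current window is terminated once the
running sum falls more than ``drop_threshold`` below its running
maximum, the prefix achieving the running maximum is emitted, and
scanning resumes after it.  Small drop thresholds split interrupted
motifs into short candidates; large ones bridge penalized interruptions
into fewer, longer candidates — the point being that merging two Z
segments across a short imperfection saves two of the four costly B–Z
junctions that separate windows would require.

Coordinates are 0-based half-open nucleotide offsets: a candidate
``[start, end)`` covers transitions ``start .. end - 2``.
"""

from __future__ import annotations

import itertools
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    ScoringParams,
    TransitionScoreArray,
    display_score,
    score_transitions,
    total_score,
)

__all__ = [
    "ZCandidate",
    "find_candidates",
    "find_candidates_in_record",
    "best_subarray",
    "brute_force_best_subarray",
    "score_sequence_set",
    "sweep_parameters",
    "CANDIDATE_COLUMNS",
]

CANDIDATE_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "length",
    "raw_score",
    "display_score",
    "subsequence",
]


@dataclass(frozen=True)
class ZCandidate:
    """One detected potential Z-DNA-forming subsequence."""

    seq_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    raw_score: float
    display_score: int
    subsequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_windows(scores: np.ndarray, drop_threshold: float):
    """Yield (start_t, end_t, score) maximal windows in transition indices.

    Each yielded window is the best prefix (longest at equal score) of
    one scan window; the scan window ends when the running sum drops
    more than ``drop_threshold`` below its running maximum.
    """
    n = len(scores)
    i = 0
    while i < n:
        if scores[i] <= 0:
            i += 1
            continue
        start = i
        run = 0.0
        best = -math.inf
        best_end = start
        j = start
        resume = None
        while j < n:
            run += scores[j]
            if run >= best:  # >= keeps the longest prefix at equal score
                best = run
                best_end = j
            if run < 0:
                # Kadane reset: a window with a negative-sum prefix is
                # always beaten by its suffix, and no sub-window of the
                # skipped stretch can reach the emitted maximum.
                resume = j + 1
                break
            if best - run > drop_threshold:
                resume = best_end + 2
                break
            j += 1
        yield start, best_end, best
        # The transition right after the best prefix is provably
        # non-positive, so restarting past it loses no window.
        i = best_end + 2 if resume is None else max(resume, best_end + 2)


def find_candidates(
    array: TransitionScoreArray, params: ScoringParams | None = None
) -> list[ZCandidate]:
    """Extract non-overlapping candidates sorted by start.

    Emits each terminated scan window iff its best-prefix score reaches
    ``params.threshold``; negative-scoring flanks are never included.
    """
    params = params or ScoringParams()
    out: list[ZCandidate] = []
    for start_t, end_t, score in _scan_windows(array.scores, params.drop_threshold):
        if score >= params.threshold:
            start, end = start_t, end_t + 2  # nucleotide coordinates
            out.append(
                ZCandidate(
                    seq_id=array.seq_id,
                    start=start,
                    end=end,
                    raw_score=float(score),
                    display_score=int(display_score(score, "integer_floor")),
                    subsequence=array.sequence[start:end],
                )
            )
    return out


def best_subarray(
    array: TransitionScoreArray, params: ScoringParams | None = None
) -> tuple[int, int, float] | None:
    """Best-scoring window over all scan windows, ignoring the threshold.

    Returns ``(start, end, raw_score)`` in nucleotide coordinates, or
    ``None`` when no positive transition exists.  Ties are resolved
    longest then leftmost, matching :func:`find_candidates`.
    """
    params = params or ScoringParams()
    best: tuple[int, int, float] | None = None
    for start_t, end_t, score in _scan_windows(array.scores, params.drop_threshold):
        cand = (start_t, end_t + 2, float(score))
        if best is None:
            best = cand
            continue
        length, blength = cand[1] - cand[0], best[1] - best[0]
        if cand[2] > best[2] or (
            cand[2] == best[2] and (length > blength or (length == blength and cand[0] < best[0]))
        ):
            best = cand
    return best


def brute_force_best_subarray(
    array: TransitionScoreArray,
) -> tuple[int, int, float] | None:
    """Exhaustive maximum over all contiguous non-empty transition windows.

    Test oracle, O(n^2); guarded to arrays of at most 10,000 transitions.
    Ties resolved longest then leftmost, in nucleotide coordinates.
    """
    scores = array.scores
    n = len(scores)
    if n > 10_000:
        raise ValueError(f"oracle guard: array of {n} transitions exceeds 10,000")
    if n == 0:
        return None
    best = -math.inf
    best_s = best_len = -1
    for s in range(n):
        tot = 0.0
        for e in range(s, n):
            tot += scores[e]
            length = e - s + 1
            if tot > best or (
                tot == best and (length > best_len or (length == best_len and s < best_s))
            ):
                best, best_s, best_len = tot, s, length
    return best_s, best_s + best_len + 1, float(best)


def find_candidates_in_record(record, params: ScoringParams | None = None) -> list[ZCandidate]:
    """Run candidate detection over the ACGT segments of a SequenceRecord.

    Ambiguous bases split the sequence into independently scored
    segments (no candidate may span an ambiguous base); coordinates are
    reported on the original sequence.
    """
    params = params or ScoringParams()
    out: list[ZCandidate] = []
    for offset, segment in record.segments:
        arr = score_transitions(segment, params, seq_id=record.seq_id)
        for c in find_candidates(arr, params):
            out.append(
                ZCandidate(
                    seq_id=c.seq_id,
                    start=c.start + offset,
                    end=c.end + offset,
                    raw_score=c.raw_score,
                    display_score=c.display_score,
                    subsequence=c.subsequence,
                )
            )
    return out


def _score_one(args) -> list[dict]:
    seq_id, sequence, params = args
    if params.total_sequence_scoring:
        return [{"seq_id": seq_id, "total_score": total_score(sequence, params)}]
    arr = score_transitions(sequence, params, seq_id=seq_id)
    return [
        {
            "seq_id": c.seq_id,
            "start": c.start,
            "end": c.end,
            "length": c.length,
            "raw_score": c.raw_score,
            "display_score": c.display_score,
            "subsequence": c.subsequence,
        }
        for c in find_candidates(arr, params)
    ]


def score_sequence_set(
    records: Iterable[tuple[str, str]],
    params: ScoringParams | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Score a set of (seq_id, sequence) records.

    In total-scoring mode returns one row per record with its total
    score; otherwise the concatenated candidate tables.  Output order is
    input order then candidate start, identical for any worker count.
    """
    params = params or ScoringParams()
    records = list(records)
    ids = [r[0] for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate seq_ids: {', '.join(dupes)}")
    jobs = [(seq_id, seq, params) for seq_id, seq in records]
    if n_workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            per_record = list(pool.map(_score_one, jobs, chunksize=max(1, len(jobs) // n_workers)))
    else:
        per_record = [_score_one(j) for j in jobs]
    rows = [row for rec_rows in per_record for row in rec_rows]
    if params.total_sequence_scoring:
        return pd.DataFrame(rows, columns=["seq_id", "total_score"])
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def sweep_parameters(
    labeled: Sequence[tuple[str, str]],
    grid: Mapping[str, Sequence[float]],
    base_params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Grid sweep of scoring weights against labeled control sequences.

    ``labeled`` pairs each sequence with its expected label, ``forming``
    or ``nonforming``.  ``grid`` maps ScoringParams field names (e.g.
    ``gc_weight``, ``gt_weight``, ``ac_weight``) to value lists; the
    full cross-product is evaluated.  A sequence is classified forming
    when its best-subarray raw score reaches the threshold.  Returns one
    row per combination with correct-classification counts.
    """
    if not labeled:
        raise ValueError("labeled sequence set must be non-empty")
    for seq, label in labeled:
        if label not in ("forming", "nonforming"):
            raise ValueError(f"label must be 'forming' or 'nonforming', got {label!r}")
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = sorted(grid)
    for k in keys:
        if len(grid[k]) == 0:
            raise ValueError(f"empty grid axis {k!r}")
    base = base_params or ScoringParams()
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = ScoringParams(**{**base.__dict__, **dict(zip(keys, combo))})
        n_forming = n_nonforming = ok_forming = ok_nonforming = 0
        for seq, label in labeled:
            best = best_subarray(score_transitions(seq, params), params)
            forming = best is not None and best[2] >= params.threshold
            if label == "forming":
                n_forming += 1
                ok_forming += forming
            else:
                n_nonforming += 1
                ok_nonforming += not forming
        rows.append(
            {
                **dict(zip(keys, combo)),
                "forming_correct": ok_forming,
                "forming_total": n_forming,
                "nonforming_correct": ok_nonforming,
                "nonforming_total": n_nonforming,
                "accuracy": (ok_forming + ok_nonforming) / len(labeled),
            }
        )
    return pd.DataFrame(rows)
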