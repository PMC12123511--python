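"""Dinucleotide-transition scoring for Z-DNA propensity.

Z-DNA is a left-handed duplex conformation favored by alternating
purine–pyrimidine tracts.  The score of a sequence is the sum of
per-transition contributions over every adjacent base pair:

* alternating steps carry flat positive weights (GC/CG the strongest,
  GT/TG and AC/CA intermediate, AT/TA weakest);
* AT/TA steps additionally take a position-dependent adjustment within a
  contiguous AT-run, because long AT tracts form hairpins/cruciforms
  rather than Z-DNA;
* every non-alternating step ("mismatch": purine–purine,
  pyrimidine–pyrimidine, or a same-base step) is penalized, with the
  penalty escalating along a contiguous mismatch run and resetting after
  any non-mismatch step.

Defaults are calibrated so that the shortest experimentally supported
Z-forming repeats sit at the detection threshold: a GC repeat of 4 units
(7 GC steps, score 49) falls just below the threshold of 50 while 5 units
(score 63) clear it, and a GT repeat of 25 units (49 GT steps, 61.25)
clears it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "TransitionClass",
    "ScoringParams",
    "TransitionScoreArray",
    "classify_transition",
    "score_transitions",
    "total_score",
    "display_score",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_CONSECUTIVE_AT = (0.5, 0.5, 0.5, 0.0, 0.0, -5.0, -100.0)


class TransitionClass(Enum):
    """Partition of the 16 ordered dinucleotides into scoring classes."""

    GC = "GC"
    GT = "GT"
    AC = "AC"
    AT = "AT"
    MISMATCH = "MISMATCH"


_PAIR_CLASS = {
    "GC": TransitionClass.GC,
    "CG": TransitionClass.GC,
    "GT": TransitionClass.GT,
    "TG": TransitionClass.GT,
    "AC": TransitionClass.AC,
    "CA": TransitionClass.AC,
    "AT": TransitionClass.AT,
    "TA": TransitionClass.AT,
}


@dataclass(frozen=True)
class ScoringParams:
    """Tunable parameters of the transition-scoring model.

    All weights are in score units per transition.  ``threshold`` is the
    acceptance cutoff for candidates (compared with ``>=``);
    ``drop_threshold`` is the depth below the running maximum at which
    subarray scanning terminates the current candidate window.
    """

    threshold: float = 50.0
    gc_weight: float = 7.0
    gt_weight: float = 1.25
    ac_weight: float = 1.25
    at_weight: float = 0.5
    consecutive_at_adjustments: tuple[float, ...] = DEFAULT_CONSECUTIVE_AT
    mismatch_start: float = 3.0
    mismatch_type: str = "linear"  # "linear" | "exponential"
    mismatch_delta: float = 3.0
    drop_threshold: float = 50.0
    total_sequence_scoring: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "consecutive_at_adjustments",
            tuple(float(x) for x in self.consecutive_at_adjustments),
        )
        for name in (
            "threshold",
            "gc_weight",
            "gt_weight",
            "ac_weight",
            "at_weight",
            "mismatch_start",
            "mismatch_delta",
            "drop_threshold",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.drop_threshold <= 0:
            raise ValueError("drop_threshold must be > 0")
        if self.mismatch_start < 0:
            raise ValueError("mismatch_start must be >= 0")
        if self.mismatch_delta < 0:
            raise ValueError("mismatch_delta must be >= 0")
        if not self.consecutive_at_adjustments:
            raise ValueError("consecutive_at_adjustments must be non-empty")
        if any(not math.isfinite(x) for x in self.consecutive_at_adjustments):
            raise ValueError("consecutive_at_adjustments must be finite")
        if self.mismatch_type not in ("linear", "exponential"):
            raise ValueError(
                f"mismatch_type must be 'linear' or 'exponential', got {self.mismatch_type!r}"
            )

    def weight_of(self, cls: TransitionClass) -> float:
        return {
            TransitionClass.GC: self.gc_weight,
            TransitionClass.GT: self.gt_weight,
            TransitionClass.AC: self.ac_weight,
            TransitionClass.AT: self.at_weight,
        }[cls]


@dataclass
class TransitionScoreArray:
    """Per-transition scores for one sequence.

    ``scores[i]`` and ``classes[i]`` describe the step between
    nucleotides ``i`` and ``i + 1``; both have length ``max(0, n - 1)``.
    The source sequence is retained so candidate extraction can report
    subsequences.
    """

    seq_id: str
    sequence: str
    scores: np.ndarray
    classes: list[TransitionClass] = field(repr=False)

    def __len__(self) -> int:
        return len(self.scores)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def classify_transition(pair: str) -> TransitionClass:
    """Classify one ordered dinucleotide.

    GC/CG, GT/TG, AC/CA and AT/TA are the alternating
    purine–pyrimidine classes; every other ordered pair over ACGT is a
    mismatch.
    """
    if len(pair) != 2:
        raise ValueError(f"expected a dinucleotide, got {pair!r}")
    for i, base in enumerate(pair):
        if base not in "ACGT":
            raise ValueError(f"invalid nucleotide {base!r} at position {i} of {pair!r}")
    return _PAIR_CLASS.get(pair, TransitionClass.MISMATCH)


def _validate_sequence(sequence: str) -> None:
    for i, base in enumerate(sequence):
        if base not in "ACGT":
            raise ValueError(
                f"invalid character {base!r} at position {i}: only A/C/G/T are scoreable"
            )


def score_transitions(
    sequence: str, params: ScoringParams | None = None, seq_id: str = ""
) -> TransitionScoreArray:
    """Score every adjacent pair of a sequence.

    AT-class steps receive ``at_weight`` plus the k-th consecutive-AT
    adjustment, where k is the 1-based position within the contiguous
    AT-run (the last adjustment repeats once the run outgrows the
    array).  Mismatch steps receive an escalating negative penalty within
    a contiguous mismatch run: ``-(start + (j-1)*delta)`` linearly, or
    ``-(start * 2**(j-1))`` exponentially.  Any non-AT step resets the
    AT-run counter, any non-mismatch step resets the mismatch counter.
    """
    params = params or ScoringParams()
    sequence = sequence.upper()
    _validate_sequence(sequence)
    n = len(sequence)
    scores = np.zeros(max(0, n - 1), dtype=float)
    classes: list[TransitionClass] = []
    adj = params.consecutive_at_adjustments
    at_run = 0
    mm_run = 0
    for i in range(n - 1):
        cls = _PAIR_CLASS.get(sequence[i : i + 2], TransitionClass.MISMATCH)
        classes.append(cls)
        if cls is TransitionClass.AT:
            at_run += 1
            mm_run = 0
            k = min(at_run, len(adj))
            scores[i] = params.at_weight + adj[k - 1]
        elif cls is TransitionClass.MISMATCH:
            mm_run += 1
            at_run = 0
            if params.mismatch_type == "linear":
                scores[i] = -(params.mismatch_start + (mm_run - 1) * params.mismatch_delta)
            else:
                scores[i] = -(params.mismatch_start * 2.0 ** (mm_run - 1))
        else:
            at_run = 0
            mm_run = 0
            scores[i] = params.weight_of(cls)
    return TransitionScoreArray(seq_id=seq_id, sequence=sequence, scores=scores, classes=classes)


def total_score(sequence: str, params: ScoringParams | None = None) -> float:
    """Sum of the transition score array; 0.0 for length <= 1."""
    return float(score_transitions(sequence, params).scores.sum())


def display_score(raw: float, style: str = "integer_floor") -> float | int:
    """Convert a raw score to its reporting convention.

    ``integer_floor`` truncates toward -inf (the convention of the
    integer score tables: 71.25 prints as 71, 65.5 as 65);
    ``one_decimal`` rounds half away from zero to one decimal
    (63.75 prints as 63.8).
    """
    if not math.isfinite(raw):
        raise ValueError(f"raw score must be finite, got {raw!r}")
    if style == "integer_floor":
        return math.floor(raw)
    if style == "one_decimal":
        return math.copysign(math.floor(abs(raw) * 10 + 0.5), raw) / 10
    raise ValueError(f"unknown display style {style!r}")
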