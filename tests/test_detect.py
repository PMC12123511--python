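import math

import numpy as np
import pytest

from zdnascan import (
    ScoringParams,
    best_subarray,
    brute_force_best_subarray,
    find_candidates,
    score_sequence_set,
    score_transitions,
    sweep_parameters,
    total_score,
)

from conftest import MODEL, MODEL_CONTEXT, MUTANT, NATIVE, TABLE2


def random_sequences(n, rng, min_len=2, max_len=200):
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        yield "".join(rng.choice(list("ACGT"), size=length))


def test_flank_trimming_yields_model_subsequence(params):
    arr = score_transitions(MODEL_CONTEXT, params, seq_id="model")
    cands = find_candidates(arr, params)
    assert len(cands) == 1
    c = cands[0]
    assert c.subsequence == MODEL
    assert (c.start, c.end) == (1, 25)
    assert c.raw_score == pytest.approx(63.75)
    assert c.display_score == 63


def test_all_mismatch_sequence_yields_nothing(params):
    assert find_candidates(score_transitions("A" * 10, params), params) == []


def test_empty_and_single_base(params):
    assert find_candidates(score_transitions("", params), params) == []
    assert find_candidates(score_transitions("G", params), params) == []


@pytest.mark.parametrize("seq,printed", TABLE2)
def test_published_sequence_scores(seq, printed, params):
    best = best_subarray(score_transitions(seq, params), params)
    assert best is not None
    assert math.floor(best[2]) == printed


def test_oracle_equivalence_on_random_sequences(params):
    """Scan-based best subarray equals exhaustive enumeration, with
    identical longest-then-leftmost tie resolution."""
    rng = np.random.default_rng(42)
    for seq in random_sequences(300, rng):
        arr = score_transitions(seq, params)
        got = best_subarray(arr, params)
        want = brute_force_best_subarray(arr)
        if want is None or want[2] <= 0:
            continue
        assert got == want, seq


def test_brute_force_trivial_cases():
    arr = score_transitions("GCGC")
    assert brute_force_best_subarray(arr) == (0, 4, 21.0)
    arr2 = score_transitions("AGCT")  # scores [-3, 7, -3]: middle singleton wins
    s, e, score = brute_force_best_subarray(arr2)
    assert score == 7.0 and (s, e) == (1, 3)
    assert brute_force_best_subarray(score_transitions("A")) is None


def test_candidate_rescoring_roundtrip(params):
    rng = np.random.default_rng(7)
    checked = 0
    for seq in random_sequences(200, rng, min_len=30, max_len=150):
        arr = score_transitions(seq, params, seq_id="r")
        for c in find_candidates(arr, params):
            assert c.subsequence == seq[c.start : c.end]
            assert total_score(c.subsequence, params) == pytest.approx(c.raw_score)
            checked += 1
    # low-threshold pass so the roundtrip is exercised even though random
    # sequences rarely reach 50
    low = ScoringParams(threshold=5.0)
    for seq in random_sequences(50, rng, min_len=30, max_len=150):
        arr = score_transitions(seq, low, seq_id="r")
        for c in find_candidates(arr, low):
            assert total_score(c.subsequence, low) == pytest.approx(c.raw_score)
            checked += 1
    assert checked > 0


def test_candidates_non_overlapping_and_sorted():
    low = ScoringParams(threshold=5.0, drop_threshold=5.0)
    rng = np.random.default_rng(3)
    for seq in random_sequences(100, rng, min_len=50, max_len=200):
        cands = find_candidates(score_transitions(seq, low), low)
        for a, b in zip(cands, cands[1:]):
            assert a.end <= b.start


def test_candidate_flanks_positive():
    low = ScoringParams(threshold=5.0, drop_threshold=5.0)
    rng = np.random.default_rng(11)
    for seq in random_sequences(100, rng, min_len=50, max_len=200):
        arr = score_transitions(seq, low)
        for c in find_candidates(arr, low):
            assert arr.scores[c.start] > 0
            assert arr.scores[c.end - 2] > 0


TWO_BLOCKS = "GC" * 6 + "TTTT" + "GC" * 6  # two strong motifs, penalized gap


def test_drop_threshold_monotonicity(params):
    counts, max_lens = [], []
    for drop in (5.0, 15.0, 50.0, 200.0):
        p = ScoringParams(drop_threshold=drop)
        cands = find_candidates(score_transitions(TWO_BLOCKS, p), p)
        counts.append(len(cands))
        max_lens.append(max((c.length for c in cands), default=0))
    assert counts == sorted(counts, reverse=True)
    assert max_lens == sorted(max_lens)
    assert counts[0] == 2 and counts[-1] == 1


def test_junction_merging_rewards_bridged_motifs(params):
    """A bridged candidate keeps both blocks and pays only the spacer
    penalties, rather than scoring the blocks independently."""
    block = total_score("GC" * 6, params)  # 77 each
    cands = find_candidates(score_transitions(TWO_BLOCKS, params), params)
    assert len(cands) == 1
    merged = cands[0].raw_score
    # gap steps: C-T -3, T-T -6, T-T -9, T-T -12, junction T-G +1.25
    assert merged == pytest.approx(2 * block - 30 + 1.25)
    assert merged >= 2 * block - 30.0


def test_score_sequence_set_candidate_mode(params):
    df = score_sequence_set([("s1", MODEL_CONTEXT), ("s2", "A" * 20)], params)
    assert list(df["seq_id"]) == ["s1"]
    assert df.iloc[0]["raw_score"] == pytest.approx(63.75)


def test_score_sequence_set_total_mode():
    p = ScoringParams(total_sequence_scoring=True)
    df = score_sequence_set([("s", "GC")], p)
    assert df.shape == (1, 2)
    assert df.iloc[0]["total_score"] == pytest.approx(7.0)


def test_score_sequence_set_duplicate_ids(params):
    with pytest.raises(ValueError, match="dup"):
        score_sequence_set([("dup", "GCGC"), ("dup", "ATAT")], params)


def test_worker_determinism(params):
    rng = np.random.default_rng(19)
    records = [(f"s{i}", seq) for i, seq in enumerate(random_sequences(40, rng, 150, 200))]
    p = ScoringParams(threshold=5.0)
    serial = score_sequence_set(records, p, n_workers=1)
    parallel = score_sequence_set(records, p, n_workers=4)
    assert serial.to_csv(index=False) == parallel.to_csv(index=False)


def test_sweep_single_combination(params):
    rows = sweep_parameters(
        [("GC" * 5, "forming"), ("A" * 30, "nonforming")],
        {"gc_weight": [7.0]},
    )
    assert len(rows) == 1
    assert rows.iloc[0]["forming_correct"] == 1
    assert rows.iloc[0]["nonforming_correct"] == 1
    assert rows.iloc[0]["accuracy"] == 1.0


def test_sweep_gc_weight_closed_form():
    # GC(5) has 9 GC steps: forming iff 9 * w >= 50, i.e. w >= 6.
    rows = sweep_parameters(
        [("GC" * 5, "forming")], {"gc_weight": [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]}
    )
    got = dict(zip(rows["gc_weight"], rows["forming_correct"]))
    assert got == {4.0: 0, 5.0: 0, 6.0: 1, 7.0: 1, 8.0: 1, 9.0: 1}


def test_sweep_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        sweep_parameters([], {"gc_weight": [7.0]})
    with pytest.raises(ValueError):
        sweep_parameters([("GC", "forming")], {"gc_weight": []})
    with pytest.raises(ValueError):
        sweep_parameters([("GC", "maybe")], {"gc_weight": [7.0]})


def test_default_classification_matches_published_scores(params):
    labeled = [(seq, "forming" if printed >= 50 else "nonforming") for seq, printed in TABLE2]
    labeled += [(NATIVE, "nonforming"), (MUTANT, "forming"), (MODEL, "forming")]
    rows = sweep_parameters(labeled, {"gc_weight": [7.0], "gt_weight": [1.25], "ac_weight": [1.25]})
    row = rows.iloc[0]
    assert row["forming_correct"] == row["forming_total"]
    assert row["nonforming_correct"] == row["nonforming_total"]
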