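import pytest

from zdnascan import ScoringParams

# Published integer display scores (floored best-subarray raw score,
# default parameters) for 20 experimentally ranked Z-forming sequences.
TABLE2 = [
    ("TGCGTGCGCGCGCGCG", 87),
    ("GCGCCCGCGCGCGCGC", 82),
    ("GCGCGCGCGCGT", 71),
    ("CGCGCGCGCGC", 70),
    ("GCGCGCGCGCG", 70),
    ("GCGCGTGCGCGC", 65),
    ("GCGCGCCCGTACGCGC", 64),
    ("GCACGCACACGCGCGT", 64),
    ("CGCACGCGCACGCA", 62),
    ("CGCGCGCGCACA", 59),
    ("TGTGCGCGCGCACATG", 58),
    ("GCGCGCACGCG", 58),
    ("CGCGCGCGC", 56),
    ("GCGCACGCACGC", 54),
    ("GCGCGCGCCCGC", 54),
    ("TGTGTGCGCGCGTGTG", 53),
    ("CGCGCACGCACACATG", 53),
    ("GTGCGTGCCCGCGCGT", 53),
    ("CACGCGCACGTGC", 49),
    ("CGTGCGTGTGTGTGCG", 47),
]

# Mouse metallothionein-I promoter series: the native sequence does not
# form Z-DNA in vivo, the AC->CA point-reversal mutant does, and the
# longer model context forms it readily.
NATIVE = "GCGCGTGACTATGCGTG"  # raw 45.5, below threshold
MUTANT = "GCGCGTGCATATGCGTG"  # raw 59.5
MODEL_CONTEXT = "GACGCGGGGCGCGTGCATATGCGTGG"  # 26 nt, flanks trimmed on detection
MODEL = "ACGCGGGGCGCGTGCATATGCGTG"  # 24 nt, raw 63.75, one-decimal display 63.8


@pytest.fixture
def params():
    return ScoringParams()
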