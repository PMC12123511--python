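# zdnascan

Detection of potential Z-DNA-forming sequences in DNA by
dinucleotide-transition scoring.

Z-DNA is a left-handed duplex conformation with a zigzag backbone,
favored by alternating purine–pyrimidine tracts (GC the most strongly,
GT/AC intermediate, AT the least).  Z-forming tracts influence
transcription and replication and are linked to genetic instability, so
locating them in arbitrary sequence is a recurring need in genome
biology.  `zdnascan` is a library and command-line tool for that task:
it scores every adjacent base pair of a sequence, extracts
maximum-scoring subarrays as candidate Z-DNA intervals, optionally
annotates them with the nearest gene, and provides the downstream
genomic-characterization computations (compartment densities,
anchor-centered enrichment profiles with bootstrap confidence bands).

## The scoring model

For a sequence $s_1 s_2 \ldots s_n$ the score is a sum over adjacent
pairs ("transitions"):

* GC/CG transitions score $w_{GC} = 7$, GT/TG and AC/CA score
  $w_{GT} = w_{AC} = 1.25$, AT/TA score $w_{AT} = 0.5$ **plus** a
  position-dependent adjustment $a_k$ within each contiguous AT-run
  ($a = (0.5, 0.5, 0.5, 0, 0, -5, -100)$, the last value repeating),
  because long AT runs form hairpins/cruciforms rather than Z-DNA;
* every other ordered pair (purine–purine, pyrimidine–pyrimidine, or a
  same-base step, collectively "mismatches") is penalized
  $-(3 + 3(j-1))$ at the $j$-th position of a contiguous mismatch run
  (optionally $-3 \cdot 2^{\,j-1}$, exponential mode); the run resets
  after any non-mismatch transition.

The weights are calibrated to the shortest repeats that form Z-DNA in
cellular mutagenesis assays: GC(4) has 7 GC transitions (score 49, just
below the detection threshold of 50), GC(5) scores 63, and GT(25) has
49 GT transitions (61.25).

Candidates are maximum-scoring subarrays of the transition score array,
found by a Kadane-style scan with a *drop threshold*: the current
window ends once the running sum falls more than `drop_threshold`
(default 50) below its running maximum, the best prefix is emitted if
it reaches `threshold` (default 50), and scanning resumes after it.
Large drop thresholds bridge penalized interruptions into fewer,
longer candidates — merging two Z segments across a short imperfection
saves two of the four energetically costly B–Z junctions that separate
segments would need.

## Worked example

```bash
$ cat demo.fa
>native
GCGCGTGACTATGCGTG
>mutant
GCGCGTGCATATGCGTG
>model
GACGCGGGGCGCGTGCATATGCGTGG
$ zdnascan --fasta demo.fa --output_dir demo_out
INFO found 2 candidates in 3 sequences
$ cat demo_out/candidates.csv
seq_id,start,end,length,raw_score,display_score,subsequence
mutant,0,17,17,59.5,59,GCGCGTGCATATGCGTG
model,1,25,24,63.75,63,ACGCGGGGCGCGTGCATATGCGTG
```

These three sequences are a classic experimental series from the mouse
metallothionein-I promoter.  The native sequence totals 45.5 — below
the threshold of 50, consistent with its failure to form Z-DNA without
strong torsional stress — so it yields no candidate.  Reversing one AC
interruption (the mutant) restores a perfect alternating
purine–pyrimidine pattern and the score rises to 59.5, a candidate.
The longer model context scores 63.75; note its candidate interval
`[1, 25)` — the subarray maximization trims the flanking `GA` and
terminal `GG` mismatch transitions, reporting the 24-nt core.
Coordinates are 0-based half-open; `display_score` floors the raw
score.

The same results are available programmatically:

```python
from zdnascan import ScoringParams, score_transitions, find_candidates

arr = score_transitions("GACGCGGGGCGCGTGCATATGCGTGG", seq_id="model")
print(find_candidates(arr))
# [ZCandidate(seq_id='model', start=1, end=25, raw_score=63.75, ...)]
```

All scoring flags mirror the recommended-parameter names
(`--GC_weight`, `--AT_weight`, `--consecutive_AT_scoring`,
`--mismatch_penalty_starting_value`, `--drop_threshold`,
`--total_sequence_scoring`, ...); run `zdnascan --help` for the list.
Supplying `--gff genes.gff3` adds nearest-gene annotation with
strand-aware signed TSS/TES distances.

## Package layout

| module | contents |
| --- | --- |
| `zdnascan.scoring` | parameters, transition classification, score arrays, display conventions |
| `zdnascan.detect` | candidate extraction, brute-force oracle, batch scoring, sensitivity sweeps |
| `zdnascan.io` | FASTA/GFF3/BED reading, ambiguity splitting, CSV output |
| `zdnascan.annotate` | nearest-gene assignment, signed TSS/TES distances |
| `zdnascan.landscape` | motif densities, enrichment profiles, bootstrap CIs |
| `zdnascan.fixtures` | synthetic sequence/interval generators with known ground truth |
| `zdnascan.cli` | the `zdnascan` command |

See `docs/methods.md` for the full model description, parameter
semantics, and numerical design choices.
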