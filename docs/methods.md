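# Methods

## Model

`zdnascan` scores the Z-DNA-forming propensity of a DNA sequence from
its linear sequence alone.  The biological premise: Z-DNA requires
alternating syn/anti base conformations, which alternating
purine–pyrimidine dinucleotides support — GC steps most strongly,
GT/AC steps weakly, AT steps marginally (long AT runs fold into
hairpins or cruciforms instead).  Any step that breaks the alternation
(GG, CC, GA, CT, AA, TT, AG, TC) locally forces B-form and is
penalized increasingly the longer the interruption.

The score of a sequence is the sum of per-transition contributions;
a *candidate* is a contiguous stretch whose transition-sum is maximal
within its scan window and reaches the acceptance threshold.  The
score is not a statistical z-score: units are arbitrary "score units"
anchored by the calibration below.

### Transition scores

For adjacent bases $(s_i, s_{i+1})$:

| class | pairs | contribution |
| --- | --- | --- |
| GC | GC, CG | $w_{GC}$ |
| GT | GT, TG | $w_{GT}$ |
| AC | AC, CA | $w_{AC}$ |
| AT | AT, TA | $w_{AT} + a_{\min(k, |a|)}$, $k$ = 1-based position in the contiguous AT-run |
| mismatch | all others | $-(p_0 + \delta\,(j-1))$ linear, or $-p_0\,2^{\,j-1}$ exponential; $j$ = position in the contiguous mismatch run |

Both run counters reset at any transition of another class.  The AT
contribution is *additive* ($w_{AT}$ plus the adjustment), which is
the only reading that reproduces the full published calibration table
(e.g. a single AT step inside an otherwise alternating 16-mer
contributes exactly $1.0$).  The exponential escalation base (2) is
this package's choice; the option is exposed behind
`mismatch_type="exponential"` and linear is the tested default.

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| `gc_weight` | 7 | GC(4) = 7 GC steps is the shortest Z-forming GC repeat; 7·7 = 49 sits just below the threshold |
| `gt_weight`, `ac_weight` | 1.25 | GT(25) = 49 GT steps is the minimal Z-forming GT repeat; 49·1.25 = 61.25 clears the threshold |
| `at_weight` | 0.5 | weakest alternating step |
| `consecutive_at_adjustments` | 0.5, 0.5, 0.5, 0, 0, −5, −100 | up to ~4 AT units tolerated; beyond that hairpin formation dominates; the last value repeats for all further AT steps |
| `mismatch_start` / `mismatch_delta` | 3 / 3 | first interruption is cheap (one step inside a long tract), contiguous interruptions escalate |
| `threshold` | 50 | acceptance cutoff, compared with ≥ so a sequence scoring exactly 50 is reported |
| `drop_threshold` | 50 | early-stopping depth of the subarray scan (below) |
| `total_sequence_scoring` | off | score whole records instead of extracting subarrays |

All weights are per transition; thresholds are in the same score
units.  Raw scores are exact decimals internally; the integer display
convention floors (71.25 → 71, 65.5 → 65), the one-decimal convention
rounds half away from zero (63.75 → 63.8).  Both conventions are
derived from the same raw arithmetic.

### Candidate extraction

The transition score array is scanned left to right.  A window opens
at the first positive transition and accumulates a running sum,
tracking the running maximum and the prefix achieving it (at equal
sum the longer prefix is kept).  The window terminates when

1. the running sum falls more than `drop_threshold` below the running
   maximum (the drop rule: small values split interrupted motifs into
   short candidates, large values bridge interruptions into fewer,
   longer ones), or
2. the running sum falls below zero (Kadane reset: a window with a
   negative-sum prefix is always beaten by its own suffix; without
   this rule the scan provably misses the global maximum subarray when
   a dip deeper than the accumulated prefix — but shallower than the
   drop threshold — precedes a stronger block), or
3. the array ends.

The best prefix is emitted as a candidate iff its sum ≥ `threshold`;
scanning resumes at the first transition fully outside the emitted
interval (for rule 2, after the negative dip; in both cases no
sub-window of the skipped stretch can reach the emitted maximum, which
is what makes the scan agree with exhaustive enumeration).  Emitted
candidates are therefore non-overlapping, sorted, and begin and end on
positive-scoring transitions.  Ties are resolved longest, then
leftmost.  The test suite checks the scan against an $O(n^2)$
brute-force enumeration oracle on seeded random sequences; the oracle
lives in the package (`brute_force_best_subarray`) and is never used
as the implementation path.

Candidates and genes use 0-based half-open coordinates everywhere;
GFF input (1-based inclusive) is converted on read.

### Ambiguity policy

Input is uppercased.  IUPAC ambiguity codes (N, R, Y, ...) split a
record into independently scored segments — an ambiguous base cannot
be assigned a syn/anti conformation, so no candidate may span one.
Segment offsets keep reported coordinates on the original sequence.
Characters outside the IUPAC DNA alphabet (including U) are rejected
with their position.

## Annotation

Each candidate is assigned the gene minimizing the gap between
interval edges (0 when they intersect); equidistant flanking genes
resolve to the upstream (smaller-start) one.  Signed TSS/TES distances
are measured from the candidate midpoint $(start+end)/2$ in the
gene's reading direction (positive = downstream of the site); on the
'−' strand the TSS is the last base of the gene interval and the axis
flips.  The midpoint is an interval-edge coordinate while TSS/TES are
base coordinates, so coordinate reflection changes signed distances by
exactly one base — the property tests allow for this.  Nearest-gene
choice is verified against an exhaustive linear scan on 1,000-gene
fixtures.

## Landscape computations

These implement the genomic-characterization methodology generically
over interval inputs, at desk scale:

* **Region density** — motifs are merged, overlap with each region is
  accumulated, and density = overlapped bp / region bp × 1000
  (bp of motif per kb of region); per-region values are retained for
  mean ± SE summaries.  Verified against a per-base bitmap oracle.
* **Positional profiles** — a symmetric window (default half-width
  2000 bp) is laid over each anchor (TSS, TES, or origin midpoint); a
  motif adds +1 to every relative position it overlaps, clipped to the
  window; '−'-strand anchors flip the relative axis.  The count vector
  is normalized by its window mean, so a flat background sits at 1.0
  and the normalized vector always averages to exactly 1 when any
  count is present.
* **Bootstrap bands** — anchors (the sampling units of the gene-by-gene
  construction) are resampled with replacement `n_boot` times (default
  1000) and per-position 2.5th/97.5th percentiles of the normalized
  profiles are reported.  Percentiles use outer order statistics
  (`np.quantile` methods `lower`/`higher`), so two replicates give the
  elementwise min/max and repeated identical anchors give zero-width
  bands.  All randomness flows through a seeded
  `numpy.random.Generator`.

Genome-wide numbers (motif counts, bp coverage, fold-enrichments at
TSSs and replication origins) depend on a complete human assembly and
external annotation sets and are out of scope; the computations are
instead validated on synthetic data with known ground truth (below).

## Synthetic data

`fixtures` generates every non-trivial test input:

* **Planted sequences** — an i.i.d. background (default 60% A/T:
  A=T=0.3, C=G=0.2, chosen so spurious Z-scores stay far below
  threshold) is redrawn until an exact maximum-subarray check confirms
  it contains no ≥-threshold window; motifs are then planted at known
  positions behind 6-base mismatch insulator runs whose cumulative
  escalating penalty (≥ 63) exceeds anything a sub-threshold
  background can pay back, so detection provably recovers the planted
  interval exactly and the truth table's closed-form scores are
  checkable against the brute-force oracle.
* **Anchored interval sets** — anchors spaced beyond window width with
  one motif at a fixed strand-aware offset; the expected profile peak
  position (the offset) and height ($(2h+1)/\text{footprint}$) follow
  from the construction and are emitted alongside.

What the generators deliberately do not emulate: repeat structure,
GC-content heterogeneity, chromatin context, and correlated motif
placement of real genomes.  Passing tests therefore demonstrate the
correctness of the computations, not genome-scale biological effect
sizes.

## Problem sizes and determinism

The test suite runs the brute-force subarray oracle on 1,000+ seeded
random sequences of length 2–200, annotation against 1,000-gene
fixtures, densities on 100-kb synthetic genomes, and bootstrap bands
with up to 200 replicates over ~400 anchors — sizes chosen so the full
suite completes in seconds while exercising every code path at
non-toy scale.  Batch scoring and the CLI are contractually
deterministic in the worker count: records are distributed to
processes but results are emitted in input order, and tests assert
byte-identical CSVs for 1 vs 4 workers.

## Known limitations

* Linear-sequence model only: no supercoiling, ions, methylation or
  protein context; under Z-favoring conditions users should lower the
  threshold.
* The exponential mismatch escalation base is a documented convention,
  not experimentally derived.
* Extremely deep penalized gaps (deeper than `drop_threshold`) are
  never bridged even when a downstream block would more than repay
  them; with the default drop of 50 this requires ≥ 6 contiguous
  mismatches followed by a ≥ 50-unit recovery and is not observed in
  random-sequence equivalence testing.
* Nearest-gene annotation is gene-level; transcript-level resolution
  (UTRs, alternative TSSs) is out of scope.
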