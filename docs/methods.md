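# Methods

## Problem and model

Given an assembly of a *presence* sample P and short reads of an *absence*
sample A, the pipeline reports the sequences of P that A's reads never
cover: the set P − A. The central assumption is that a sequence truly
absent from A (for example a transposable-element family that invaded after
A was collected) produces a **zero-coverage gap** at each of its insertions
when A's reads are aligned to P, provided the aligner is local: reads
spanning an insertion junction must be soft-clipped at the junction rather
than forced through it, otherwise depth bleeds into the insertion and the
gap boundaries blur. Conversely the method cannot see quantitative
copy-number differences — a sequence present in both samples at different
copy number is covered everywhere and leaves no gap.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| depth threshold t | 0 | positions with depth ≤ t are gap positions (zero coverage) |
| merge distance d | 100 bp | gaps separated by ≤ d merge; absorbs sparse spurious read placements inside a gap (e.g. reads from degraded older copies of the same family) |
| minimum gap length | 1000 bp (inclusive) | shorter gaps are noise at low coverage; 1000 bp is the validated floor for reliable detection |
| bias flank | 10 kb per side | window for the flank mean f; truncated at contig ends |
| cluster identity / coverage | 80% over 50% of the shorter sequence | pairwise-link thresholds; permissive enough to unify diverged copies of one family, strict enough that unrelated kilobase-scale random sequences never link |
| minimum cluster size | 3 | groups of ≥ 3 similar gap sequences are repetitive candidates; 1–2 member groups go to the non-repetitive output |

The coverage bias of a gap is `2·f/(g+f) − 1` with f the mean depth over
the two flanking windows (positions pooled, windows truncated at contig
ends, other gaps *not* excluded) and g the genome-wide mean depth over
every position including gap interiors. It is 0 iff f = g, −1 when the
flanks are empty, +1 in the limit of infinitely inflated flanks, and
strictly increasing in f. When no reads align at all (f = g = 0) the score
is undefined and the run aborts. A cluster's score is the median of its
members' biases.

## Read mapper

The built-in mapper exists so the whole pipeline and its validation run at
desk scale without an external aligner; externally produced SAM bypasses it
and is the recommended route for real data.

- **Seeding**: exact k-mer hits (k = 17, sampled every ⌊k/3⌋ positions of
  the read) against a sorted-array index of every reference k-mer. Reads
  shorter than k are unmapped by definition.
- **Extension**: per candidate diagonal, the maximal-scoring contiguous
  segment under +1 match / −3 mismatch; the segment boundaries are the
  soft-clip boundaries. A candidate survives if the segment covers ≥ 50% of
  the read.
- **Refinement**: the clipped segment is re-aligned with edlib (semi-global
  against a padded reference window) to admit indels and fix the exact
  boundary; the placement is rejected if the edit distance exceeds 10% of
  the aligned length.
- **Tie-breaking**: minimal edit distance, then longest aligned span, then
  (contig order, lowest start). Multi-mapping reads are therefore placed
  once, deterministically — which reproduces the real-data behaviour where
  reads from degraded older copies land on new insertions and fragment
  their gaps.
- Forward orientation is tried first, then the reverse complement.
- A vectorized fast path resolves reads whose first k-mer hits a unique
  locus and which match the reference there exactly; everything else takes
  the per-read path. Depth counts only M/=/X reference columns, exactly as
  the SAM-input path does, and junction overshoot is limited to chance
  microhomology (a read is extended into an insertion only as far as its
  next bases happen to match, ~1–2 bp on average).

## Clustering and consensus

All gap-sequence pairs sharing at least one 15-mer (either strand) are
aligned with edlib: the full shorter sequence against the best infix of the
longer one, both orientations. This semi-global definition matches local
semantics for the dominant case — near-complete copies of one element —
and `identity = (columns − edit distance) / columns`. Unrelated random
kilobase sequences score ≈ 50–55%, far under the 80% threshold, and almost
never share a 15-mer in the first place. Edges above threshold define a
graph whose connected components (single linkage) are the clusters.

Each cluster's members are aligned progressively: guide tree by average
linkage on fractional shared-8-mer distances, then banded profile–profile
alignment with affine gaps (match +1, mismatch −1, gap open −2, gap extend
−0.5; band ≥ 32 columns around the length-difference diagonal). De-gapping
any row of the result reproduces the corresponding input exactly. The
consensus takes each column's most frequent base; a column where the gap
character holds a strict majority is omitted; base ties break in the fixed
order A < C < G < T; N never outvotes a base (a column of only N and
non-majority gaps yields N). Locus-specific gap-boundary overhangs appear
as gap-majority columns and drop out, which is why the consensus of a clean
run matches the simulated insert exactly even when individual gap calls
carry small flank extensions.

An optional refinement step re-extracts each member with 3000 bp of
flanking sequence and repeats MSA + consensus; element sequence that the
gap calls truncated (e.g. because reads from degraded older copies covered
part of a new insertion) re-enters the consensus this way.

## Simulation design

The validation generator reproduces the study conditions the pipeline is
benchmarked under: 25 copies of a 5000-bp uniform-random insert spliced
into a template at points ≥ 25 kb apart and ≥ 10 kb from contig ends (so
no 10-kb bias flank overlaps a neighbouring insertion), reads always drawn
from the insert-free template. The default desk-scale template is a seeded
2-Mb uniform-random sequence rather than a ~25-Mb chromosome arm; detection
quantities (TP, consensus identity/length) are template-size independent,
but false-positive counts at 1× coverage scale with genome length, so only
zero-FP regimes (coverage ≥ 5) are asserted numerically.

Read models:

- **uniform** — deterministic tiling at stride `read_length / coverage`;
  with zero error rate every read is an exact template substring.
- **random** — `round(coverage · L / read_length)` reads with uniform
  starts; at 1× this leaves zero-depth template positions, the source of
  low-coverage false positives.
- **ancient** — endogenous fragments with lognormal lengths (mean 50 bp,
  sd 15, truncated to [25, 150]), strand chosen at random, terminal
  deamination C→T at the 5' end and G→A at the 3' end with probability
  `p0 · decay^position` (p0 = 0.3, decay = 0.5); plus 10% bacterial reads
  from an independent seeded random contaminant and 8% modern-contamination
  reads (undamaged, 100 bp), totalling 82% endogenous. The modern
  contaminant defaults to the template genome itself — modern DNA of the
  study organism does not contain the simulated novel element — and can be
  pointed at any genome (e.g. the insertion-carrying assembly) via
  `modern_genome`.

Substitution sequencing errors are supported in the uniform/random models;
indel errors, base-quality profiles, and paired-end structure are not
simulated. What passing tests show is therefore that the *method* —
gap calling, bias, clustering, consensus — behaves as designed under
realistic coverage, fragmentation, damage and contamination regimes; they
do not exercise aligner sensitivity on heavily diverged real reads, for
which an external aligner plus the SAM input path is appropriate.

Evaluation uses a 50%-of-locus-length overlap rule for true positives
(insensitive on clean simulations, where gaps and loci coincide almost
exactly), counts a fragmented detection of one locus once, and splits false
positives into repetitive (clusters touching no truth locus) and
non-repetitive records. Consensus length and identity are taken from the
cluster with the most truth-overlapping members; identity uses the same
anchored semi-global alignment as clustering, so terminal truncation of a
consensus does not depress it — two sequences sharing no 15-mer score 0.

## Numerical and degenerate-case choices

- All coordinates are 0-based half-open everywhere (BED convention); SAM's
  1-based POS is converted at parse time only.
- FASTA/BED/TSV writers are byte-deterministic; with a fixed seed two runs
  produce byte-identical outputs.
- Gap merging requires sorted non-overlapping input and is idempotent and
  monotone in d; d = 0 merges only touching intervals.
- A zero-length flank window (gap touching both contig ends) contributes
  no positions, giving f = 0 and hence bias −1 when g > 0.
- Empty results (no retained gap) are a successful run with empty output
  files; `pairwise_hits` of a single sequence yields no edges and a
  singleton non-repetitive record.
- Reads failing all mapping criteria are counted, not errored; a run where
  nothing maps is a hard error.
- The problem sizes used by the test suite and acceptance script (2-Mb
  template, 25 × 5-kb inserts, coverages 1–10×, 10 read-placement seeds for
  the stochastic model) were chosen as the smallest sizes at which the
  benchmark's zero-FP claims are statistically meaningful.

## Known limitations

- The built-in mapper is tuned for the simulation regime (≤ ~10%
  divergence, substitution-dominated); real degraded reads are better
  aligned externally (`--sam`).
- Semi-global pairwise similarity understates identity when two gap
  sequences overlap only partially (e.g. one is a fragment of a composite
  region); such pairs may fail to link.
- The majority consensus can retain low-confidence columns when most
  members carry same-length locus-specific overhangs that the profile
  aligner stacks rather than gaps.
- FP counts at 1× coverage depend on template size and are not asserted
  numerically, only the zero-FP regimes at ≥ 5×.
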