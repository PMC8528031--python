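# Methods

## Depth model

Coverage of a reference base is the number of filtered alignments whose
CIGAR places a reference-consuming, non-intron operation over that base.
The tally uses the increment/decrement (delta-array) formulation: a signed
array of length *L*+1 per chromosome receives +1 at each covered block
start and −1 at each block end; one prefix sum yields per-base depth. The
array is one element longer than the chromosome so a block ending exactly
at *L* decrements without a branch. Correctness is checked against a
deliberately naive counter (`simulate.brute_force_depth`) that re-walks
every CIGAR and increments covered bases directly, with its own inline
flag/MAPQ filter — the two paths share no depth-relevant code.

CIGAR semantics: `M`, `=`, `X` cover; `D` covers iff `count_deletions`
(default true, matching common pileup-depth semantics — a deleted base
still has an alignment spanning it) and is merged into adjacent blocks;
`N` opens a junction gap, never coverage (RNA-seq introns must not inflate
depth); `I`/`S` consume query only; `H`/`P` consume nothing. With
`count_deletions=false` the `D` gap is a coverage hole but *not* a
junction.

Filtering defaults: exclude mask `0x704` (unmapped | secondary | QC-fail |
duplicate), empty include mask, supplementary alignments included — the
permissive convention of fast depth tools; all overridable. The "unique"
pass adds `MAPQ >= 10`. Both passes are tallied in one scan when
requested. Overlapping mates of a proper pair are double-counted, as depth
tools conventionally do. Alignments overhanging the stated chromosome
length are clamped to `[0, L)` with a warning (tolerant of malformed
headers); blocks entirely outside are skipped with a warning.

Depth values are 64-bit integers for alignment input and floats for BigWig
input; AUC accumulates in Python's unbounded arithmetic, so a 30× whole
genome cannot overflow.

## Runs, AUC, interval summaries

The run-length encoding emits maximal constant-value runs; expanding them
(zeros restored) reproduces the depth vector exactly, which is asserted as
a property test. AUC = Σ (end − start) × value over runs; an optional
disjoint annotation splits it into annotated/unannotated parts, and
overlapping annotations are rejected with a pointer to `disjoin` (summing
them directly would double-count bases).

Interval summaries treat uncovered bases as value 0, not missing — these
are coverage semantics, not signal-averaging semantics; BigWig tools
differ here, so the choice is stated prominently. The mean denominator is
the query length after clamping to the source's chromosome bounds
(clamping is logged). Summarization groups source runs per chromosome into
sorted arrays and answers each query with two binary searches plus a
vectorized overlap dot-product; queries keep their input order in the
output.

`disjoin` is breakpoint-cut with name propagation: the union of inputs is
cut at every distinct start/end, each piece labelled with the
semicolon-joined names of the inputs covering it, in input order. The
breakpoint-cut (rather than merged-union) construction was chosen as the
more informative superset: a merged union is recoverable from it, but not
vice versa. It is idempotent on interval bounds; on a second application
names re-join per piece, which the tests treat as the defined behaviour.

## Extended extractors

*Alternate bases*: MD/CIGAR co-walk. Matched stretches consume both; an MD
letter names the reference base and the read supplies the alternate; `^`
deletions advance reference only; `I`/`S` advance query only; `N` advances
reference only (MD does not describe skipped introns, and numeric match
counts may span them). Any disagreement between MD and CIGAR raises an
error naming the read. When MD is absent, direct comparison against a
reference FASTA produces the same list; the two mechanisms are asserted
equal on every fixture read. Records are filtered with the same default
flag mask as coverage (so PCR duplicates do not inflate counts). Output is
raw counts; allele frequency needs total depth at the position, obtained
by joining with the coverage output.

*Junctions*: one record per `N` operation, strand from `XS` when present,
else `?` — read strand is not transcript strand for unstranded protocols,
so nothing is inferred from flags. Co-occurrence groups primary alignments
by read name *within a chromosome* (cross-chromosome fragments would break
the by-chromosome parallelism contract and are vanishingly rare for
spliced pairs); a fragment with ≥ 2 distinct junctions across its mates is
flagged: those junctions were observed on one molecule, i.e. one
transcript. Duplicate-flagged pairs remain distinct fragments here, since
grouping is purely by name.

*Fragment lengths*: |TLEN| counted once per pair, from the mate with
TLEN > 0, skipping TLEN = 0 (cross-chromosome or half-mapped pairs) and,
by default, pairs without the proper-pair flag. Secondary/supplementary
records never count. The default is the raw genomic span; a
`splice_adjusted` variant subtracts the union of N-gap lengths observed in
the fragment, giving a cDNA-scale length for RNA-seq — non-default because
aligner TLEN conventions vary and the raw value is the reproducible one.

## Single-pass driver and parallelism

One scan of the input feeds every requested product simultaneously: the
two delta arrays, the alternate-base counter, the junction grouper and the
TLEN histogram each see the record stream once. Work may be split by
chromosome (never within one — that would require merging boundary state);
per-chromosome results are concatenated in the header's chromosome order,
so output bytes are identical for any worker count. Threads require an
index; without one the driver falls back to the sequential scan, which
produces the same bytes. Coordinate order is required and verified both
from the header (`SO:coordinate`) and while streaming.

## Synthetic data

The generator emulates a small paired-end RNA-seq-like sample: uniform
random reference (two 100 kb chromosomes by default), fragments with
normal genomic span (mean 320 bp, sd 60, floor 160), 100 bp mates at the
fragment ends, introns of 60–2000 bp inserted into a fragment with
probability 0.25 (occasionally two, so junction co-occurrence actually
arises), uniform substitutions at rate 0.002, short (1–3 bp) deletions at
rate 0.02 per mate, PCR-duplicate pairs at rate 0.03, and a MAPQ mixture
(60/30/3/0 at 0.70/0.10/0.15/0.05) in which 20 % of fragments fall below
the unique-pass threshold. Defaults were fixed once as a plausible desk-
scale sample; tests and the acceptance script vary splice probability,
mismatch rate and fragment count around them.

Every record's CIGAR, MD, SEQ and TLEN are constructed jointly from the
same fragment structure, and ground truth (per-base depth for both passes,
mismatch counts, per-fragment junction sets, drawn |TLEN| values) is
recorded from that structure directly — not by re-parsing the emitted SAM —
so generator, engine and naive oracle are three independent routes to the
same numbers. A single seeded RNG stream drives everything; a fixed seed
reproduces the fixture byte-for-byte, making every failing property test
replayable.

What the generator does **not** emulate: realistic base-quality strings
(constant `I`), sequence-composition bias, indel/splice motif realism,
mate overlap dovetails, chimeric or clipped alignments, or unmapped
records. Passing tests therefore demonstrate coordinate/format
correctness and algorithmic equivalence, not robustness to every artifact
of real aligner output.

## Problem sizes and numerical choices

The test suite exercises ≥ 20 random generator configurations (splice
probability 0–0.8, mismatch rate 0–0.05) including one 50 000-fragment
dataset; BigWig path agreement uses 1000 random query intervals at float32
relative tolerance 1e-6 (BigWig stores 32-bit floats); disjoin correctness
runs 1000 random interval sets against a per-base ownership oracle. These
sizes keep the full suite under a minute on one CPU while covering the
condition ranges. Integer depth summaries are exact in float64 (all values
far below 2^53), so conservation checks assert equality, not tolerance.

Known limitations: no windowed/fixed-bin mode; no strand-specific
coverage; no GFF/GTF parsing (pre-convert to BED); no overlap-mate
clipping; CRAM support is exactly what the underlying I/O library
provides, with the reference resolved through its usual configuration.
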