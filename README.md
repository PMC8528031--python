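# covtally

Coverage quantification for BAM/CRAM/SAM and BigWig files: per-base depth,
run-length-encoded coverage output (bedGraph/BigWig), per-interval sums and
means over BED annotations, the area-under-coverage (AUC) statistic, and
one-pass extraction of alternate-base coverage, splice-junction
co-occurrences and fragment-length distributions.

It is written for sequencing analyses that repeatedly re-quantify the same
samples — RNA-seq against updated gene annotations, copy-number work,
coverage under ChIP-seq peaks — where the economical workflow is: process
the alignment file **once**, keep the small coverage and summary products,
and discard the BAM.

## The method

For one chromosome of length *L*, depth is tallied with the
increment/decrement (delta-array) algorithm: each reference block
[*s*, *e*) covered by an alignment contributes

```
delta[s] += 1        delta[e] -= 1
```

and a single prefix sum turns `delta` into per-base depth, so the cost is
*O*(*L* + blocks) instead of *O*(covered bases). Covered blocks come from
the CIGAR string: `M`/`=`/`X` cover reference bases, `D` covers them by
default (a flag disables this), `N` (introns) never does, `I`/`S` consume
query only. The depth vector is then run-length encoded into maximal
constant-value runs — the unit shared by bedGraph, BigWig, interval
summarization and the AUC:

```
AUC = Σ_bases depth(b) = Σ_runs (end − start) × value
```

Interval summaries are overlap-weighted:
`sum(q) = Σ_runs overlap(q, run) × value`, `mean(q) = sum(q) / |q|`, with
uncovered bases counting as depth 0. Overlapping annotations are first
*disjoined* — cut at every breakpoint, each piece labelled with the names of
the inputs covering it — so shared bases are counted exactly once.

Two coverage passes can be produced in the same scan: **all** (default flag
filter: excludes unmapped, secondary, QC-fail, duplicate) and **unique**
(additionally requires MAPQ ≥ a threshold, default 10).

Mismatch recovery for alternate-base coverage co-walks the CIGAR with the
MD auxiliary tag (or compares against a reference FASTA when MD is absent);
junction records come from `N` operations with strand from the `XS` tag;
fragment lengths are |TLEN| counted once per pair.

## Worked example

`examples/01_depth_and_auc.py` builds a small synthetic paired-end sample
(two 100 kb chromosomes, 500 fragments), tallies depth and prints:

```
first five coverage runs (chrom, start, end, depth):
  chr1	392	465	1
  chr1	465	492	2
  chr1	492	565	1
  chr1	742	842	1
  chr1	1109	1165	1
total AUC = 100037
mean genome-wide coverage = 0.500x
```

Each run is a maximal stretch of constant depth (read pairs overlap at
465–492, hence depth 2). The AUC of 100 037 over a 200 kb genome is a mean
coverage of 0.5×: 1000 reads × 100 bp ≈ 100 kb of covered bases, with
deletions/duplicate filtering accounting for the small remainder. The other
examples show BigWig re-quantification with `disjoin` and the RNA-seq
extractors.

The same operations are available from the shell:

```bash
covtally sample.bam --coverage --auc --annotation genes.bed --op both \
    --min-unique-qual 10 --prefix sample
covtally sample.bw  --annotation genes.bed --op mean --prefix resummary
covtally sample.bam --alts --junctions --frag-dist --prefix sample
```

All requested alignment-derived outputs are produced in a single pass over
the input; with `--threads N` and an indexed BAM, chromosomes are processed
in parallel with bit-identical output for any worker count.

## Scope notes

- Overlapping proper-pair mates are double-counted, as depth tools
  conventionally do unless told otherwise; there is no per-base quality
  weighting.
- Remote HTTP/FTP URLs are passed through to the underlying I/O libraries
  (htslib via pysam, libBigWig via pyBigWig), which perform byte-range
  access; nothing remote is implemented here.
- Annotations are BED; convert GFF/GTF first, e.g.
  `awk '$3=="exon"' genes.gtf | gtf2bed` or via `gffutils`.
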