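"""Self-contained synthetic test inputs with ground truth.

The generator emits a random reference, coordinate-sorted paired spliced
reads as SAM text (CIGAR, MD, SEQ, TLEN and XS mutually consistent), and a
truth bundle: per-base depth for the all/unique passes, per-position
mismatch counts, per-fragment junction sets, and the drawn fragment
lengths.  Truth is computed from the generator's internal fragment
structures, *not* by parsing the SAM it writes, so the depth engine and the
naive counter below are both checked against independent bookkeeping.

One RNG stream per fixture, seeded from the config: every failing property
test is replayable from its seed.  Fidelity targets format and coordinate
correctness, not biology — quality strings are constant and there is no
sequencing-error model beyond uniform substitutions and short deletions.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .coverage import AlignmentInput, FilterConfig, parse_cigar

__all__ = [
    "FixtureConfig",
    "Truth",
    "Fixture",
    "generate",
    "write_fixture",
    "sam_to_bam",
    "brute_force_depth",
]

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small paired-end RNA-seq-like sample: two 100 kb
    chromosomes, 2000 fragments of ~320 bp genomic span, 100 bp reads, a
    quarter of fragments spliced over a 60-2000 bp intron, a low uniform
    substitution rate, occasional short deletions, a few percent PCR
    duplicates, and a MAPQ mix in which 20% of fragments fall below the
    default unique-pass threshold of 10.
    """

    seed: int = 0
    chroms: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000}
    )
    n_fragments: int = 2000
    read_length: int = 100
    fragment_length_distribution: tuple[float, float, int] = (320.0, 60.0, 160)
    splice_probability: float = 0.25
    intron_length_range: tuple[int, int] = (60, 2000)
    mismatch_rate: float = 0.002
    deletion_rate: float = 0.02
    duplicate_rate: float = 0.03
    mapq_distribution: tuple[tuple[int, float], ...] = (
        (60, 0.70),
        (30, 0.10),
        (3, 0.15),
        (0, 0.05),
    )

    def __post_init__(self) -> None:
        for name in ("splice_probability", "mismatch_rate", "deletion_rate", "duplicate_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        mean, sd, minimum = self.fragment_length_distribution
        if not self.read_length < minimum:
            raise ValueError(
                f"read_length={self.read_length} must be below the minimum "
                f"fragment length {minimum}"
            )
        if not self.chroms:
            raise ValueError("at least one chromosome is required")
        shortest = min(self.chroms.values())
        if minimum > shortest:
            raise ValueError(
                f"minimum fragment length {minimum} exceeds the shortest "
                f"chromosome ({shortest} bp); config is infeasible"
            )
        total_p = sum(p for _, p in self.mapq_distribution)
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError("mapq_distribution probabilities must sum to 1")


@dataclass
class Truth:
    """Ground truth computed alongside generation (default filter semantics)."""

    depth_all: dict[str, np.ndarray]
    depth_unique: dict[str, np.ndarray]
    mismatches: Counter  # (chrom, pos, ref, alt) -> count, duplicates excluded
    fragment_junctions: dict[str, tuple[tuple[str, int, int], ...]]
    fragment_lengths: list[int]  # |TLEN| per counted pair, duplicates included
    fragment_lengths_splice_adjusted: list[int]


@dataclass
class Fixture:
    config: FixtureConfig
    reference: dict[str, str]
    sam_text: str
    truth: Truth


def _mate_ops(
    w0: int, w1: int, start: int, introns: list[tuple[int, int]]
) -> tuple[int, list[list]]:
    """Map a cDNA window [w0, w1) onto the genome, splitting at each intron.

    ``introns`` holds (cDNA offset, genomic length) pairs, sorted by offset;
    an intron at offset o inserts its length into the genomic coordinate of
    every cDNA base at or beyond o.  Introns strictly inside the window
    become N operations; introns at or before the window only shift it.
    """
    g0 = start + w0 + sum(length for o, length in introns if o <= w0)
    ops: list[list] = []
    prev = w0
    for o, length in introns:
        if w0 < o < w1:
            ops.append([o - prev, "M"])
            ops.append([length, "N"])
            prev = o
    ops.append([w1 - prev, "M"])
    return g0, ops


def _ref_span(ops: Iterable[list]) -> int:
    return sum(n for n, op in ops if op in "MDN")


def _realize_mate(
    ref_arr: np.ndarray,
    g0: int,
    ops: list[list],
    rng: np.random.Generator,
    mismatch_rate: float,
) -> tuple[str, str, list[tuple[int, str, str]]]:
    """Produce SEQ, MD and the mismatch list for one mate's op structure."""
    pos_parts = []
    r = g0
    for n, op in ops:
        if op == "M":
            pos_parts.append(np.arange(r, r + n))
        if op in "MDN":
            r += n
    positions = np.concatenate(pos_parts)
    orig = ref_arr[positions]
    read = orig.copy()
    rl = len(read)
    hits = np.flatnonzero(rng.random(rl) < mismatch_rate) if mismatch_rate > 0 else []
    mism: list[tuple[int, str, str]] = []
    for h in hits:
        ref_b = bytes(orig[h])
        alt = _BASES[(_BASES.index(ref_b) + 1 + int(rng.integers(0, 3))) % 4]
        read[h] = np.frombuffer(alt, dtype="S1")[0]
        mism.append((int(positions[h]), ref_b.decode(), alt.decode()))

    hits_sorted = sorted(int(h) for h in hits)
    md_parts: list[str] = []
    run = 0
    qoff = 0
    r = g0
    for n, op in ops:
        if op == "M":
            in_op = [h for h in hits_sorted if qoff <= h < qoff + n]
            prev = qoff
            for h in in_op:
                run += h - prev
                md_parts.append(str(run))
                run = 0
                md_parts.append(bytes(orig[h]).decode())
                prev = h + 1
            run += qoff + n - prev
            qoff += n
            r += n
        elif op == "D":
            md_parts.append(str(run))
            run = 0
            md_parts.append("^" + ref_arr[r : r + n].tobytes().decode())
            r += n
        elif op == "N":
            r += n
    md_parts.append(str(run))
    return read.tobytes().decode(), "".join(md_parts), mism


def _gap_spans(g0: int, ops: list[list]) -> list[tuple[int, int]]:
    spans = []
    r = g0
    for n, op in ops:
        if op == "N":
            spans.append((r, r + n))
        if op in "MDN":
            r += n
    return spans


def _cigar_string(ops: list[list]) -> str:
    return "".join(f"{n}{op}" for n, op in ops)


def generate(config: FixtureConfig) -> Fixture:
    """Generate a reference, a coordinate-sorted SAM, and the truth bundle."""
    rng = np.random.default_rng(config.seed)
    cfg = config
    rl = cfg.read_length
    mean, sd, minimum = cfg.fragment_length_distribution
    default_filters = FilterConfig()

    chrom_names = list(cfg.chroms)
    chrom_lens = np.array([cfg.chroms[c] for c in chrom_names], dtype=np.float64)
    chrom_p = chrom_lens / chrom_lens.sum()
    mapq_vals = [q for q, _ in cfg.mapq_distribution]
    mapq_p = np.array([p for _, p in cfg.mapq_distribution])

    reference: dict[str, str] = {}
    ref_arrs: dict[str, np.ndarray] = {}
    letters = np.frombuffer(b"ACGT", dtype="S1")
    for c in chrom_names:
        arr = letters[rng.integers(0, 4, cfg.chroms[c])]
        ref_arrs[c] = arr
        reference[c] = arr.tobytes().decode()

    depth_all = {c: np.zeros(cfg.chroms[c], dtype=np.int64) for c in chrom_names}
    depth_unique = {c: np.zeros(cfg.chroms[c], dtype=np.int64) for c in chrom_names}
    mismatches: Counter = Counter()
    fragment_junctions: dict[str, tuple[tuple[str, int, int], ...]] = {}
    frag_lengths: list[int] = []
    frag_lengths_adj: list[int] = []

    records: list[tuple[int, int, str, str]] = []  # (chrom idx, pos, qname, SAM line)

    for i in range(cfg.n_fragments):
        ci = int(rng.choice(len(chrom_names), p=chrom_p))
        chrom = chrom_names[ci]
        clen = cfg.chroms[chrom]
        arr = ref_arrs[chrom]

        span_c = max(int(minimum), int(round(rng.normal(mean, sd))))
        span_c = min(span_c, clen)
        spliced = rng.random() < cfg.splice_probability and span_c >= 3
        introns: list[tuple[int, int]] = []
        if spliced:
            lo, hi = cfg.intron_length_range
            # one intron, or occasionally two so junction co-occurrence
            # within a fragment actually arises
            n_introns = 2 if rng.random() < 0.35 else 1
            offsets = sorted(
                int(x) + 1 for x in rng.choice(span_c - 1, size=n_introns, replace=False)
            )
            introns = [(o, int(rng.integers(lo, hi + 1))) for o in offsets]
            if span_c + sum(l for _, l in introns) > clen:
                introns = []
        genomic = span_c + sum(l for _, l in introns)
        start = int(rng.integers(0, clen - genomic + 1))
        ts_strand = "+" if rng.random() < 0.5 else "-"
        mapq = int(mapq_vals[int(rng.choice(len(mapq_vals), p=mapq_p))])

        mates = []
        for w0, w1 in ((0, rl), (span_c - rl, span_c)):
            g0, ops = _mate_ops(w0, w1, start, introns)
            if rng.random() < cfg.deletion_rate:
                m_idx = [k for k, (n, op) in enumerate(ops) if op == "M" and n >= 4]
                if m_idx:
                    k = m_idx[int(rng.integers(0, len(m_idx)))]
                    n = ops[k][0]
                    cut = int(rng.integers(1, n))
                    d = int(rng.integers(1, 4))
                    trial = ops[:k] + [[cut, "M"], [d, "D"], [n - cut, "M"]] + ops[k + 1 :]
                    if g0 + _ref_span(trial) <= clen:
                        ops = trial
            seq, md, mism = _realize_mate(arr, g0, ops, rng, cfg.mismatch_rate)
            mates.append((g0, ops, seq, md, mism))

        (g1, ops1, seq1, md1, mism1), (g2, ops2, seq2, md2, mism2) = mates
        end1, end2 = g1 + _ref_span(ops1), g2 + _ref_span(ops2)
        tlen = max(end1, end2) - g1  # mate 1 is leftmost by construction

        gaps = sorted(set(_gap_spans(g1, ops1)) | set(_gap_spans(g2, ops2)))
        gap_total = sum(e - s for s, e in gaps)

        qname = f"frag{i:06d}"
        is_dup = rng.random() < cfg.duplicate_rate
        names = [qname] + ([qname + "d"] if is_dup else [])

        for name_idx, name in enumerate(names):
            dup_flag = 0x400 if name_idx == 1 else 0
            for mate_idx, (g0, ops, seq, md, mism) in enumerate(mates):
                flags = (0x63 if mate_idx == 0 else 0x93) | dup_flag
                this_tlen = tlen if mate_idx == 0 else -tlen
                other_g0 = mates[1 - mate_idx][0]
                tags = [f"MD:Z:{md}"]
                if any(op == "N" for _, op in ops):
                    tags.append(f"XS:A:{ts_strand}")
                line = "\t".join(
                    [
                        name,
                        str(flags),
                        chrom,
                        str(g0 + 1),
                        str(mapq),
                        _cigar_string(ops),
                        "=",
                        str(other_g0 + 1),
                        str(this_tlen),
                        seq,
                        "I" * len(seq),
                    ]
                    + tags
                )
                records.append((ci, g0, name, line))

            # truth bookkeeping (per emitted pair)
            frag_lengths.append(tlen)
            frag_lengths_adj.append(tlen - gap_total)
            if gaps:
                fragment_junctions[name] = tuple((chrom, s, e) for s, e in gaps)
            if dup_flag == 0:
                # default filter excludes duplicates; both passes see this pair
                for g0, ops, _, _, mism in mates:
                    r = g0
                    for n, op in ops:
                        if op in "MD":  # deletions covered by default
                            depth_all[chrom][r : r + n] += 1
                            if mapq >= default_filters.min_mapq_unique:
                                depth_unique[chrom][r : r + n] += 1
                        if op in "MDN":
                            r += n
                    for pos, rb, ab in mism:
                        mismatches[(chrom, pos, rb, ab)] += 1

    records.sort(key=lambda t: (t[0], t[1], t[2]))
    header = ["@HD\tVN:1.6\tSO:coordinate"] + [
        f"@SQ\tSN:{c}\tLN:{cfg.chroms[c]}" for c in chrom_names
    ]
    sam_text = "\n".join(header + [line for *_, line in records]) + "\n"

    truth = Truth(
        depth_all=depth_all,
        depth_unique=depth_unique,
        mismatches=mismatches,
        fragment_junctions=fragment_junctions,
        fragment_lengths=frag_lengths,
        fragment_lengths_splice_adjusted=frag_lengths_adj,
    )
    return Fixture(config=cfg, reference=reference, sam_text=sam_text, truth=truth)


def write_fixture(fixture: Fixture, directory: str) -> dict[str, str]:
    """Write the reference FASTA and SAM to ``directory``; returns the paths."""
    os.makedirs(directory, exist_ok=True)
    fasta = os.path.join(directory, "ref.fa")
    sam = os.path.join(directory, "reads.sam")
    with open(fasta, "w") as fh:
        for chrom, seq in fixture.reference.items():
            fh.write(f">{chrom}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
    with open(sam, "w") as fh:
        fh.write(fixture.sam_text)
    return {"fasta": fasta, "sam": sam}


def sam_to_bam(sam_path: str, bam_path: str) -> str:
    """Convert a coordinate-sorted SAM to an indexed BAM via the standard I/O library."""
    import pysam

    with pysam.AlignmentFile(sam_path) as fin:
        with pysam.AlignmentFile(bam_path, "wb", template=fin) as fout:
            for r in fin:
                fout.write(r)
    pysam.index(bam_path)
    return bam_path


def brute_force_depth(
    records: Iterable[AlignmentInput],
    chroms: Mapping[str, int],
    filters: Optional[FilterConfig] = None,
    unique_pass: bool = False,
    count_deletions: bool = True,
) -> dict[str, np.ndarray]:
    """Per-base depth by directly incrementing every covered base.

    The deliberately naive oracle for the delta-array engine: no
    increment/decrement trick, no run-length encoding — walk each CIGAR and
    add one to each covered base.  Filtering is re-implemented inline so the
    oracle shares no depth-relevant code with the engine.
    """
    f = filters or FilterConfig()
    depth = {c: np.zeros(l, dtype=np.int64) for c, l in chroms.items()}
    for a in records:
        if a.flags & f.exclude_flags or a.flags & 0x4:
            continue
        if (a.flags & f.include_flags) != f.include_flags:
            continue
        if unique_pass and a.mapq < f.min_mapq_unique:
            continue
        if a.ref_name not in depth:
            continue
        d = depth[a.ref_name]
        r = a.pos
        for n, op in parse_cigar(a.cigar):
            if op in "M=X":
                d[max(r, 0) : r + n] += 1
                r += n
            elif op == "D":
                if count_deletions:
                    d[max(r, 0) : r + n] += 1
                r += n
            elif op == "N":
                r += n
    return depth
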