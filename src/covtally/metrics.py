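"""One-pass extraction of coverage-adjacent statistics from an RNA-seq BAM.

These extractors exist so an alignment file can be processed once and then
discarded: alternate-base coverage (a substrate for genotyping and
allele-specific expression), per-fragment splice-junction sets with a
co-occurrence flag (junctions seen in the same fragment came from the same
transcript), and the fragment-length distribution from TLEN.

Mismatches are recovered from the MD auxiliary tag by co-walking MD and
CIGAR; when MD is absent a reference FASTA can be supplied instead, and the
two mechanisms serve as each other's oracle in the test suite.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, NamedTuple, Optional, Union

from .coverage import (
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_READ2,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    FLAG_UNMAPPED,
    AlignmentInput,
    FilterConfig,
    cigar_reference_blocks,
    parse_cigar,
    passes_filters,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AltBaseRecord",
    "JunctionRecord",
    "FragmentJunctions",
    "FragmentStats",
    "MalformedRecordError",
    "mismatches_from_md",
    "mismatches_from_reference",
    "alt_base_coverage",
    "extract_junctions",
    "junction_cooccurrence",
    "fragment_lengths",
]


class MalformedRecordError(ValueError):
    """MD/CIGAR disagreement or similar per-record inconsistency; names the qname."""


class AltBaseRecord(NamedTuple):
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    count: int


class JunctionRecord(NamedTuple):
    """One intron (N-gap) observed in one alignment record."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '?' (no XS tag)
    qname: str
    mate_index: int  # 1 or 2


class FragmentJunctions(NamedTuple):
    """The union of junctions observed across both mates of one fragment."""

    qname: str
    chrom: str
    strand: str
    junctions: tuple[tuple[int, int], ...]
    cooccurring: bool  # >= 2 junctions in the same fragment


@dataclass
class FragmentStats:
    """Fragment-length histogram; each counted pair contributes exactly once."""

    histogram: Counter
    n_pairs: int


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _md_tokens(md: str, qname: str) -> list[Union[int, str]]:
    tokens: list[Union[int, str]] = []
    idx = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != idx:
            raise MalformedRecordError(f"{qname}: malformed MD tag {md!r}")
        if m.group(1) is not None:
            tokens.append(int(m.group(1)))
        else:
            tokens.append(m.group(0))
        idx = m.end()
    if idx != len(md):
        raise MalformedRecordError(f"{qname}: malformed MD tag {md!r}")
    return tokens


def mismatches_from_md(a: AlignmentInput) -> list[tuple[int, str, str]]:
    """Recover (reference position, ref base, read base) mismatches from MD.

    Co-walks CIGAR and MD: matched stretches advance both; an MD mismatch
    letter names the reference base while the read supplies the alternate;
    ``^``-deletions advance the reference only; insertions and soft clips
    advance the query only; N gaps advance the reference only (MD does not
    describe skipped introns).
    """
    md = a.tags.get("MD")
    if md is None:
        raise MalformedRecordError(f"{a.qname}: no MD tag")
    if a.seq == "*" or not a.seq:
        raise MalformedRecordError(f"{a.qname}: no sequence stored; cannot call mismatches")
    tokens = _md_tokens(md, a.qname)
    ti = 0  # token index
    match_left = 0  # unconsumed bases of the current numeric token
    out: list[tuple[int, str, str]] = []
    ref = a.pos
    q = 0

    def bad(why: str) -> MalformedRecordError:
        return MalformedRecordError(f"{a.qname}: MD {md!r} disagrees with CIGAR {a.cigar!r} ({why})")

    for n, op in parse_cigar(a.cigar):
        if op in "M=X":
            need = n
            while need:
                if match_left:
                    t = min(match_left, need)
                    ref += t
                    q += t
                    need -= t
                    match_left -= t
                    continue
                if ti >= len(tokens):
                    raise bad("MD exhausted inside a match op")
                tok = tokens[ti]
                ti += 1
                if isinstance(tok, int):
                    match_left = tok
                    continue
                if tok.startswith("^"):
                    raise bad("deletion token inside a match op")
                read_base = a.seq[q].upper()
                ref_base = tok.upper()
                if read_base != ref_base:
                    out.append((ref, ref_base, read_base))
                ref += 1
                q += 1
                need -= 1
        elif op in "IS":
            q += n
        elif op == "D":
            # skip a zero match count preceding the deletion token
            while match_left == 0 and ti < len(tokens) and tokens[ti] == 0:
                ti += 1
            if match_left:
                raise bad("match bases left at a deletion")
            if ti >= len(tokens) or not (
                isinstance(tokens[ti], str) and tokens[ti].startswith("^")
            ):
                raise bad("missing ^-deletion token")
            if len(tokens[ti]) - 1 != n:
                raise bad("deletion length mismatch")
            ti += 1
            ref += n
        elif op == "N":
            ref += n
        # H, P: nothing
    while ti < len(tokens) and tokens[ti] == 0:
        ti += 1
    if match_left or ti < len(tokens):
        raise bad("MD longer than the alignment")
    return out


RefFetch = Callable[[str, int, int], str]


def _as_fetcher(reference: Union[RefFetch, Mapping[str, str], str]) -> RefFetch:
    if callable(reference):
        return reference
    if isinstance(reference, str):
        import pyfaidx

        fa = pyfaidx.Fasta(reference)
        return lambda chrom, start, end: str(fa[chrom][start:end])
    if isinstance(reference, Mapping):
        return lambda chrom, start, end: reference[chrom][start:end]
    raise TypeError(f"cannot interpret reference of type {type(reference)!r}")


def mismatches_from_reference(
    a: AlignmentInput, reference: Union[RefFetch, Mapping[str, str], str]
) -> list[tuple[int, str, str]]:
    """Direct read-vs-reference mismatch calling (no MD tag needed).

    The independent counterpart of :func:`mismatches_from_md`; both must
    agree on any consistent record.
    """
    if a.seq == "*" or not a.seq:
        raise MalformedRecordError(f"{a.qname}: no sequence stored; cannot call mismatches")
    fetch = _as_fetcher(reference)
    out: list[tuple[int, str, str]] = []
    ref = a.pos
    q = 0
    for n, op in parse_cigar(a.cigar):
        if op in "M=X":
            ref_seq = fetch(a.ref_name, ref, ref + n).upper()
            if len(ref_seq) != n:
                raise MalformedRecordError(
                    f"{a.qname}: alignment runs off the end of reference {a.ref_name}"
                )
            for j in range(n):
                rb, qb = ref_seq[j], a.seq[q + j].upper()
                if rb != qb:
                    out.append((ref + j, rb, qb))
            ref += n
            q += n
        elif op in "IS":
            q += n
        elif op in "DN":
            ref += n
    return out


def alt_base_coverage(
    alignments: Iterable[AlignmentInput],
    reference: Optional[Union[RefFetch, Mapping[str, str], str]] = None,
    min_count: int = 1,
    filters: Optional[FilterConfig] = None,
) -> list[AltBaseRecord]:
    """Aggregate per-position alternate-base counts over passing alignments.

    Each record contributes its mismatches (from MD when present, else by
    comparison against ``reference``); counts are keyed by
    (chrom, pos, ref, alt) and reported when ``count >= min_count``, sorted
    by (chrom, pos, alt).
    """
    f = filters or FilterConfig()
    counts: Counter = Counter()
    for a in alignments:
        if not passes_filters(a, f, unique_pass=False):
            continue
        if "MD" in a.tags:
            mm = mismatches_from_md(a)
        elif reference is not None:
            mm = mismatches_from_reference(a, reference)
        else:
            raise ValueError(
                f"{a.qname}: no MD tag and no reference given; cannot call alternate bases"
            )
        for pos, rb, ab in mm:
            counts[(a.ref_name, pos, rb, ab)] += 1
    return [
        AltBaseRecord(chrom, pos, rb, ab, c)
        for (chrom, pos, rb, ab), c in sorted(counts.items())
        if c >= min_count
    ]


def extract_junctions(a: AlignmentInput) -> list[JunctionRecord]:
    """One record per N operation; strand from the XS tag when present."""
    if a.cigar == "*" or "N" not in a.cigar:
        return []
    gaps = cigar_reference_blocks(a.pos, a.cigar, count_deletions=True).junctions
    strand = a.tags.get("XS", "?")
    mate = 2 if a.flags & FLAG_READ2 else 1
    return [JunctionRecord(a.ref_name, s, e, strand, a.qname, mate) for s, e in gaps]


def junction_cooccurrence(
    alignments: Iterable[AlignmentInput],
) -> list[FragmentJunctions]:
    """Per-fragment junction sets from primary alignments, flagged for co-occurrence.

    Groups primary records by read name, takes the sorted union of both
    mates' junctions, and emits one record per fragment that has at least one
    junction.  Fragments with two or more junctions are flagged: their
    junctions were observed on the same sequenced molecule, hence the same
    transcript.  More than two primary records for a name is malformed
    pairing; the first two are kept with a warning.  Output is sorted by
    (chrom, first junction, qname).
    """
    frags: dict[tuple[str, str], list[AlignmentInput]] = {}
    for a in alignments:
        if a.flags & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            continue
        frags.setdefault((a.ref_name, a.qname), []).append(a)
    out: list[FragmentJunctions] = []
    for (chrom, qname), recs in frags.items():
        if len(recs) > 2:
            logger.warning(
                "%s: %d primary alignments on %s; keeping the first two",
                qname, len(recs), chrom,
            )
            recs = recs[:2]
        spans: set[tuple[int, int]] = set()
        strand = "?"
        for a in recs:
            for j in extract_junctions(a):
                spans.add((j.start, j.end))
                if j.strand != "?":
                    strand = j.strand
        if not spans:
            continue
        ordered = tuple(sorted(spans))
        out.append(FragmentJunctions(qname, chrom, strand, ordered, len(ordered) >= 2))
    out.sort(key=lambda fr: (fr.chrom, fr.junctions[0], fr.qname))
    return out


def _fragment_gap_lengths(recs: list[AlignmentInput]) -> int:
    spans: set[tuple[int, int]] = set()
    for a in recs:
        for j in extract_junctions(a):
            spans.add((j.start, j.end))
    return sum(e - s for s, e in spans)


def _counts_fragment(a: AlignmentInput, require_proper: bool) -> bool:
    if not a.flags & FLAG_PAIRED:
        return False
    if a.flags & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
        return False
    if require_proper and not a.flags & FLAG_PROPER_PAIR:
        return False
    return a.tlen > 0


def fragment_lengths(
    alignments: Iterable[AlignmentInput],
    require_proper: bool = True,
    splice_adjusted: bool = False,
) -> FragmentStats:
    """Histogram of template lengths, one count per pair.

    Each pair is counted from the mate carrying a positive TLEN (the
    leftmost), so record order is irrelevant and cross-chromosome or
    half-mapped pairs (TLEN 0) are skipped.  ``splice_adjusted`` subtracts
    the union of N-gap (intron) lengths observed in the fragment, turning a
    genomic span into a cDNA fragment length for spliced RNA-seq data.
    """
    hist: Counter = Counter()
    if not splice_adjusted:
        for a in alignments:
            if _counts_fragment(a, require_proper):
                hist[a.tlen] += 1
    else:
        counting: dict[tuple[str, str], int] = {}
        mates: dict[tuple[str, str], list[AlignmentInput]] = {}
        for a in alignments:
            if a.flags & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
                continue
            if not a.flags & FLAG_PAIRED:
                continue
            key = (a.ref_name, a.qname)
            mates.setdefault(key, []).append(a)
            if _counts_fragment(a, require_proper):
                counting[key] = a.tlen
        for key, tlen in counting.items():
            adj = tlen - _fragment_gap_lengths(mates[key])
            if adj > 0:
                hist[adj] += 1
            else:
                logger.warning("%s: splice-adjusted length %d <= 0; skipped", key[1], adj)
    return FragmentStats(histogram=hist, n_pairs=sum(hist.values()))
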