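"""Readers and writers for the standard containers.

SAM/BAM/CRAM record streams go through pysam, BigWig through pyBigWig; this
module only converts between those libraries' objects and the package's
domain types.  Remote URLs are passed straight through to the underlying
library, which handles byte-range access for indexed formats.

Text siblings (bedGraph, BED, chrom.sizes) are parsed here directly — they
are line-oriented TSV.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence, Union

import pyBigWig
import pysam

from .coverage import AlignmentInput, CoverageRun
from .intervals import QueryInterval, ValueRun

logger = logging.getLogger(__name__)

__all__ = [
    "ChromDict",
    "UnsortedInputError",
    "read_alignments",
    "alignment_chroms",
    "write_bigwig",
    "read_bigwig_runs",
    "bigwig_chroms",
    "format_value",
    "write_bedgraph",
    "read_bedgraph",
    "read_bed",
    "read_chrom_sizes",
    "is_bigwig",
]

#: Ordered chromosome name -> length mapping, in header order.
ChromDict = dict


class UnsortedInputError(ValueError):
    """The alignment file is not coordinate-sorted."""


def _to_alignment_input(r: pysam.AlignedSegment) -> AlignmentInput:
    tags = {}
    if r.has_tag("MD"):
        tags["MD"] = str(r.get_tag("MD"))
    if r.has_tag("XS"):
        tags["XS"] = str(r.get_tag("XS"))
    return AlignmentInput(
        qname=r.query_name or "",
        flags=r.flag,
        ref_name=r.reference_name or "*",
        pos=r.reference_start if r.reference_start is not None else -1,
        mapq=r.mapping_quality,
        cigar=r.cigarstring or "*",
        tlen=r.template_length,
        seq=r.query_sequence or "*",
        tags=tags,
    )


def _check_sorted_header(af: pysam.AlignmentFile, path: str) -> None:
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate":
        raise UnsortedInputError(
            f"{path}: header sort order is {so!r}, need coordinate-sorted input "
            "(sort with 'samtools sort' first)"
        )


def alignment_chroms(path: str, reference: Optional[str] = None) -> ChromDict:
    """Chromosome name -> length from an alignment file header, in header order."""
    with pysam.AlignmentFile(path, reference_filename=reference) as af:
        return dict(zip(af.references, af.lengths))


def read_alignments(
    path: str,
    region: Optional[QueryInterval] = None,
    reference: Optional[str] = None,
) -> tuple[ChromDict, Iterator[AlignmentInput]]:
    """Open a SAM/BAM/CRAM file (or URL) as a coordinate-ordered record stream.

    Returns the header's chromosome dictionary and a generator of records.
    A ``region`` restricts the stream to records overlapping it and requires
    an index; its absence raises an explicit error.  Coordinate order is
    verified while streaming, so a file with a lying header is refused too.
    """
    af = pysam.AlignmentFile(path, reference_filename=reference)
    _check_sorted_header(af, path)
    chroms = dict(zip(af.references, af.lengths))

    if region is not None:
        if not af.has_index():
            af.close()
            raise FileNotFoundError(
                f"{path}: region queries need an index (.bai/.crai/.csi); none found"
            )

    def gen() -> Iterator[AlignmentInput]:
        last: tuple[int, int] = (-1, -1)
        try:
            if region is not None:
                it: Iterable[pysam.AlignedSegment] = af.fetch(
                    region.chrom, region.start, region.end
                )
            else:
                it = af
            for r in it:
                if r.is_unmapped and r.reference_id < 0:
                    continue  # placed-unmapped-less records carry no coordinate
                key = (r.reference_id, r.reference_start)
                if region is None and key < last:
                    raise UnsortedInputError(
                        f"{path}: record {r.query_name} out of coordinate order "
                        "despite SO:coordinate header"
                    )
                last = key
                yield _to_alignment_input(r)
        finally:
            af.close()

    return chroms, gen()


def write_bigwig(
    runs: Union[Iterable[Union[ValueRun, CoverageRun]], Mapping[str, Sequence]],
    chroms: ChromDict,
    path: str,
) -> None:
    """Write value runs to a BigWig file.

    Runs must be sorted and disjoint per chromosome, with ends inside the
    chromosome; everything is validated before the first byte is written.
    Values are stored as 32-bit floats (the format's precision).
    """
    if isinstance(runs, Mapping):
        per_chrom: dict[str, list] = {c: list(rs) for c, rs in runs.items()}
    else:
        per_chrom = {}
        for r in runs:
            per_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in per_chrom.items():
        if chrom not in chroms:
            raise ValueError(f"run chromosome {chrom!r} missing from chromosome dictionary")
        length = chroms[chrom]
        prev_end = 0
        for r in rs:
            if not (0 <= r.start < r.end <= length):
                raise ValueError(
                    f"run {chrom}:{r.start}-{r.end} exceeds chromosome length {length}"
                )
            if r.start < prev_end:
                raise ValueError(f"runs on {chrom} are unsorted or overlapping at {r.start}")
            prev_end = r.end

    bw = pyBigWig.open(path, "w")
    try:
        bw.addHeader([(c, int(l)) for c, l in chroms.items()])
        for chrom in chroms:
            rs = per_chrom.get(chrom)
            if not rs:
                continue
            bw.addEntries(
                [chrom] * len(rs),
                [int(r.start) for r in rs],
                ends=[int(r.end) for r in rs],
                values=[float(r.value) for r in rs],
            )
    finally:
        bw.close()


def bigwig_chroms(path: str) -> ChromDict:
    bw = pyBigWig.open(path)
    try:
        return {c: int(l) for c, l in bw.chroms().items()}
    finally:
        bw.close()


def read_bigwig_runs(
    path: str, region: Optional[QueryInterval] = None
) -> tuple[ChromDict, Iterator[ValueRun]]:
    """Read a BigWig (or URL) back as value runs, per chromosome in file order."""
    bw = pyBigWig.open(path)
    chroms = {c: int(l) for c, l in bw.chroms().items()}
    if region is not None and region.chrom not in chroms:
        bw.close()
        raise ValueError(f"{path}: chromosome {region.chrom!r} not in BigWig")

    def gen() -> Iterator[ValueRun]:
        try:
            if region is not None:
                ivs = bw.intervals(region.chrom, region.start, region.end)
                for s, e, v in ivs or ():
                    yield ValueRun(region.chrom, int(s), int(e), float(v))
            else:
                for chrom in chroms:
                    for s, e, v in bw.intervals(chrom) or ():
                        yield ValueRun(chrom, int(s), int(e), float(v))
        finally:
            bw.close()

    return chroms, gen()


def format_value(v: float) -> str:
    """Integer rendering when integral, else the shortest round-trip decimal."""
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def write_bedgraph(runs: Iterable[Union[ValueRun, CoverageRun]], out: Union[str, IO[str]]) -> None:
    """Write runs as bedGraph text: chrom, start, end, value (0-based half-open)."""
    own = isinstance(out, str)
    fh = open(out, "w") if own else out
    try:
        for r in runs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{format_value(r.value)}\n")
    finally:
        if own:
            fh.close()


def read_bedgraph(path: str) -> Iterator[ValueRun]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            yield ValueRun(chrom, int(start), int(end), float(value))


def read_bed(path: str) -> list[QueryInterval]:
    """Read BED3/BED6 intervals (name from column 4, strand from column 6)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: BED needs at least 3 columns")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-." else None
            out.append(QueryInterval(cols[0], int(cols[1]), int(cols[2]), name, strand))
    return out


def read_chrom_sizes(path: str) -> ChromDict:
    """Read a UCSC chrom.sizes table (two-column TSV)."""
    chroms: ChromDict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            if name in chroms:
                raise ValueError(f"{path}: duplicate chromosome {name}")
            chroms[name] = int(length)
            if chroms[name] <= 0:
                raise ValueError(f"{path}: non-positive length for {name}")
    return chroms


_BIGWIG_MAGICS = {b"\x26\xfc\x8f\x88", b"\x88\x8f\xfc\x26"}


def is_bigwig(path: str) -> bool:
    """Detect BigWig input from its magic number (either endianness).

    URLs cannot be sniffed locally, so they fall back to the extension.
    """
    if "://" in path:
        return path.lower().endswith((".bw", ".bigwig"))
    with open(path, "rb") as fh:
        return fh.read(4) in _BIGWIG_MAGICS
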