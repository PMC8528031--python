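"""Single-pass driver: one input file in, all requested outputs out.

Alignment input is scanned exactly once; every requested alignment-derived
product (coverage, BigWig, AUC, interval summaries, alternate bases,
junctions, fragment lengths) is tallied during that same scan.  Work may be
split by chromosome across worker threads when the input is indexed;
results are always assembled in the header's chromosome order, so output
bytes are identical for any worker count.

BigWig input supports the coverage/summary/AUC subset — BigWigs store
coverage vectors, not alignments, so record-level extractors are rejected.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pysam

from . import formats, metrics
from .coverage import (
    DEFAULT_EXCLUDE_FLAGS,
    AlignmentInput,
    AucResult,
    CoverageRun,
    DeltaArray,
    DepthVector,
    FilterConfig,
    accumulate,
    auc,
    cigar_reference_blocks,
    depth_to_runs,
    finalize,
    passes_filters,
)
from .intervals import QueryInterval, ValueRun, summarize_intervals
from .metrics import FragmentStats

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "UsageError", "run", "ALIGNMENT_ONLY_OUTPUTS"]

#: outputs that require alignment records and are meaningless for BigWig input
ALIGNMENT_ONLY_OUTPUTS = frozenset({"alts", "junctions", "frag_dist"})
_ALL_OUTPUTS = frozenset(
    {"coverage", "bigwig", "annotation", "auc", "alts", "junctions", "frag_dist"}
)


class UsageError(ValueError):
    """Invalid option combination (maps to a non-zero CLI exit)."""


@dataclass
class RunConfig:
    """Everything one invocation needs.

    ``min_unique_qual`` switches on the second, MAPQ-thresholded "unique"
    coverage pass; both passes are tallied in the same scan.
    """

    input: str
    prefix: str
    outputs: set[str] = field(default_factory=lambda: {"coverage"})
    annotation: Optional[str] = None
    op: str = "both"
    min_unique_qual: Optional[int] = None
    include_flags: int = 0
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS
    count_deletions: bool = True
    emit_zero_runs: bool = False
    reference: Optional[str] = None
    min_alt_count: int = 1
    require_proper: bool = True
    splice_adjusted: bool = False
    threads: int = 1

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_mapq_unique=self.min_unique_qual if self.min_unique_qual is not None else 10,
            include_flags=self.include_flags,
            exclude_flags=self.exclude_flags,
            count_deletions=self.count_deletions,
        )


class _ChromTally:
    """Per-chromosome accumulator fed by a single pass over its records."""

    def __init__(self, chrom: str, length: int, cfg: RunConfig, filters: FilterConfig):
        self.chrom = chrom
        self.cfg = cfg
        self.filters = filters
        want = cfg.outputs
        need_cov = bool(want & {"coverage", "bigwig", "auc", "annotation"})
        self.delta_all = DeltaArray(chrom, length) if need_cov else None
        self.delta_unique = (
            DeltaArray(chrom, length)
            if need_cov and cfg.min_unique_qual is not None
            else None
        )
        self.alts: Counter = Counter()
        self.want_alts = "alts" in want
        self.ref_fetch = None
        if self.want_alts and cfg.reference is not None:
            self.ref_fetch = metrics._as_fetcher(cfg.reference)
        self.want_junctions = "junctions" in want
        self.jx_records: list[AlignmentInput] = []
        self.want_frags = "frag_dist" in want
        self.frag_records: list[AlignmentInput] = []  # splice-adjusted grouping only
        self.frag_hist: Counter = Counter()

    def add(self, a: AlignmentInput) -> None:
        cfg = self.cfg
        primary = not a.flags & (0x4 | 0x100 | 0x800)
        if self.want_junctions and primary and a.cigar != "*" and "N" in a.cigar:
            self.jx_records.append(a)
        if self.want_frags:
            if cfg.splice_adjusted:
                if primary and a.flags & 0x1:
                    self.frag_records.append(a)
            elif metrics._counts_fragment(a, cfg.require_proper):
                self.frag_hist[a.tlen] += 1
        if not passes_filters(a, self.filters, unique_pass=False):
            return
        if self.delta_all is not None or self.want_alts:
            if a.cigar == "*":
                return
        if self.delta_all is not None:
            blocks = cigar_reference_blocks(a.pos, a.cigar, self.filters.count_deletions)
            accumulate(self.delta_all, blocks)
            if self.delta_unique is not None and a.mapq >= self.filters.min_mapq_unique:
                accumulate(self.delta_unique, blocks)
        if self.want_alts:
            if "MD" in a.tags:
                mm = metrics.mismatches_from_md(a)
            elif self.ref_fetch is not None:
                mm = metrics.mismatches_from_reference(a, self.ref_fetch)
            else:
                raise UsageError(
                    f"{a.qname}: no MD tag and no --reference given; cannot call alternate bases"
                )
            for pos, rb, ab in mm:
                self.alts[(self.chrom, pos, rb, ab)] += 1

    def finish(self) -> "_ChromResult":
        res = _ChromResult(self.chrom)
        if self.delta_all is not None:
            res.depth_all = finalize(self.delta_all)
        if self.delta_unique is not None:
            res.depth_unique = finalize(self.delta_unique)
        res.alts = self.alts
        if self.want_junctions:
            res.fragments = metrics.junction_cooccurrence(self.jx_records)
        if self.want_frags:
            if self.cfg.splice_adjusted:
                res.frag_hist = metrics.fragment_lengths(
                    self.frag_records,
                    require_proper=self.cfg.require_proper,
                    splice_adjusted=True,
                ).histogram
            else:
                res.frag_hist = self.frag_hist
        return res


class _ChromResult:
    def __init__(self, chrom: str):
        self.chrom = chrom
        self.depth_all: Optional[DepthVector] = None
        self.depth_unique: Optional[DepthVector] = None
        self.alts: Counter = Counter()
        self.fragments: list = []
        self.frag_hist: Counter = Counter()


def _process_chrom_indexed(
    path: str, chrom: str, length: int, cfg: RunConfig, filters: FilterConfig
) -> _ChromResult:
    tally = _ChromTally(chrom, length, cfg, filters)
    with pysam.AlignmentFile(path, reference_filename=cfg.reference) as af:
        for r in af.fetch(chrom):
            tally.add(formats._to_alignment_input(r))
    return tally.finish()


def _scan_alignments(cfg: RunConfig) -> tuple[dict, list[_ChromResult]]:
    filters = cfg.filter_config()
    chroms = formats.alignment_chroms(cfg.input, reference=cfg.reference)

    use_threads = cfg.threads > 1
    if use_threads:
        try:
            with pysam.AlignmentFile(cfg.input, reference_filename=cfg.reference) as af:
                use_threads = af.has_index()
        except (OSError, ValueError):
            use_threads = False
        if not use_threads:
            logger.warning("no index for %s; falling back to a sequential scan", cfg.input)

    if use_threads:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            futures = {
                chrom: pool.submit(
                    _process_chrom_indexed, cfg.input, chrom, length, cfg, filters
                )
                for chrom, length in chroms.items()
            }
            results = [futures[c].result() for c in chroms]
        return chroms, results

    _, stream = formats.read_alignments(cfg.input, reference=cfg.reference)
    tallies: dict[str, _ChromTally] = {}
    for a in stream:
        t = tallies.get(a.ref_name)
        if t is None:
            if a.ref_name not in chroms:
                logger.warning("record %s on unknown chromosome %s; skipped", a.qname, a.ref_name)
                continue
            t = tallies[a.ref_name] = _ChromTally(a.ref_name, chroms[a.ref_name], cfg, filters)
        t.add(a)
    results = []
    for chrom, length in chroms.items():
        t = tallies.get(chrom) or _ChromTally(chrom, length, cfg, filters)
        results.append(t.finish())
    return chroms, results


def _runs_for(results: list[_ChromResult], which: str, emit_zero: bool) -> list[CoverageRun]:
    runs: list[CoverageRun] = []
    for res in results:
        d = getattr(res, which)
        if d is not None:
            runs.extend(depth_to_runs(d, emit_zero_runs=emit_zero))
    return runs


def _write_auc(path: str, result: AucResult) -> None:
    with open(path, "w") as fh:
        fh.write(f"total\t{formats.format_value(result.total_auc)}\n")
        fh.write(f"annotated\t{formats.format_value(result.annotated_auc)}\n")
        fh.write(f"unannotated\t{formats.format_value(result.unannotated_auc)}\n")


def _write_annotation(
    path: str,
    queries: list[QueryInterval],
    summaries,
    op: str,
) -> None:
    with open(path, "w") as fh:
        for q, s in zip(queries, summaries):
            cols = [q.chrom, str(q.start), str(q.end)]
            if q.name is not None or q.strand is not None:
                cols.append(q.name if q.name is not None else ".")
            if q.strand is not None:
                cols.extend([".", q.strand])
            if op in ("sum", "both"):
                cols.append(formats.format_value(s.sum))
            if op in ("mean", "both"):
                cols.append(repr(float(s.mean)))
            fh.write("\t".join(cols) + "\n")


def _write_alts(path: str, alts: Counter, min_count: int) -> None:
    with open(path, "w") as fh:
        for (chrom, pos, rb, ab), c in sorted(alts.items()):
            if c >= min_count:
                fh.write(f"{chrom}\t{pos}\t{rb}\t{ab}\t{c}\n")


def _write_junctions(path: str, fragments: Iterable) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            span_list = ",".join(f"{s}-{e}" for s, e in fr.junctions)
            fh.write(
                f"{fr.qname}\t{fr.chrom}\t{fr.strand}\t{len(fr.junctions)}\t"
                f"{span_list}\t{1 if fr.cooccurring else 0}\n"
            )


def _write_frag_dist(path: str, hist: Counter) -> None:
    with open(path, "w") as fh:
        for length in sorted(hist):
            fh.write(f"{length}\t{hist[length]}\n")


def _validate(cfg: RunConfig) -> None:
    unknown = cfg.outputs - _ALL_OUTPUTS
    if unknown:
        raise UsageError(f"unknown outputs requested: {sorted(unknown)}")
    if not cfg.outputs:
        raise UsageError("no outputs requested")
    if "annotation" in cfg.outputs and cfg.annotation is None:
        raise UsageError("interval summaries requested but no annotation BED given")
    if not os.path.exists(cfg.input) and "://" not in cfg.input:
        raise FileNotFoundError(f"input {cfg.input!r} does not exist")


def run(cfg: RunConfig) -> dict[str, str]:
    """Execute one invocation; returns {output name: written path}."""
    _validate(cfg)
    bigwig_input = formats.is_bigwig(cfg.input)
    if bigwig_input:
        forbidden = cfg.outputs & ALIGNMENT_ONLY_OUTPUTS
        if forbidden:
            raise UsageError(
                f"{sorted(forbidden)} need alignment input; BigWig files store "
                "coverage vectors, not alignments"
            )
    queries = formats.read_bed(cfg.annotation) if cfg.annotation is not None else None
    written: dict[str, str] = {}

    if bigwig_input:
        chroms, run_iter = formats.read_bigwig_runs(cfg.input)
        runs = list(run_iter)
        unique_runs = None
    else:
        chroms, results = _scan_alignments(cfg)
        runs = _runs_for(results, "depth_all", cfg.emit_zero_runs)
        unique_runs = (
            _runs_for(results, "depth_unique", cfg.emit_zero_runs)
            if cfg.min_unique_qual is not None
            else None
        )

    def emit(name: str, suffix: str, writer) -> None:
        path = f"{cfg.prefix}.{suffix}"
        writer(path)
        written[name] = path
        logger.info("wrote %s", path)

    for label, pass_runs in (("", runs), ("unique.", unique_runs)):
        if pass_runs is None:
            continue
        if "coverage" in cfg.outputs:
            emit(
                f"{label}coverage",
                f"{label}coverage.bedgraph",
                lambda p, r=pass_runs: formats.write_bedgraph(r, p),
            )
        if "bigwig" in cfg.outputs:
            nz = [r for r in pass_runs if r.value != 0]
            emit(
                f"{label}bigwig",
                f"{label}coverage.bw",
                lambda p, r=nz: formats.write_bigwig(r, chroms, p),
            )
        if "auc" in cfg.outputs or ("annotation" in cfg.outputs and queries is not None):
            ann = None
            if queries is not None:
                from .intervals import disjoin

                ann = [(q.chrom, q.start, q.end) for q in disjoin(queries)]
            if "auc" in cfg.outputs:
                result = auc((r for r in pass_runs if r.value != 0), ann)
                emit(f"{label}auc", f"{label}auc.tsv", lambda p, r=result: _write_auc(p, r))
        if "annotation" in cfg.outputs and queries is not None:
            vruns = [ValueRun(*r) for r in pass_runs]
            summaries = summarize_intervals(vruns, queries, op=cfg.op, chroms=chroms)
            emit(
                f"{label}annotation",
                f"{label}annotation.tsv",
                lambda p, s=summaries: _write_annotation(p, queries, s, cfg.op),
            )

    if not bigwig_input:
        if "alts" in cfg.outputs:
            alts: Counter = Counter()
            for res in results:
                alts.update(res.alts)
            emit("alts", "alts.tsv", lambda p: _write_alts(p, alts, cfg.min_alt_count))
        if "junctions" in cfg.outputs:
            frags = [fr for res in results for fr in res.fragments]
            emit("junctions", "jxs.tsv", lambda p: _write_junctions(p, frags))
        if "frag_dist" in cfg.outputs:
            hist: Counter = Counter()
            for res in results:
                hist.update(res.frag_hist)
            emit("frag_dist", "frags.tsv", lambda p: _write_frag_dist(p, hist))

    return written
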