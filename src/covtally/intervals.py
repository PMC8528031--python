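"""Summarize coverage over query intervals, and flatten annotations.

Two coverage sources feed the same summarizer: per-base depth vectors from
alignment input (viewed as value runs) and value runs read from a BigWig.
Sums are overlap-length weighted; bases with no run under them count as
coverage 0, *not* as missing — these are coverage semantics, not
signal-averaging semantics, and BigWig tools differ on this point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np

from .coverage import CoverageRun, DepthVector, depth_to_runs

logger = logging.getLogger(__name__)

__all__ = [
    "QueryInterval",
    "ValueRun",
    "IntervalSummary",
    "summarize_intervals",
    "disjoin",
    "depth_source_as_runs",
]


class QueryInterval(NamedTuple):
    """A BED-style query interval (0-based half-open), name and strand optional."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None


class ValueRun(NamedTuple):
    """A constant-value coverage run (chrom, start, end, value)."""

    chrom: str
    start: int
    end: int
    value: float


@dataclass
class IntervalSummary:
    interval: QueryInterval
    sum: float
    mean: float


def summarize_intervals(
    source: Iterable[ValueRun | CoverageRun],
    queries: list[QueryInterval],
    op: str = "both",
    chroms: Optional[Mapping[str, int]] = None,
) -> list[IntervalSummary]:
    """Overlap-weighted coverage sum and mean for each query interval.

    Parameters
    ----------
    source
        Value runs, sorted and non-overlapping per chromosome (gaps allowed;
        a gap is coverage 0).
    queries
        Query intervals, any order, may overlap each other.  Output order
        matches input order.
    op
        ``sum``, ``mean`` or ``both`` — which statistic the caller intends to
        keep; both are always computed (mean needs the sum anyway).
    chroms
        Optional chromosome lengths of the source.  When given, queries are
        clamped to chromosome bounds and the mean denominator is the clamped
        length (logged when clamping changes a query).

    Queries on a chromosome absent from the source get sum = mean = 0 with a
    logged warning; annotations routinely include contigs a sample lacks.
    """
    if op not in ("sum", "mean", "both"):
        raise ValueError(f"op must be one of sum/mean/both, got {op!r}")

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    acc: dict[str, list[ValueRun]] = {}
    for r in source:
        acc.setdefault(r.chrom, []).append(r)
    for chrom, rs in acc.items():
        starts[chrom] = np.fromiter((r.start for r in rs), dtype=np.int64, count=len(rs))
        ends[chrom] = np.fromiter((r.end for r in rs), dtype=np.int64, count=len(rs))
        values[chrom] = np.fromiter((r.value for r in rs), dtype=np.float64, count=len(rs))
        if np.any(starts[chrom][1:] < ends[chrom][:-1]):
            raise ValueError(f"source runs on {chrom} are unsorted or overlapping")

    warned_missing: set[str] = set()
    out: list[IntervalSummary] = []
    for q in queries:
        if q.chrom not in starts:
            if chroms is None or q.chrom not in chroms:
                if q.chrom not in warned_missing:
                    logger.warning("query chromosome %s absent from source; sum=mean=0", q.chrom)
                    warned_missing.add(q.chrom)
                out.append(IntervalSummary(q, 0.0, 0.0))
                continue
        qs, qe = q.start, q.end
        if chroms is not None and q.chrom in chroms:
            cs, ce = max(qs, 0), min(qe, chroms[q.chrom])
            if (cs, ce) != (qs, qe):
                logger.warning(
                    "query %s:%d-%d clamped to chromosome bounds [0,%d)",
                    q.chrom, qs, qe, chroms[q.chrom],
                )
            qs, qe = cs, ce
        length = qe - qs
        if length <= 0 or q.chrom not in starts:
            out.append(IntervalSummary(q, 0.0, 0.0))
            continue
        s_arr, e_arr, v_arr = starts[q.chrom], ends[q.chrom], values[q.chrom]
        i0 = int(np.searchsorted(e_arr, qs, side="right"))
        i1 = int(np.searchsorted(s_arr, qe, side="left"))
        if i1 <= i0:
            total = 0.0
        else:
            ov = np.minimum(e_arr[i0:i1], qe) - np.maximum(s_arr[i0:i1], qs)
            np.clip(ov, 0, None, out=ov)
            total = float(ov @ v_arr[i0:i1])
        out.append(IntervalSummary(q, total, total / length))
    return out


def disjoin(intervals: Iterable[QueryInterval]) -> list[QueryInterval]:
    """Cut a set of intervals at every breakpoint into disjoint pieces.

    The union of the inputs is partitioned at every distinct start/end
    coordinate; each output piece carries the semicolon-joined names of all
    inputs covering it (in input order).  The operation is idempotent and
    preserves the union of covered bases.  This is the "flattened annotation"
    used when quantifying a gene annotation without double counting bases
    shared between overlapping transcripts.
    """
    by_chrom: dict[str, list[tuple[int, int, int, Optional[str]]]] = {}
    for idx, iv in enumerate(intervals):
        if iv.start >= iv.end:
            raise ValueError(f"interval {iv} is empty or inverted")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx, iv.name))

    out: list[QueryInterval] = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        points = sorted({p for s, e, _, _ in ivs for p in (s, e)})
        ivs_sorted = sorted(ivs)  # by start, then end, then input index
        end_of = {idx: e for _, e, idx, _ in ivs}
        name_of = {idx: name for _, _, idx, name in ivs}
        active: set[int] = set()
        k = 0
        for a, b in zip(points, points[1:]):
            while k < len(ivs_sorted) and ivs_sorted[k][0] <= a:
                active.add(ivs_sorted[k][2])
                k += 1
            active = {i for i in active if end_of[i] > a}
            if not active:
                continue
            names = [name_of[i] for i in sorted(active)]
            label = (
                ";".join(n if n is not None else "" for n in names)
                if any(n is not None for n in names)
                else None
            )
            out.append(QueryInterval(chrom, a, b, label))
    return out


def depth_source_as_runs(d: DepthVector) -> list[ValueRun]:
    """Lossless zero-including run view of a depth vector."""
    return [
        ValueRun(r.chrom, r.start, r.end, r.value)
        for r in depth_to_runs(d, emit_zero_runs=True)
    ]
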