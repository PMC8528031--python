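"""Alternate-base, junction and fragment-length extractors against their oracles."""

from collections import Counter

import pytest

import covtally as ct
from covtally.coverage import AlignmentInput
from covtally.metrics import (
    MalformedRecordError,
    alt_base_coverage,
    extract_junctions,
    fragment_lengths,
    junction_cooccurrence,
    mismatches_from_md,
    mismatches_from_reference,
)


def _aln(qname="r", flags=0, chrom="c", pos=100, cigar="10M", seq="A" * 10, md=None, xs=None,
         mapq=60, tlen=0):
    tags = {}
    if md is not None:
        tags["MD"] = md
    if xs is not None:
        tags["XS"] = xs
    return AlignmentInput(qname, flags, chrom, pos, mapq, cigar, tlen, seq, tags)


class TestMismatchesFromMD:
    def test_single_substitution(self):
        a = _aln(cigar="10M", md="5A4", seq="CCCCCGCCCC")
        assert mismatches_from_md(a) == [(105, "A", "G")]

    def test_perfect_match(self):
        assert mismatches_from_md(_aln(md="10")) == []

    def test_deletion_advances_reference_only(self):
        # 5M 2D 5M with a mismatch two bases into the second block:
        # read offset 7 maps to reference 100+5(del +2)+2 = 109
        a = _aln(cigar="5M2D5M", md="5^AC2T2", seq="GGGGGGGGGG")
        assert mismatches_from_md(a) == [(109, "T", "G")]

    def test_soft_clip_and_insertion_advance_query_only(self):
        # aligned offset 3 (4th M base) sits at ref 103 but query offset 5
        a = _aln(cigar="2S4M2I4M", md="3C4", seq="NNAAAGTTCCCC")
        assert mismatches_from_md(a) == [(103, "C", "G")]

    def test_n_gap_advances_reference_only(self):
        a = _aln(cigar="5M100N5M", md="6A3", seq="AAAAAAGAAA"[:10])
        # mismatch is at the 7th aligned base: ref 100+5(+100 intron)+1 = 206
        assert mismatches_from_md(a) == [(206, "A", "G")]

    def test_md_cigar_disagreement_names_qname(self):
        a = _aln(qname="badrec", cigar="10M", md="5A10", seq="C" * 10)
        with pytest.raises(MalformedRecordError, match="badrec"):
            mismatches_from_md(a)

    def test_missing_seq_rejected(self):
        with pytest.raises(MalformedRecordError):
            mismatches_from_md(_aln(md="10", seq="*"))


class TestMismatchesFromReference:
    REF = {"c": "A" * 300}

    def test_agrees_with_md_on_fixture_reads(self, fixture_bundle, fixture_records):
        _, recs = fixture_records
        ref = fixture_bundle.reference
        for a in recs[:400]:
            assert mismatches_from_md(a) == mismatches_from_reference(a, ref)

    def test_direct_call(self):
        a = _aln(cigar="10M", seq="AAAAAGAAAA")
        assert mismatches_from_reference(a, self.REF) == [(105, "A", "G")]


class TestAltBaseCoverage:
    def test_aggregation_and_min_count(self):
        reads = [
            _aln(qname="r1", cigar="10M", md="5A4", seq="CCCCCGCCCC"),
            _aln(qname="r2", cigar="10M", md="5A4", seq="CCCCCGCCCC"),
        ]
        (rec,) = alt_base_coverage(reads, min_count=1)
        assert rec == ("c", 105, "A", "G", 2)
        assert alt_base_coverage(reads, min_count=3) == []

    def test_no_md_no_reference_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            alt_base_coverage([_aln(seq="C" * 10)])

    def test_fixture_counts_equal_generator_truth(self, fixture_bundle, fixture_records):
        _, recs = fixture_records
        got = Counter(
            {(r.chrom, r.pos, r.ref_base, r.alt_base): r.count
             for r in alt_base_coverage(recs)}
        )
        assert got == fixture_bundle.truth.mismatches


class TestJunctions:
    def test_single_intron_with_strand(self):
        a = _aln(cigar="10M5N10M", seq="A" * 20, xs="+")
        (j,) = extract_junctions(a)
        assert (j.start, j.end, j.strand) == (110, 115, "+")

    def test_unspliced_read_has_none(self):
        assert extract_junctions(_aln(cigar="20M", seq="A" * 20)) == []

    def test_two_introns(self):
        a = _aln(pos=100, cigar="5M10N5M20N5M", seq="A" * 15)
        js = extract_junctions(a)
        assert [(j.start, j.end) for j in js] == [(105, 115), (120, 140)]
        assert all(j.strand == "?" for j in js)

    def test_mate_union_and_cooccurrence(self):
        m1 = _aln(qname="f", flags=0x40 | 0x1, cigar="5M10N5M", seq="A" * 10, xs="+")
        m2 = _aln(qname="f", flags=0x80 | 0x1, pos=200, cigar="5M30N5M", seq="A" * 10, xs="+")
        (fr,) = junction_cooccurrence([m1, m2])
        assert fr.junctions == ((105, 115), (205, 235))
        assert fr.cooccurring and fr.strand == "+"

    def test_junction_free_fragments_emit_nothing(self):
        m1 = _aln(qname="f", flags=0x40, cigar="10M", seq="A" * 10)
        m2 = _aln(qname="f", flags=0x80, pos=200, cigar="10M", seq="A" * 10)
        assert junction_cooccurrence([m1, m2]) == []

    def test_secondary_and_supplementary_ignored(self):
        sec = _aln(qname="f", flags=0x100, cigar="5M10N5M", seq="A" * 10)
        assert junction_cooccurrence([sec]) == []

    def test_more_than_two_primaries_warns_keeps_two(self, caplog):
        recs = [
            _aln(qname="f", flags=0x40, cigar="5M10N5M", seq="A" * 10),
            _aln(qname="f", flags=0x80, cigar="5M10N5M", seq="A" * 10),
            _aln(qname="f", flags=0x80, pos=400, cigar="5M99N5M", seq="A" * 10),
        ]
        with caplog.at_level("WARNING"):
            (fr,) = junction_cooccurrence(recs)
        assert "keeping the first two" in caplog.text
        assert fr.junctions == ((105, 115),)

    def test_invariant_under_record_order(self, fixture_records):
        _, recs = fixture_records
        primaries = [a for a in recs if not a.flags & 0x904]
        fwd = junction_cooccurrence(primaries)
        rev = junction_cooccurrence(primaries[::-1])
        assert fwd == rev

    def test_fixture_sets_equal_generator_truth(self, fixture_bundle, fixture_records):
        _, recs = fixture_records
        frs = junction_cooccurrence(recs)
        got = {fr.qname: tuple((fr.chrom, s, e) for s, e in fr.junctions) for fr in frs}
        assert got == fixture_bundle.truth.fragment_junctions


class TestFragmentLengths:
    def test_one_proper_pair(self):
        m1 = _aln(qname="f", flags=0x1 | 0x2 | 0x40, tlen=300)
        m2 = _aln(qname="f", flags=0x1 | 0x2 | 0x80, tlen=-300)
        fs = fragment_lengths([m1, m2])
        assert fs.histogram == Counter({300: 1}) and fs.n_pairs == 1

    def test_unpaired_reads_empty(self):
        fs = fragment_lengths([_aln(flags=0x0, tlen=500)])
        assert fs.histogram == Counter() and fs.n_pairs == 0

    def test_improper_pairs_gated_by_flag(self):
        m1 = _aln(qname="f", flags=0x1 | 0x40, tlen=250)
        assert fragment_lengths([m1]).n_pairs == 0
        assert fragment_lengths([m1], require_proper=False).histogram == Counter({250: 1})

    def test_order_invariance_and_single_count(self, fixture_records):
        _, recs = fixture_records
        fwd = fragment_lengths(recs)
        rev = fragment_lengths(recs[::-1])
        assert fwd.histogram == rev.histogram

    def test_fixture_histogram_equals_drawn_lengths(self, fixture_bundle, fixture_records):
        _, recs = fixture_records
        fs = fragment_lengths(recs)
        assert fs.histogram == Counter(fixture_bundle.truth.fragment_lengths)

    def test_splice_adjusted_matches_truth(self, fixture_bundle, fixture_records):
        _, recs = fixture_records
        fs = fragment_lengths(recs, splice_adjusted=True)
        assert fs.histogram == Counter(
            fixture_bundle.truth.fragment_lengths_splice_adjusted
        )
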