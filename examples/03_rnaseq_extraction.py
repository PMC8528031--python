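"""One-pass RNA-seq extraction: alternate bases, junctions, fragment lengths.

These are the summaries worth keeping when the BAM itself will be deleted:
candidate variant positions, which splice junctions co-occur on one
fragment (hence one transcript), and the insert-size distribution.
"""

import tempfile
from collections import Counter

import covtally as ct
from covtally.simulate import FixtureConfig, generate, write_fixture

fx = generate(FixtureConfig(seed=7, n_fragments=1_000, splice_probability=0.5,
                            mismatch_rate=0.01))
with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture(fx, tmp)
    chroms, records = ct.read_alignments(paths["sam"])
    recs = list(records)

alts = ct.alt_base_coverage(recs, min_count=2)
print(f"alternate-base positions seen in >= 2 reads: {len(alts)}")
for r in alts[:3]:
    print(f"  {r.chrom}:{r.pos} {r.ref_base}>{r.alt_base} x{r.count}")

frags = ct.junction_cooccurrence(recs)
co = [fr for fr in frags if fr.cooccurring]
print(f"fragments with junctions: {len(frags)}; with co-occurring junctions: {len(co)}")
if co:
    fr = co[0]
    spans = ", ".join(f"{s}-{e}" for s, e in fr.junctions)
    print(f"  e.g. {fr.qname} on {fr.chrom} ({fr.strand}): {spans}")

fs = ct.fragment_lengths(recs)
mean_len = sum(l * c for l, c in fs.histogram.items()) / fs.n_pairs
print(f"fragment pairs counted: {fs.n_pairs}; mean |TLEN| = {mean_len:.1f}")
# Junctions listed on one line came from the same sequenced fragment, direct
# evidence they belong to the same transcript isoform. A position recurrently
# showing the same alternate base is a genotyping/ASE candidate.
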