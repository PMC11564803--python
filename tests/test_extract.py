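"""Read-pair consensus, the filter stack, aggregation and VCF round trips."""

import numpy as np
import pytest

from mmfinder.extract import (
    aggregate_support,
    anchor_indel,
    apply_fragment_filters,
    consensus_merge,
    extract_mismatches,
    filter_germline,
    left_align_indel,
    read_vcf,
    write_vcf,
)
from mmfinder.records import (
    DEL,
    INS,
    SBS,
    FilterConfig,
    FragmentRecord,
    GenomicIntervals,
    GermlineStore,
    Mismatch,
    ReadRecord,
)


def mk_mismatch(pos, ref="C", alt="T", bq=30, **kw):
    return Mismatch(chrom="chr1", pos=pos, ref=ref, alt=alt, klass=SBS,
                    bq=bq, read_quals=(bq,), **kw)


def mk_read(start, length=10, seq=None, quals=None):
    seq = seq or "A" * length
    return ReadRecord(chrom="chr1", start=start, cigar=f"{length}M",
                      md=str(length), seq=seq,
                      quals=bytes(quals or [30] * length))


class TestConsensus:
    def test_agreeing_mates_sum_qualities(self):
        e1 = [mk_mismatch(5, bq=30)]
        e2 = [mk_mismatch(5, bq=35)]
        (m,) = consensus_merge(e1, e2, (0, 20))
        assert m.bq == 65
        assert m.in_overlap
        assert m.read_quals == (30, 35)

    def test_disagreeing_mates_keep_higher_base_with_penalty(self):
        e1 = [mk_mismatch(5, alt="A", bq=40)]
        e2 = [mk_mismatch(5, alt="C", bq=20)]
        (m,) = consensus_merge(e1, e2, (0, 20))
        assert (m.alt, m.bq) == ("A", 30)  # 40 - 20/2

    def test_strict_overlap_drops_disagreements(self):
        e1 = [mk_mismatch(5, alt="A", bq=40)]
        e2 = [mk_mismatch(5, alt="C", bq=20)]
        assert consensus_merge(e1, e2, (0, 20), strict_overlap=True) == []

    def test_lone_mate_mismatch_against_reference_quality(self):
        # other mate reads the reference at the site: higher-quality
        # mismatch survives with a penalty, lower-quality one is vetoed
        r2 = mk_read(0, 20, quals=[20] * 20)
        e1 = [mk_mismatch(5, bq=41)]
        (m,) = consensus_merge(e1, [], (0, 20), read2=r2)
        assert m.bq == 41 - 10
        r2_hi = mk_read(0, 20, quals=[41] * 20)
        assert consensus_merge([mk_mismatch(5, bq=30)], [], (0, 20),
                               read2=r2_hi) == []

    def test_outside_overlap_passthrough_and_only_overlap(self):
        e1 = [mk_mismatch(50, bq=30)]
        (m,) = consensus_merge(e1, [], (0, 20))
        assert not m.in_overlap and m.bq == 30
        assert consensus_merge(e1, [], (0, 20), only_overlap=True) == []

    def test_no_mismatch_created_from_nothing(self):
        assert consensus_merge([], [], (0, 50), strict_overlap=False) == []

    def test_equal_quality_tie_keeps_first_mate_base(self):
        e1 = [mk_mismatch(5, alt="A", bq=30)]
        e2 = [mk_mismatch(5, alt="G", bq=30)]
        (m,) = consensus_merge(e1, e2, (0, 20))
        assert m.alt == "A" and m.bq == 15


class TestFragmentFilters:
    def frag(self, **kw):
        return FragmentRecord(name="f", r1=mk_read(0, 100),
                              r2=mk_read(66, 100), tlen=kw.pop("tlen", 166))

    def test_too_many_mismatches_rejects_whole_fragment(self):
        cfg = FilterConfig(min_bq=0, min_avg_bq=0)
        mms = [mk_mismatch(i + 1) for i in range(16)]
        kept, reason = apply_fragment_filters(
            self.frag(), mms, cfg, per_read_counts=(16, 0))
        assert kept == [] and reason == "mismatch_count_per_read"
        kept, reason = apply_fragment_filters(
            self.frag(), mms[:15], cfg, per_read_counts=(15, 0))
        assert reason is None and len(kept) == 15

    def test_fragment_size_window(self):
        cfg = FilterConfig(min_bq=0, min_avg_bq=0,
                           fragment_windows=[(100, 150)])
        kept, reason = apply_fragment_filters(
            self.frag(), [mk_mismatch(5)], cfg)
        assert reason == "fragment_size"

    def test_combined_bq_threshold_is_inclusive(self):
        cfg = FilterConfig(min_avg_bq=0)
        frag = self.frag()
        kept, _ = apply_fragment_filters(frag, [mk_mismatch(5, bq=64)], cfg)
        assert kept == []
        kept, _ = apply_fragment_filters(frag, [mk_mismatch(5, bq=65)], cfg)
        assert len(kept) == 1

    def test_duplicate_and_mapq_rejection(self):
        frag = self.frag()
        frag.r1.is_duplicate = True
        _, reason = apply_fragment_filters(frag, [], FilterConfig())
        assert reason == "duplicate_or_secondary"
        frag = self.frag()
        frag.r2.mapq = 5
        _, reason = apply_fragment_filters(frag, [], FilterConfig())
        assert reason == "mapping_quality"

    def test_whitelist_and_blacklist(self):
        wl = GenomicIntervals([("chr1", 0, 10)])
        cfg = FilterConfig(min_bq=0, min_avg_bq=0, whitelist=wl)
        kept, _ = apply_fragment_filters(
            self.frag(), [mk_mismatch(5), mk_mismatch(50)], cfg)
        assert [m.pos for m in kept] == [5]
        cfg = FilterConfig(min_bq=0, min_avg_bq=0, blacklist=wl)
        kept, _ = apply_fragment_filters(
            self.frag(), [mk_mismatch(5), mk_mismatch(50)], cfg)
        assert [m.pos for m in kept] == [50]


class TestGermline:
    def test_empty_store_is_identity(self):
        mms = [mk_mismatch(5), mk_mismatch(9)]
        assert filter_germline(mms, GermlineStore()) == mms
        assert filter_germline(mms, None) == mms

    def test_set_difference_and_order(self):
        mms = [mk_mismatch(5), mk_mismatch(9), mk_mismatch(12)]
        store = GermlineStore([("chr1", 9, "C", "T")])
        assert [m.pos for m in filter_germline(mms, store)] == [5, 12]

    def test_allele_specific_lookup(self):
        store = GermlineStore([("chr1", 5, "C", "G")])
        (m,) = filter_germline([mk_mismatch(5, alt="T")], store)
        assert m.pos == 5  # same site, different alt allele: retained

    def test_idempotent(self):
        mms = [mk_mismatch(p) for p in (5, 9, 12)]
        store = GermlineStore([("chr1", 5, "C", "T")])
        once = filter_germline(mms, store)
        assert filter_germline(once, store) == once


class TestAggregation:
    def test_multi_counts_distinct_fragments(self):
        mms = [mk_mismatch(5), mk_mismatch(5), mk_mismatch(9)]
        sites = aggregate_support(mms)
        assert [(m.pos, m.support) for m in sites] == [(5, 2), (9, 1)]

    def test_min_support_filter(self):
        mms = [mk_mismatch(5), mk_mismatch(9)]
        assert aggregate_support(mms, min_support=2) == []

    def test_multi_totals_conserve_fragment_mismatches(self):
        rng = np.random.default_rng(3)
        mms = [mk_mismatch(int(p)) for p in rng.integers(1, 30, size=200)]
        sites = aggregate_support(mms)
        assert sum(m.support for m in sites) == len(mms)


class TestIndelNormalisation:
    def test_left_align_deletion_in_repeat(self):
        ref = "GCACACACAT"  # 1-based

        def base(chrom, pos1):
            return ref[pos1 - 1]

        # deleting AC at pos 7 is equivalent to deleting CA at pos 2
        m = Mismatch(chrom="chr1", pos=7, ref="AC", alt="", klass=DEL, bq=30)
        la = left_align_indel(m, base)
        assert (la.pos, la.ref) == (2, "CA")
        anchored = anchor_indel(la, base)
        assert (anchored.pos, anchored.ref, anchored.alt) == (1, "GCA", "G")

    def test_left_align_insertion(self):
        ref = "GATTTC"

        def base(chrom, pos1):
            return ref[pos1 - 1]

        m = Mismatch(chrom="chr1", pos=5, ref="", alt="T", klass=INS, bq=30)
        la = left_align_indel(m, base)
        assert (la.pos, la.alt) == (2, "T")
        anchored = anchor_indel(la, base)
        assert (anchored.pos, anchored.ref, anchored.alt) == (2, "A", "AT")


class TestVcf:
    def test_empty_vcf_parses(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], "s1", path, {"chr1": 1000})
        assert read_vcf(path) == []

    def test_single_record_has_multi(self, tmp_path):
        path = tmp_path / "one.vcf"
        write_vcf([mk_mismatch(5, support=3)], "s1", path, {"chr1": 1000})
        text = path.read_text()
        assert "MULTI=3" in text
        line = [l for l in text.splitlines() if not l.startswith("#")][0]
        assert line.split("\t")[1] == "5"  # POS is 1-based

    def test_round_trip_preserves_keys(self, tmp_path):
        sites = [
            mk_mismatch(5, support=2),
            mk_mismatch(9, ref="G", alt="A", support=1),
            Mismatch(chrom="chr1", pos=21, ref="A", alt="ATT", klass=INS,
                     bq=30, support=4),
        ]
        # VCF wants anchored alleles; the INS above is already anchored
        path = tmp_path / "rt.vcf"
        write_vcf(sites, "s1", path, {"chr1": 1000})
        back = read_vcf(path)
        got = {(m.chrom, m.pos, m.ref, m.alt, m.support) for m in back}
        assert ("chr1", 5, "C", "T", 2) in got
        assert ("chr1", 9, "G", "A", 1) in got
        # gap-style internal representation of the anchored insertion
        assert ("chr1", 21, "", "TT", 4) in got

    def test_duplicate_keys_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_vcf([mk_mismatch(5), mk_mismatch(5)], "s1",
                      tmp_path / "x.vcf", {"chr1": 100})


def test_filter_stack_monotonicity_on_fuzzed_fragments():
    """Stricter configs always retain a subset: the per-fragment retained
    count under a stricter config never exceeds the looser one."""
    from mmfinder.simulate import simulate_clean_reads
    from mmfinder.workbench import get_preset, make_fixture_genome

    genome, _ = make_fixture_genome(length=200_000, seed=5)
    counts = {}
    for preset in "ABCD":
        frags = simulate_clean_reads(genome, 2.0, seed=9)
        res = extract_mismatches(frags, get_preset(preset))
        counts[preset] = res.report["retained_fragment_mismatches"]
    assert counts["A"] >= counts["B"] >= counts["C"] >= counts["D"]
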