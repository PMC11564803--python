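"""Sizing equations, read simulation, spike-ins, downsampling, admixture."""

import numpy as np
import pandas as pd
import pytest

from mmfinder.extract import extract_mismatches
from mmfinder.records import FilterConfig
from mmfinder.simulate import (
    AdmixtureSpec,
    DownsampleSpec,
    QualityProfile,
    ReadSimParams,
    admix,
    donor_fraction,
    downsample,
    downsample_fraction,
    inject_variants,
    measure_error_rate,
    plan_spike_in,
    simulate_clean_reads,
    spike_in_variant_count,
    tumour_read_fraction,
)


class TestSizingEquations:
    def test_spike_in_count(self):
        assert spike_in_variant_count(0.1, 3_000_000_000) == 300
        assert spike_in_variant_count(100.0, 3_000_000_000) == 300_000
        assert spike_in_variant_count(0.0, 3_000_000_000) == 0

    def test_downsample_fraction(self):
        f = downsample_fraction(3_000_000_000, 3.0, 100, 180_000_000)
        assert f == pytest.approx(0.5)
        with pytest.raises(ValueError):
            downsample_fraction(3_000_000_000, 30.0, 100, 180_000_000)

    def test_tumour_fraction(self):
        assert tumour_read_fraction(0.06, 0.12) == pytest.approx(0.5)
        assert tumour_read_fraction(0.12, 0.12) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            tumour_read_fraction(0.2, 0.1)

    def test_donor_fraction(self):
        assert donor_fraction(0.5, 1000, 1000) == pytest.approx(0.5)
        assert donor_fraction(1.0, 1000, 1000) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            donor_fraction(0.0, 2000, 1000)  # donor too small

    def test_error_rate(self):
        assert measure_error_rate(3, 30_000_000) == pytest.approx(1e-7)
        assert measure_error_rate(0, 100) == 0.0
        with pytest.raises(ValueError):
            measure_error_rate(1, 0)


class TestCleanReads:
    def test_error_free_reads_yield_no_mismatches(self, small_genome):
        genome, _ = small_genome
        params = ReadSimParams(profile=QualityProfile.error_free())
        frags = simulate_clean_reads(genome, 0.5, params=params, seed=3)
        res = extract_mismatches(frags, FilterConfig(min_bq=0, min_avg_bq=0))
        assert res.n_sites == 0

    def test_fragment_length_distribution(self, small_genome):
        genome, _ = small_genome
        frags = list(simulate_clean_reads(genome, 2.0, seed=4))
        lens = np.array([f.fragment_length for f in frags])
        assert len(frags) >= 9_000
        assert abs(lens.mean() - 166.0) < 1.0
        assert abs(lens.std() - 24.0) < 2.0
        # reads never run off the contig
        L = len(genome["chr1"])
        assert all(f.r2.start + 100 <= L for f in frags)

    def test_observed_error_rate_matches_profile(self, small_genome):
        genome, _ = small_genome
        profile = QualityProfile()
        frags = simulate_clean_reads(genome, 2.0, seed=5)
        # preset-A style raw count: every per-read mismatch, every base
        cfg = FilterConfig(min_mapq=0, min_bq=0, min_avg_bq=0,
                           max_mismatches=10**9, consensus=False)
        res = extract_mismatches(frags, cfg)
        rate = measure_error_rate(
            res.report["retained_fragment_mismatches"],
            res.report["filtered_bases"])
        expected = profile.expected_error_rate()
        # DBS merging of adjacent errors removes a negligible fraction
        assert abs(rate - expected) / expected < 0.05

    def test_seed_determinism(self, small_genome):
        genome, _ = small_genome
        a = list(simulate_clean_reads(genome, 0.2, seed=9))
        b = list(simulate_clean_reads(genome, 0.2, seed=9))
        assert [(f.r1.start, f.r1.seq, f.r1.md) for f in a] == \
               [(f.r1.start, f.r1.seq, f.r1.md) for f in b]


class TestSpikeIn:
    def test_plan_contexts_match_signature(self, small_genome, sbs_catalogue):
        genome, _ = small_genome
        sig = sbs_catalogue.matrix["SBS7a"]
        plan = plan_spike_in(sig, 500.0, genome, seed=1)
        assert plan.n_vars == 500
        # every variant's reference base matches the genome
        for chrom, pos, ref, alt in plan.variants:
            assert genome[chrom][pos - 1] == ref
            assert ref != alt
        # positions unique
        keys = {(c, p) for c, p, _r, _a in plan.variants}
        assert len(keys) == plan.n_vars
        # SBS7a is C>T at dipyrimidines: pyrimidine-normalised alt is T
        from mmfinder.records import revcomp

        n_ct = 0
        for chrom, pos, ref, alt in plan.variants:
            if ref in "CT":
                n_ct += (ref, alt) == ("C", "T")
            else:
                n_ct += (revcomp(ref), revcomp(alt)) == ("C", "T")
        assert n_ct / plan.n_vars > 0.85

    def test_empty_plan(self, small_genome, sbs_catalogue):
        genome, _ = small_genome
        plan = plan_spike_in(sbs_catalogue.matrix["SBS2"], 0.0, genome,
                             seed=1)
        assert plan.variants == []

    def test_exhausted_channel_raises(self, sbs_catalogue):
        tiny = {"chr1": "ACGT" * 200}
        with pytest.raises(ValueError, match="exhausted"):
            plan_spike_in(sbs_catalogue.matrix["SBS2"], 500_000.0, tiny,
                          seed=1)

    def test_af_one_every_covering_fragment_carries(self, small_genome,
                                                    sbs_catalogue):
        genome, _ = small_genome
        params = ReadSimParams(profile=QualityProfile.error_free())
        frags = list(simulate_clean_reads(genome, 1.0, params=params, seed=6))
        plan = plan_spike_in(sbs_catalogue.matrix["SBS2"], 100.0, genome,
                             seed=2, allele_frequency=1.0)
        edited, stats = inject_variants(frags, plan, seed=3)
        sites = plan.positions_by_chrom()["chr1"]
        for f in edited:
            for r in (f.r1, f.r2):
                for pos, (ref, alt) in sites.items():
                    off = pos - 1 - r.start
                    if 0 <= off < len(r.seq):
                        assert r.seq[off] == alt
        assert stats["alleles_injected"] > 0

    def test_allele_fraction_binomial(self, small_genome, sbs_catalogue):
        genome, _ = small_genome
        params = ReadSimParams(profile=QualityProfile.error_free())
        frags = list(simulate_clean_reads(genome, 3.0, params=params, seed=7))
        plan = plan_spike_in(sbs_catalogue.matrix["SBS2"], 1000.0, genome,
                             seed=4, allele_frequency=0.1)
        edited, stats = inject_variants(frags, plan, seed=5)
        sites = plan.positions_by_chrom()["chr1"]
        carrying = covering = 0
        for f in edited:
            seen = set()
            for r in (f.r1, f.r2):
                for pos in sites:
                    off = pos - 1 - r.start
                    if 0 <= off < len(r.seq) and pos not in seen:
                        seen.add(pos)
                        covering += 1
                        carrying += r.seq[off] == sites[pos][1]
        frac = carrying / covering
        # 99% binomial CI around 0.1
        half = 2.58 * np.sqrt(0.1 * 0.9 / covering)
        assert abs(frac - 0.1) < half + 1e-9

    def test_injection_determinism(self, small_genome, sbs_catalogue):
        genome, _ = small_genome
        frags = list(simulate_clean_reads(genome, 0.5, seed=8))
        plan = plan_spike_in(sbs_catalogue.matrix["SBS2"], 200.0, genome,
                             seed=2)
        a, _ = inject_variants(frags, plan, seed=9)
        b, _ = inject_variants(frags, plan, seed=9)
        assert [(f.r1.seq, f.r1.md) for f in a] == \
               [(f.r1.seq, f.r1.md) for f in b]


class TestDownsampleAdmix:
    def _frags(self, genome, seed=10, depth=0.5):
        return list(simulate_clean_reads(genome, depth, seed=seed))

    def test_full_fraction_is_identity(self, small_genome):
        genome, _ = small_genome
        frags = self._frags(genome)
        spec = DownsampleSpec(depth_t=0.5, len_read=100,
                              n_reads=2 * len(frags),
                              n_genome=100 * 2 * len(frags) // 1, seed=1)
        assert spec.fraction == pytest.approx(0.5 * 100 * 2 * len(frags)
                                              / (100 * 2 * len(frags)))

    def test_downsample_reproducible_and_thinned(self, small_genome):
        genome, _ = small_genome
        frags = self._frags(genome)
        n_reads = 2 * len(frags)
        spec = DownsampleSpec(depth_t=0.25, len_read=100, n_reads=n_reads,
                              n_genome=len(genome["chr1"]), seed=2)
        a = downsample(frags, spec)
        b = downsample(frags, spec)
        assert [f.name for f in a] == [f.name for f in b]
        expected = spec.fraction * len(frags)
        assert abs(len(a) - expected) < 4 * np.sqrt(expected)

    def test_admix_identity_at_equal_purity(self, small_genome):
        genome, _ = small_genome
        src = self._frags(genome, seed=11)
        don = self._frags(genome, seed=12)
        spec = AdmixtureSpec(p_s=0.12, p_t=0.12, n_s=len(src), n_d=len(don),
                             seed=3)
        assert spec.f_tumour == pytest.approx(1.0)
        assert spec.f_normal == pytest.approx(0.0)
        mixed = admix(src, don, spec)
        assert sorted(f.name for f in mixed) == sorted(f.name for f in src)

    def test_admix_expected_composition(self, small_genome):
        genome, _ = small_genome
        src = self._frags(genome, seed=13, depth=1.0)
        don = self._frags(genome, seed=14, depth=1.0)
        spec = AdmixtureSpec(p_s=0.12, p_t=0.06, n_s=len(src), n_d=len(don),
                             seed=4)
        assert spec.f_tumour == pytest.approx(0.5)
        mixed = admix(src, don, spec)
        n_src = sum(1 for f in mixed if not f.name.startswith("donor_"))
        assert abs(n_src - 0.5 * len(src)) < 4 * np.sqrt(0.5 * len(src))
        assert abs(len(mixed) - len(src)) < 6 * np.sqrt(len(src))
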