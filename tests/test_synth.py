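"""Synthetic-data generators: determinism, invariants, ground-truth exactness."""

import numpy as np
import pytest

from refbias.synth import (
    PopulationQuartet,
    ReferenceGenome,
    VariantPanel,
    VariantRecord,
    make_contaminant_genome,
    make_diploid_sample,
    make_population_quartet,
    make_reference,
    make_variant_panel,
)
from refbias.popgen import dstat_abba_baba, with_reference_p3


class TestMakeReference:
    def test_deterministic_for_fixed_seed(self):
        a = make_reference({"chr1": 10_000}, 0.41, seed=7)
        b = make_reference({"chr1": 10_000}, 0.41, seed=7)
        assert a["chr1"] == b["chr1"]
        c = make_reference({"chr1": 10_000}, 0.41, seed=8)
        assert a["chr1"] != c["chr1"]

    def test_gc_content_within_binomial_interval(self):
        ref = make_reference({"chr1": 100_000}, 0.41, seed=1)
        gc = sum(ref["chr1"].count(b) for b in "GC") / 100_000
        # 0.41 +/- ~4 binomial SEs (SE = sqrt(.41*.59/1e5) ~ 0.0016)
        assert abs(gc - 0.41) < 0.0065

    @pytest.mark.parametrize("bad_len", [0, 100, 999])
    def test_rejects_too_short_chromosomes(self, bad_len):
        with pytest.raises(ValueError):
            make_reference({"chr1": bad_len}, 0.41, seed=0)

    def test_rejects_bad_gc(self):
        with pytest.raises(ValueError):
            make_reference({"chr1": 2000}, 0.0, seed=0)


class TestVariantPanel:
    def test_count_sorted_nonoverlapping(self, small_ref):
        panel = make_variant_panel(
            small_ref, n_snps=50, n_indels=10, indel_len_max=18, min_spacing=60, seed=2
        )
        assert len(panel) == 60
        keys = [(r.chrom, r.pos) for r in panel]
        assert keys == sorted(keys)
        for a, b in zip(panel.records, panel.records[1:]):
            assert b.start0 >= a.end0

    def test_snp_ref_allele_matches_reference(self, small_ref, small_panel):
        for r in small_panel:
            assert small_ref[r.chrom][r.start0 : r.end0] == r.ref_allele

    def test_indel_lengths_bounded_by_maximum(self, small_panel):
        lens = [r.indel_len for r in small_panel if r.vtype != "snp"]
        assert lens and max(lens) <= 18

    def test_maf_floor_respected(self, small_panel):
        assert all(r.maf >= 0.001 for r in small_panel)

    def test_impossible_placement_reports_shortfall(self, small_ref):
        with pytest.raises(ValueError, match="capacity"):
            make_variant_panel(small_ref, n_snps=10_000, min_spacing=60, seed=0)

    def test_overlapping_records_rejected(self):
        recs = [
            VariantRecord("c", 5, "ACGTA", "A", "deletion", 0.1),
            VariantRecord("c", 7, "G", "T", "snp", 0.1),
        ]
        with pytest.raises(ValueError, match="overlap"):
            VariantPanel(recs)


class TestDiploidSample:
    def test_all_het_phase_convention(self, small_ref, small_panel):
        s = make_diploid_sample(small_ref, small_panel, het_rate=1.0, hom_alt_rate=0.0, seed=1)
        assert all(g == "het" for g in s.genotypes.values())
        # haplotype A carries the reference allele everywhere
        assert s.haplotypes["chr1"][0] == small_ref["chr1"]

    def test_all_hom_ref_identity(self, small_ref, small_panel):
        s = make_diploid_sample(small_ref, small_panel, het_rate=0.0, hom_alt_rate=0.0, seed=1)
        assert s.haplotypes["chr1"] == (small_ref["chr1"], small_ref["chr1"])

    def test_liftover_offset_past_deletion(self):
        ref = make_reference({"c": 5000}, 0.41, seed=3)
        seq = ref["c"]
        rec = VariantRecord("c", 1001, seq[1000:1006], seq[1000], "deletion", 0.2)
        s = make_diploid_sample(ref, VariantPanel([rec]), het_rate=1.0, hom_alt_rate=0.0, seed=0)
        lift = s.liftovers[("c", 1)]  # hap B carries the deletion
        # a base 100 bp past the junction maps 5 bp further on the reference
        assert int(lift.hap_to_ref(1101)[0]) == 1106

    def test_haplotype_reconstruction_byte_exact(self, small_ref, small_panel, small_diploid):
        """Applying genotyped alleles to the reference reproduces haplotypes."""
        seq = list(small_ref["chr1"])
        out_a, out_b = [], []
        cursor = 0
        hap_a, hap_b = [], []
        for rec in small_panel:
            g = small_diploid.genotypes[rec.key]
            chunk = small_ref["chr1"][cursor : rec.start0]
            hap_a.append(chunk)
            hap_b.append(chunk)
            hap_a.append(rec.alt_allele if g == "hom_alt" else rec.ref_allele)
            hap_b.append(rec.alt_allele if g in ("het", "hom_alt") else rec.ref_allele)
            cursor = rec.end0
        hap_a.append(small_ref["chr1"][cursor:])
        hap_b.append(small_ref["chr1"][cursor:])
        assert "".join(hap_a) == small_diploid.haplotypes["chr1"][0]
        assert "".join(hap_b) == small_diploid.haplotypes["chr1"][1]

    def test_bad_rates_rejected(self, small_ref, small_panel):
        with pytest.raises(ValueError):
            make_diploid_sample(small_ref, small_panel, het_rate=0.8, hom_alt_rate=0.4)


def _longest_common_substring_at_most(a: str, b: str, k: int) -> bool:
    """True iff the longest exact shared substring is <= k (k-mer set check)."""
    kk = k + 1
    kmers = {a[i : i + kk] for i in range(len(a) - kk + 1)}
    return all(b[i : i + kk] not in kmers for i in range(len(b) - kk + 1))


class TestContaminant:
    def test_independent_of_target_reference(self):
        ref = make_reference({"chr1": 50_000}, 0.41, seed=9)
        cont = make_contaminant_genome(50_000, 0.41, seed=9)
        assert _longest_common_substring_at_most(ref["chr1"], cont["contig1"], 30)

    def test_deterministic(self):
        a = make_contaminant_genome(5_000, 0.45, seed=4)
        b = make_contaminant_genome(5_000, 0.45, seed=4)
        assert a["contig1"] == b["contig1"]


class TestPopulationQuartet:
    def test_full_bias_forces_reference_alleles(self, small_panel):
        q = make_population_quartet(small_panel, bias_toward_ref=1.0, seed=2)
        assert (q.alleles[0] == 0).all()

    def test_symmetric_drift_gives_zero_expected_d(self, small_panel):
        ds = []
        for rep in range(40):
            q = make_population_quartet(small_panel, (0.05, 0.05, 0.1, 0.0), 0.0, seed=rep)
            res = dstat_abba_baba(q, block_size_sites=10)
            if not res.undefined:
                ds.append(res.D)
        assert abs(np.mean(ds)) < 0.1

    def test_reference_bias_drives_d_negative(self, small_panel):
        ds = []
        for rep in range(30):
            q = make_population_quartet(small_panel, (0.02, 0.02, 0.1, 0.0), 0.25, seed=rep)
            res = dstat_abba_baba(with_reference_p3(q), block_size_sites=10)
            ds.append(res.D)
        assert np.mean(ds) < -0.05

    def test_bad_drift_rejected(self, small_panel):
        with pytest.raises(ValueError):
            make_population_quartet(small_panel, (0.1, -0.1, 0.1, 0.0), 0.0, seed=0)
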