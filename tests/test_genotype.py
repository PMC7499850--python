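"""Pileups, the diploid caller, downsampling and pseudo-haploid sampling."""

import math

import numpy as np
import pytest

from refbias.aligners import Alignment
from refbias.damage import SimulatedRead
from refbias.genotype import (
    GenotypeCall,
    PileupColumn,
    call_diploid_genotypes,
    downsample_alignments,
    het_recovery,
    indel_support_by_length,
    pileup_sites,
    pseudo_haploid_calls,
)
from refbias.synth import VariantPanel, VariantRecord, make_reference


@pytest.fixture(scope="module")
def world():
    ref = make_reference({"chr1": 10_000}, 0.41, seed=31)
    seq = ref["chr1"]
    snp = VariantRecord("chr1", 2001, seq[2000], "ACGT".replace(seq[2000], "")[0], "snp", 0.1)
    dele = VariantRecord("chr1", 4001, seq[4000:4006], seq[4000], "deletion", 0.1)
    return ref, VariantPanel([snp, dele]), snp, dele


def _read(seq, rid="r"):
    return SimulatedRead(rid, seq)


class TestPileup:
    def test_snp_base_contribution(self, world):
        ref, panel, snp, _ = world
        seq = ref["chr1"]
        aln = Alignment("r", True, chrom="chr1", pos=1980, cigar=(("M", 50),), mapq=37)
        pile = pileup_sites([aln], [_read(seq[1980:2030])], panel, ref=ref)
        assert [e[1] for e in pile[snp.key].entries] == ["ref"]
        alt_read = seq[1980:2000] + snp.alt_allele + seq[2001:2030]
        pile = pileup_sites([aln], [_read(alt_read)], panel, ref=ref)
        assert [e[1] for e in pile[snp.key].entries] == ["alt"]

    def test_deletion_read_contributes_alt(self, world):
        ref, panel, _, dele = world
        seq = ref["chr1"]
        read = seq[3981:4001] + seq[4006:4036]
        aln = Alignment("r", True, chrom="chr1", pos=3981,
                        cigar=(("M", 20), ("D", 5), ("M", 30)), mapq=37)
        pile = pileup_sites([aln], [_read(read)], panel, ref=ref)
        assert [e[1] for e in pile[dele.key].entries] == ["alt"]

    def test_full_span_ref_read_supports_ref_allele(self, world):
        ref, panel, _, dele = world
        seq = ref["chr1"]
        aln = Alignment("r", True, chrom="chr1", pos=3981, cigar=(("M", 50),), mapq=37)
        pile = pileup_sites([aln], [_read(seq[3981:4031])], panel, ref=ref)
        assert [e[1] for e in pile[dele.key].entries] == ["ref"]

    def test_mapq_filter_excludes_reads(self, world):
        ref, panel, snp, _ = world
        seq = ref["chr1"]
        aln = Alignment("r", True, chrom="chr1", pos=1980, cigar=(("M", 50),), mapq=10)
        pile = pileup_sites([aln], [_read(seq[1980:2030])], panel, min_mapq=30, ref=ref)
        assert pile[snp.key].depth == 0


class TestCaller:
    def _col(self, rec, n_ref, n_alt):
        col = PileupColumn(rec)
        col.entries = [(f"x{i}", "ref", 30, 37) for i in range(n_ref)] + [
            (f"y{i}", "alt", 30, 37) for i in range(n_alt)
        ]
        return col

    def test_balanced_site_called_het_with_expected_quality(self, world):
        _, _, snp, _ = world
        calls = call_diploid_genotypes({snp.key: self._col(snp, 5, 5)}, err=0.01)
        c = calls[0]
        assert c.genotype == "het"
        # independent likelihood arithmetic for the posterior
        l_het = 0.5**10
        l_hom = (0.99**5) * (0.01**5)
        post = l_het / (l_het + 2 * l_hom)
        expected_q = -10 * math.log10(1 - post)
        assert c.qual == pytest.approx(expected_q, rel=1e-6)
        assert c.qual > 30

    def test_all_ref_called_hom_ref(self, world):
        _, _, snp, _ = world
        calls = call_diploid_genotypes({snp.key: self._col(snp, 10, 0)})
        assert calls[0].genotype == "hom_ref"

    def test_zero_depth_no_call(self, world):
        _, _, snp, _ = world
        calls = call_diploid_genotypes({snp.key: self._col(snp, 0, 0)})
        assert calls[0].genotype == "no_call" and math.isnan(calls[0].qual)

    def test_transition_masking_skips_site(self):
        rec = VariantRecord("chr1", 11, "C", "T", "snp", 0.1)
        calls = call_diploid_genotypes(
            {rec.key: self._col(rec, 5, 5)}, mask_transitions=True
        )
        assert calls == []

    def test_empty_pileup_rejected(self):
        with pytest.raises(ValueError):
            call_diploid_genotypes({})


class TestDownsample:
    def test_fraction_one_identity(self):
        mask = downsample_alignments(list(range(100)), 1.0, seed=1)
        assert mask.all()

    def test_binomial_retention(self):
        mask = downsample_alignments(list(range(10_000)), 0.5, seed=2)
        se = np.sqrt(0.25 * 10_000)
        assert abs(mask.sum() - 5000) < 3 * se

    def test_seeded_reproducibility(self):
        a = downsample_alignments(list(range(1000)), 0.3, seed=3)
        b = downsample_alignments(list(range(1000)), 0.3, seed=3)
        assert (a == b).all()

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            downsample_alignments([1], 0.0)


class TestHetRecovery:
    def _call(self, rec, genotype="het", qual=60.0):
        return GenotypeCall(rec, genotype, qual, 20, 10, 10)

    def _tv(self, pos):
        return VariantRecord("chr1", pos, "A", "C", "snp", 0.1)

    def test_identical_sets_full_recovery(self):
        calls = [self._call(self._tv(p)) for p in (11, 21, 31)]
        assert het_recovery(calls, calls) == 1.0

    def test_disjoint_sets_zero(self):
        full = [self._call(self._tv(p)) for p in (11, 21)]
        down = [self._call(self._tv(p), genotype="hom_ref") for p in (11, 21)]
        assert het_recovery(full, down) == 0.0

    def test_transitions_excluded(self):
        ts = VariantRecord("chr1", 41, "C", "T", "snp", 0.1)
        full = [self._call(self._tv(11)), self._call(ts)]
        assert het_recovery(full, full) == 1.0  # denominator ignores the transition

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            het_recovery([], [])


class TestPseudoHaploid:
    def test_single_read_site_returns_that_allele(self, world):
        _, _, snp, _ = world
        col = PileupColumn(snp, [("a", "alt", 30, 37)])
        assert pseudo_haploid_calls({snp.key: col}, seed=1) == {snp.key: "alt"}

    def test_sampled_allele_always_observed(self, world):
        _, _, snp, _ = world
        col = PileupColumn(snp, [("a", "ref", 30, 37), ("b", "alt", 30, 37)])
        for seed in range(20):
            assert pseudo_haploid_calls({snp.key: col}, seed=seed)[snp.key] in ("ref", "alt")

    def test_sampling_probability_matches_pileup_fraction(self, world):
        _, _, snp, _ = world
        col = PileupColumn(
            snp, [("a", "ref", 30, 37), ("b", "ref", 30, 37), ("c", "alt", 30, 37)]
        )
        picks = [pseudo_haploid_calls({snp.key: col}, seed=s)[snp.key] for s in range(3000)]
        frac = np.mean([p == "alt" for p in picks])
        se = np.sqrt((1 / 3) * (2 / 3) / 3000)
        assert abs(frac - 1 / 3) < 3.5 * se


class TestIndelSupport:
    def test_no_indels_gives_empty_table(self, world):
        ref, _, snp, _ = world
        df = indel_support_by_length({}, VariantPanel([snp]))
        assert df.empty
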