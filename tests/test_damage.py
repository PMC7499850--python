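"""Damage model and read simulation."""

import numpy as np
import pytest

from refbias.damage import (
    DamageModel,
    SimulatedRead,
    apply_deamination,
    enumerate_site_reads,
    sample_shotgun_reads,
)
from refbias.synth import VariantPanel, VariantRecord, make_reference, make_diploid_sample


class TestDamageModel:
    def test_exponential_shape(self):
        m = DamageModel.exponential(d_max=1.0, lambda_decay=0.5, d_background=0.01)
        assert m.d5[0] == pytest.approx(1.0)
        assert m.d5[1] == pytest.approx(0.01 + 0.99 * 0.5)
        assert np.all(np.diff(m.d5) <= 0)

    def test_scaling_and_overflow(self):
        m = DamageModel.exponential()
        d5, _ = m.profile_for_length(50, 0.2)
        assert d5[0] == pytest.approx(0.2)
        with pytest.raises(ValueError):
            m.profile_for_length(50, 1.5)

    def test_from_tsv_roundtrip(self, tmp_path):
        p5 = tmp_path / "d5.tsv"
        p3 = tmp_path / "d3.tsv"
        p5.write_text("0\t0.3\n1\t0.1\n2\t0.05\n")
        p3.write_text("1\t0.08\n0\t0.25\n2\t0.04\n")  # unsorted on purpose
        m = DamageModel.from_tsv(str(p5), str(p3))
        assert m.d5.tolist() == [0.3, 0.1, 0.05]
        assert m.d3.tolist() == [0.25, 0.08, 0.04]

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError):
            DamageModel(np.array([0.5, 1.2]), np.array([0.1]))


class TestEnumerateSiteReads:
    def test_snp_placement_combinatorics(self):
        ref = make_reference({"c": 5000}, 0.41, seed=1)
        rec = VariantRecord("c", 2001, ref["c"][2000], "ACGT".replace(ref["c"][2000], "")[0], "snp", 0.1)
        reads = enumerate_site_reads(ref, VariantPanel([rec]), read_len=50)
        refs = [r for r in reads if r.carried_allele == "ref"]
        alts = [r for r in reads if r.carried_allele == "alt"]
        assert len(refs) == 50 and len(alts) == 50
        # alt reads differ from the matching ref read at exactly one position
        by_start = {r.ref_start: r for r in refs}
        for a in alts:
            diffs = sum(x != y for x, y in zip(a.sequence, by_start[a.ref_start].sequence))
            assert diffs == 1

    def test_deletion_reads_span_extra_reference(self):
        ref = make_reference({"c": 5000}, 0.41, seed=2)
        seq = ref["c"]
        rec = VariantRecord("c", 2001, seq[2000:2006], seq[2000], "deletion", 0.1)
        reads = enumerate_site_reads(ref, VariantPanel([rec]), read_len=50)
        alts = [r for r in reads if r.carried_allele == "alt"]
        assert all(len(r.sequence) == 50 for r in alts)
        assert all(r.ref_end - r.ref_start == 55 for r in alts)
        # sequence really comes from the deleted haplotype
        a = alts[0]
        expected = seq[a.ref_start : 2001] + seq[2006 : a.ref_end]
        assert a.sequence == expected

    def test_both_strands_flag_adds_reverse_complements(self):
        ref = make_reference({"c": 5000}, 0.41, seed=1)
        rec = VariantRecord("c", 2001, ref["c"][2000], "ACGT".replace(ref["c"][2000], "")[0], "snp", 0.1)
        fwd = enumerate_site_reads(ref, VariantPanel([rec]), 50)
        both = enumerate_site_reads(ref, VariantPanel([rec]), 50, both_strands=True)
        assert len(both) == 2 * len(fwd)

    def test_read_len_too_short_rejected(self, small_ref, small_panel):
        with pytest.raises(ValueError):
            enumerate_site_reads(small_ref, small_panel, read_len=10)


class TestApplyDeamination:
    def test_zero_rate_is_identity(self):
        reads = [SimulatedRead("r1", "ACGTACGTAC")]
        model = DamageModel.exponential(d_background=0.0)
        out = apply_deamination(reads, model, 0.0, seed=1)
        assert out[0].sequence == reads[0].sequence
        assert out[0].damage_positions == []

    def test_terminal_conversion_rate_binomial(self):
        model = DamageModel.exponential()
        reads = [SimulatedRead(f"r{i}", "C" + "A" * 39) for i in range(10_000)]
        out = apply_deamination(reads, model, 0.3, seed=7)
        frac = np.mean([r.sequence[0] == "T" for r in out])
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(frac - 0.3) < 3 * se

    def test_read_without_c_or_g_untouched(self):
        model = DamageModel.exponential()
        out = apply_deamination([SimulatedRead("r", "ATATATAT")], model, 1.0, seed=0)
        assert out[0].sequence == "ATATATAT"

    def test_single_strand_mode_converts_c_at_both_ends(self):
        model = DamageModel(np.array([1.0]), np.array([1.0]))
        out = apply_deamination(
            [SimulatedRead("r", "CAAAAAAC")], model, 1.0, seed=0, single_strand=True
        )
        assert out[0].sequence == "TAAAAAAT"

    def test_damage_positions_recorded(self):
        model = DamageModel(np.array([1.0]), np.array([1.0]))
        out = apply_deamination([SimulatedRead("r", "CAAAAAAG")], model, 1.0, seed=0)
        assert out[0].sequence == "TAAAAAAA"
        assert out[0].damage_positions == [0, 7]


@pytest.fixture(scope="module")
def sample():
    ref = make_reference({"c": 100_000}, 0.41, seed=5)
    from refbias.synth import make_variant_panel

    panel = make_variant_panel(ref, n_snps=50, n_indels=10, min_spacing=200, seed=5)
    return make_diploid_sample(ref, panel, seed=5)


class TestShotgunReads:

    def test_total_base_expectation(self, sample):
        reads = sample_shotgun_reads(sample, coverage=4.0, fraglen_mean=60, seed=1)
        total = sum(len(r.sequence) for r in reads)
        assert abs(total - 4 * 100_000) / (4 * 100_000) < 0.05

    def test_strand_balance(self, sample):
        reads = sample_shotgun_reads(sample, coverage=8.0, fraglen_mean=60, seed=2)
        frac = np.mean([r.strand == "-" for r in reads])
        se = np.sqrt(0.25 / len(reads))
        assert abs(frac - 0.5) < 3 * se

    def test_endogenous_fraction_one_means_no_contaminant(self, sample):
        reads = sample_shotgun_reads(sample, coverage=1.0, endogenous_fraction=1.0, seed=3)
        assert all(r.source == "target" for r in reads)

    def test_contaminant_admixture(self, sample):
        from refbias.synth import make_contaminant_genome

        cont = make_contaminant_genome(50_000, 0.45, seed=1)
        reads = sample_shotgun_reads(
            sample, coverage=2.0, contaminant=cont, endogenous_fraction=0.8, seed=4
        )
        frac = np.mean([r.source == "contaminant" for r in reads])
        assert abs(frac - 0.2) < 0.02

    def test_undamaged_reads_match_haplotype(self, sample):
        from refbias.util import revcomp

        reads = sample_shotgun_reads(sample, coverage=0.5, seed=6)
        for r in reads[:200]:
            hap_pair = sample.haplotypes[r.chrom]
            seq = revcomp(r.sequence) if r.strand == "-" else r.sequence
            assert seq in hap_pair[0] or seq in hap_pair[1]

    def test_fraglen_below_min_rejected(self, sample):
        with pytest.raises(ValueError):
            sample_shotgun_reads(sample, coverage=1.0, fraglen_mean=20, min_len=35)
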