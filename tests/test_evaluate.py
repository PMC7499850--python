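"""Truth-based scoring: placement assessment, bias reports, profiles."""

import numpy as np
import pytest

from refbias.aligners import Alignment
from refbias.damage import SimulatedRead
from refbias.evaluate import (
    assess_read_placement,
    bias_report,
    damage_profile,
    sensitivity_by_damage,
)
from refbias.synth import make_reference


def _truth(start=100, chrom="chr1", allele="ref", L=50, strand="+"):
    return SimulatedRead(
        "r", "A" * L, chrom=chrom, ref_start=start, ref_end=start + L,
        strand=strand, carried_allele=allele,
    )


class TestAssessPlacement:
    def test_softclip_offset_is_corrected(self):
        aln = Alignment("r", True, chrom="chr1", pos=105, cigar=(("S", 5), ("M", 45)))
        assert assess_read_placement(aln, _truth(100)) == "correct"

    def test_wrong_chromosome_incorrect(self):
        aln = Alignment("r", True, chrom="chr2", pos=100, cigar=(("M", 50),))
        assert assess_read_placement(aln, _truth(100)) == "incorrect"

    def test_deletion_read_at_truth_start_correct(self):
        aln = Alignment(
            "r", True, chrom="chr1", pos=100,
            cigar=(("M", 20), ("D", 5), ("M", 30)),
        )
        t = _truth(100)
        t.ref_end = 155
        assert assess_read_placement(aln, t) == "correct"

    def test_majority_m_rule(self):
        aln = Alignment("r", True, chrom="chr1", pos=100, cigar=(("S", 30), ("M", 20)))
        t = SimulatedRead("r", "A" * 50, chrom="chr1", ref_start=70, ref_end=120)
        assert assess_read_placement(aln, t) == "incorrect"  # only 40% aligned

    def test_unmapped(self):
        assert assess_read_placement(Alignment("r", False), _truth()) == "unmapped"

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            assess_read_placement(Alignment("r", False), None)


class TestBiasReport:
    def _mk(self, n_alt_mapped, n_ref_mapped, n=500):
        alns, truths = [], []
        for i in range(n):
            t = _truth(100 + i, allele="alt")
            mapped = i < n_alt_mapped
            alns.append(
                Alignment(f"a{i}", mapped, chrom="chr1" if mapped else None,
                          pos=100 + i if mapped else None,
                          cigar=(("M", 50),) if mapped else (), mapq=37)
            )
            truths.append(t)
        for i in range(n):
            t = _truth(100 + i, allele="ref")
            mapped = i < n_ref_mapped
            alns.append(
                Alignment(f"r{i}", mapped, chrom="chr1" if mapped else None,
                          pos=100 + i if mapped else None,
                          cigar=(("M", 50),) if mapped else (), mapq=37)
            )
            truths.append(t)
        return alns, truths

    def test_balanced_counts_closed_form_ci(self):
        alns, truths = self._mk(500, 500)
        rep = bias_report(alns, truths, mapq_min=0)
        assert rep.alt_fraction == 0.5
        lo, hi = rep.alt_fraction_ci95
        assert hi - lo == pytest.approx(2 * 1.96 * np.sqrt(0.25 / 1000))
        assert rep.err_per_million_ref == 0.0

    def test_all_alt_unmapped(self):
        alns, truths = self._mk(0, 500)
        rep = bias_report(alns, truths, mapq_min=0)
        assert rep.alt_fraction == 0.0
        assert rep.sensitivity_alt == 0.0

    def test_mapq_threshold_above_cap_flags_undefined(self):
        alns, truths = self._mk(500, 500)
        rep = bias_report(alns, truths, mapq_min=60)
        assert rep.undefined and np.isnan(rep.alt_fraction)

    def test_conservation_mapped_plus_unmapped(self):
        alns, truths = self._mk(300, 400)
        rep = bias_report(alns, truths, mapq_min=0)
        assert rep.n_alt_mapped + (rep.n_alt_reads - rep.n_alt_mapped) == 500
        assert rep.n_ref_mapped + (rep.n_ref_reads - rep.n_ref_mapped) == 500


class TestSensitivityByDamage:
    def _rep(self, sens):
        alns, truths = [], []
        return type("R", (), {"sensitivity_ref": sens, "sensitivity_alt": sens})()

    def test_exact_ols_on_hand_points(self):
        reps = [self._rep(s) for s in (1.0, 0.95, 0.90)]
        out = sensitivity_by_damage([0.0, 0.1, 0.2], reps)
        assert out["alt"]["slope"] == pytest.approx(-50.0)
        assert out["alt"]["intercept"] == pytest.approx(100.0)
        assert out["alt"]["r2"] == pytest.approx(1.0)

    def test_flat_response_zero_slope(self):
        reps = [self._rep(0.97)] * 4
        out = sensitivity_by_damage([0, 0.1, 0.2, 0.3], reps)
        assert out["ref"]["slope"] == pytest.approx(0.0)

    def test_requires_three_levels(self):
        with pytest.raises(ValueError):
            sensitivity_by_damage([0.0, 0.1], [self._rep(1.0)] * 2)


class TestDamageProfile:
    def test_undamaged_reads_show_no_signal(self):
        ref = make_reference({"chr1": 5000}, 0.41, seed=2)
        reads, alns = [], []
        for i in range(100):
            s = 40 * i
            reads.append(SimulatedRead(f"r{i}", ref["chr1"][s : s + 40],
                                       chrom="chr1", ref_start=s, ref_end=s + 40))
            alns.append(Alignment(f"r{i}", True, chrom="chr1", pos=s, cigar=(("M", 40),)))
        prof = damage_profile(alns, reads, ref, max_pos=10)
        assert np.nansum(prof["ct_rate_5p"]) == 0.0
        assert np.nansum(prof["ga_rate_3p"]) == 0.0

    def test_softclipped_bases_excluded(self):
        ref = make_reference({"chr1": 5000}, 0.41, seed=3)
        s = 1000
        seq = ref["chr1"][s : s + 40]
        # clip the first 10 bases: they must not enter the counts
        aln = Alignment("r", True, chrom="chr1", pos=s + 10,
                        cigar=(("S", 10), ("M", 30)))
        read = SimulatedRead("r", "T" * 10 + seq[10:], chrom="chr1",
                             ref_start=s, ref_end=s + 40)
        prof = damage_profile([aln], [read], ref, max_pos=10)
        # positions 0-9 of the read are clipped: zero denominators
        assert prof["n_ref_C_5p"].iloc[:10].sum() == 0


class TestWaldCoverage:
    def test_ci_covers_nominal_rate(self):
        """Empirical coverage of the Wald interval ~95% over repeated runs."""
        rng = np.random.default_rng(1234)
        n, p = 400, 0.5
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.binomial(n, p)
            f = x / n
            half = 1.96 * np.sqrt(f * (1 - f) / n)
            hits += (f - half) <= p <= (f + half)
        assert hits / reps > 0.90


class TestContaminantMappingRate:
    def test_monotone_in_mapq_and_length_and_empty_input(self):
        from refbias.aligners import LinearAligner
        from refbias.evaluate import contaminant_mapping_rate
        from refbias.synth import make_contaminant_genome, make_reference
        from refbias.util import rng_stream

        ref = make_reference({"chr1": 60_000}, 0.41, seed=8)
        cont = make_contaminant_genome(80_000, 0.45, seed=8)
        rng = rng_stream(8, "cont-reads")
        seq = cont["contig1"]
        reads = []
        for L in (35, 70):
            for i in range(400):
                s = int(rng.integers(0, len(seq) - L))
                reads.append(SimulatedRead(f"c{L}:{i}", seq[s : s + L],
                                           source="contaminant"))
        la = LinearAligner(ref)
        r0 = contaminant_mapping_rate(reads, la, mapq_min=0)
        r30 = contaminant_mapping_rate(reads, la, mapq_min=30)
        # raising the threshold never raises the rate
        assert (r30["rate"] <= r0["rate"] + 1e-12).all()
        # longer unrelated reads are never easier to map
        by_len = dict(zip(r0["read_len"], r0["rate"]))
        assert by_len[70] <= by_len[35]
        empty = contaminant_mapping_rate([], la, mapq_min=30)
        assert empty.empty
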