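"""Pileup-based diploid calling and downsampling analyses.

A deliberately plain biallelic genotype caller: per site, read alleles are
resolved through CIGARs (indel alleles must be spelled completely, with one
anchoring base on each side), genotype likelihoods assume symmetric base
error, and the prior over {hom_ref, het, hom_alt} is flat so that mapping
bias is the only bias under test.  Pseudo-haploid sampling, coverage
downsampling, heterozygote recovery and indel support-by-length mirror the
standard ancient-DNA workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aligners import Alignment, AlignmentTable
from .damage import SimulatedRead
from .synth import VariantPanel, VariantRecord
from .util import rng_stream

GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass
class PileupColumn:
    site: VariantRecord
    entries: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (read_id, allele in {ref, alt, other}, baseq, mapq)

    @property
    def depth(self) -> int:
        return len(self.entries)

    @property
    def ad_ref(self) -> int:
        return sum(1 for e in self.entries if e[1] == "ref")

    @property
    def ad_alt(self) -> int:
        return sum(1 for e in self.entries if e[1] == "alt")


Pileup = dict[tuple[str, int], PileupColumn]


@dataclass
class GenotypeCall:
    site: VariantRecord
    genotype: str  # hom_ref | het | hom_alt | no_call
    qual: float  # phred-scaled 1 - posterior(argmax); nan for no_call
    depth: int
    ad_ref: int
    ad_alt: int


def _aligned_blocks(aln: Alignment):
    """Yield (ref_start, ref_end, read_start) for M runs, plus indel events.

    Returns (blocks, events) where events are ('D'|'I', ref_pos, length,
    read_pos); ref_pos for an insertion is the position of the base *after*
    which the insertion occurs.
    """
    blocks = []
    events = []
    rp, ro = aln.pos, 0
    for op, ln in aln.cigar:
        if op == "S":
            ro += ln
        elif op == "M":
            blocks.append((rp, rp + ln, ro))
            rp += ln
            ro += ln
        elif op == "D":
            events.append(("D", rp, ln, ro))
            rp += ln
        elif op == "I":
            events.append(("I", rp, ln, ro))
            ro += ln
    return blocks, events


def _resolve_snp(aln: Alignment, seq: str, rec: VariantRecord) -> str | None:
    blocks, _ = _aligned_blocks(aln)
    for b0, b1, ro in blocks:
        if b0 <= rec.start0 < b1:
            base = seq[ro + rec.start0 - b0]
            if base == rec.ref_allele:
                return "ref"
            if base == rec.alt_allele:
                return "alt"
            return "other"
    return None


def _equivalent_deletion(refseq: str | None, canon: int, obs: int, g: int) -> bool:
    """Is deleting ref[obs:obs+g] the same haplotype as deleting
    ref[canon:canon+g]?  Aligners left-shift gaps through repeat runs, so an
    observed D may sit upstream of the VCF-anchored position."""
    if obs == canon:
        return True
    if refseq is None:
        return False
    lo, hi = min(obs, canon), max(obs, canon)
    if hi - lo > g + 32:  # far outside any plausible repeat run
        return False
    window = refseq[max(0, lo - 1) : hi + g + 1]
    a = lo - max(0, lo - 1)
    b = hi - max(0, lo - 1)
    return window[:a] + window[a + g :] == window[: b] + window[b + g :]


def _equivalent_insertion(
    refseq: str | None, canon: int, canon_ins: str, obs: int, obs_ins: str
) -> bool:
    """Does inserting ``obs_ins`` before ref[obs] spell the same haplotype
    as inserting ``canon_ins`` before ref[canon]?"""
    if obs == canon and obs_ins == canon_ins:
        return True
    if refseq is None:
        return False
    lo, hi = min(obs, canon), max(obs, canon)
    if hi - lo > len(canon_ins) + 32:
        return False
    start = max(0, lo - 1)
    window = refseq[start : hi + 1]
    a, b = obs - start, canon - start
    return window[:a] + obs_ins + window[a:] == window[:b] + canon_ins + window[b:]


def _resolve_indel(
    aln: Alignment, seq: str, rec: VariantRecord, refseq: str | None = None
) -> str | None:
    """Allele support for an indel site; requires the full allele spelled
    with >= 1 anchoring M base on each side, otherwise no contribution.

    Gap placements equivalent to the canonical left-anchored one (shifted
    through a repeat run) are accepted when the reference sequence is
    available."""
    blocks, events = _aligned_blocks(aln)
    g = rec.indel_len
    anchor = rec.start0  # the shared anchor base
    if rec.vtype == "deletion":
        for op, rp, ln, _ in events:
            if op == "D" and ln == g and _equivalent_deletion(refseq, anchor + 1, rp, g):
                covers = any(b1 == rp for _, b1, _ in blocks) and any(
                    b0 == rp + g for b0, _, _ in blocks
                )
                if covers:
                    return "alt"
        # ref: M covering [anchor, end0] with no event inside
        span_ok = any(b0 <= anchor and rec.end0 < b1 for b0, b1, _ in blocks)
        if span_ok:
            return "ref"
        return None
    else:  # insertion
        canon_ins = rec.alt_allele[1:]
        for op, rp, ln, ro in events:
            if op == "I" and ln == g:
                ins = seq[ro : ro + ln]
                if _equivalent_insertion(refseq, anchor + 1, canon_ins, rp, ins):
                    covers = any(b1 == rp for _, b1, _ in blocks) and any(
                        b0 == rp for b0, _, _ in blocks
                    )
                    if covers:
                        return "alt"
        # ref: M run crossing the junction with no insertion there
        for b0, b1, _ in blocks:
            if b0 <= anchor and anchor + 1 < b1:
                return "ref"
        return None


def pileup_sites(
    alignments,
    reads: list[SimulatedRead],
    panel: VariantPanel,
    min_baseq: int = 20,
    min_mapq: int = 0,
    ref=None,
) -> Pileup:
    """Per-site read alleles resolved through CIGARs.

    ``reads`` supplies sequences and base qualities for the alignments (same
    order); reverse-strand alignments are resolved in aligned orientation.
    Supplying the reference genome lets repeat-shifted gap placements be
    recognised as the canonical indel allele.  Reads below either quality
    threshold contribute nothing.
    """
    from .util import revcomp

    by_chrom: dict[str, tuple[np.ndarray, list[VariantRecord]]] = {}
    for chrom in {r.chrom for r in panel}:
        recs = [r for r in panel if r.chrom == chrom]
        by_chrom[chrom] = (np.asarray([r.start0 for r in recs]), recs)
    pile: Pileup = {r.key: PileupColumn(r) for r in panel}

    it = alignments if isinstance(alignments, AlignmentTable) else list(alignments)
    for i, truth in enumerate(reads):
        aln = it[i]
        if not aln.mapped or aln.mapq < min_mapq or truth.qual < min_baseq:
            continue
        if aln.chrom not in by_chrom:
            continue
        starts, recs = by_chrom[aln.chrom]
        lo = int(np.searchsorted(starts, aln.pos - 1))
        hi = int(np.searchsorted(starts, aln.end_pos))
        if lo == hi:
            continue
        seq = revcomp(truth.sequence) if aln.strand == "-" else truth.sequence
        refseq = ref[aln.chrom] if ref is not None else None
        for rec in recs[lo:hi]:
            allele = (
                _resolve_snp(aln, seq, rec)
                if rec.vtype == "snp"
                else _resolve_indel(aln, seq, rec, refseq)
            )
            if allele is not None:
                pile[rec.key].entries.append((aln.read_id, allele, truth.qual, aln.mapq))
    return pile


def call_diploid_genotypes(
    pileup: Pileup, err: float = 0.01, mask_transitions: bool = False
) -> list[GenotypeCall]:
    """Flat-prior biallelic genotype likelihoods per covered site.

    L(g) multiplies per-read allele probabilities: P(alt | het) = 0.5,
    P(alt | hom_alt) = 1 - err, P(alt | hom_ref) = err; 'other' observations
    are ignored.  qual is the phred of 1 - posterior(argmax).  With
    ``mask_transitions`` C<->T / G<->A SNP sites are skipped entirely
    (removing potential deamination artifacts).
    """
    if not pileup:
        raise ValueError("empty pileup")
    out: list[GenotypeCall] = []
    lp = {
        "hom_ref": (math.log(1 - err), math.log(err)),
        "het": (math.log(0.5), math.log(0.5)),
        "hom_alt": (math.log(err), math.log(1 - err)),
    }
    for key in sorted(pileup):
        col = pileup[key]
        rec = col.site
        if mask_transitions and rec.is_transition():
            continue
        n_ref = col.ad_ref
        n_alt = col.ad_alt
        depth = col.depth
        if n_ref + n_alt == 0:
            out.append(GenotypeCall(rec, "no_call", float("nan"), depth, 0, 0))
            continue
        logl = np.array(
            [lp[g][0] * n_ref + lp[g][1] * n_alt for g in GENOTYPES], dtype=float
        )
        post = np.exp(logl - logl.max())
        post /= post.sum()
        g_i = int(np.argmax(post))
        p_err = max(1.0 - float(post[g_i]), 1e-300)
        qual = min(-10.0 * math.log10(p_err), 1000.0)
        out.append(GenotypeCall(rec, GENOTYPES[g_i], qual, depth, n_ref, n_alt))
    return out


def downsample_alignments(alignments, fraction: float, seed: int = 0) -> np.ndarray:
    """Per-read Bernoulli retention mask (seeded)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(alignments) if hasattr(alignments, "__len__") else len(list(alignments))
    if fraction == 1.0:
        return np.ones(n, dtype=bool)
    rng = rng_stream(seed, "downsample")
    return rng.random(n) < fraction


def het_recovery(
    full_calls: list[GenotypeCall],
    down_calls: list[GenotypeCall],
    site_class: str = "snp",
    qual_min: float = 30.0,
) -> float:
    """Fraction of full-coverage heterozygotes recovered after downsampling.

    For SNPs the comparison is restricted to transversions (deamination
    artifacts look like transitions).  Both call sets must cover the same
    panel.
    """
    if site_class not in ("snp", "indel"):
        raise ValueError("site_class must be 'snp' or 'indel'")

    def het_keys(calls: list[GenotypeCall]) -> set:
        keys = set()
        for c in calls:
            rec = c.site
            if site_class == "snp":
                if rec.vtype != "snp" or rec.is_transition():
                    continue
            elif rec.vtype == "snp":
                continue
            if c.genotype == "het" and c.qual >= qual_min:
                keys.add(rec.key)
        return keys

    full = het_keys(full_calls)
    if not full:
        raise ValueError("no qualifying heterozygous sites at full coverage")
    down = het_keys(down_calls)
    return len(full & down) / len(full)


def pseudo_haploid_calls(pileup: Pileup, seed: int = 0) -> dict[tuple[str, int], str]:
    """One uniformly sampled read allele per covered site (ref/alt only)."""
    rng = rng_stream(seed, "pseudo-haploid")
    out: dict[tuple[str, int], str] = {}
    for key in sorted(pileup):
        col = pileup[key]
        alleles = [e[1] for e in col.entries if e[1] in ("ref", "alt")]
        if alleles:
            out[key] = alleles[int(rng.integers(0, len(alleles)))]
    return out


def indel_support_by_length(pileup: Pileup, panel: VariantPanel) -> pd.DataFrame:
    """Mean alternate-allele read depth per indel length.

    One row per distinct |len(ref) - len(alt)| present in the panel, with
    the mean and total alternate-supporting depth over indel sites.
    """
    rows: dict[int, list[int]] = {}
    for rec in panel:
        if rec.vtype == "snp":
            continue
        col = pileup.get(rec.key)
        rows.setdefault(rec.indel_len, []).append(col.ad_alt if col else 0)
    data = [
        {
            "indel_len": ln,
            "n_sites": len(v),
            "mean_ad_alt": float(np.mean(v)),
            "total_ad_alt": int(np.sum(v)),
        }
        for ln, v in sorted(rows.items())
    ]
    return pd.DataFrame(data, columns=["indel_len", "n_sites", "mean_ad_alt", "total_ad_alt"])
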