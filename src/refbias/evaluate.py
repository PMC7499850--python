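"""Scoring alignments against simulation truth.

Produces the headline statistics of the analysis: per-condition sensitivity
for reference- and alternate-allele reads, the alternate-allele fraction of
mapped reads with its Wald 95% CI, placement-error rates per million mapped
reads, damage-response regressions, contaminant false-mapping rates and
terminal misincorporation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aligners import Alignment, AlignmentTable
from .damage import SimulatedRead
from .synth import ReferenceGenome
from .util import encode_dna


@dataclass
class BiasReport:
    """Fig-2-style per-condition summary of allele representation."""

    condition: str
    n_ref_reads: int
    n_alt_reads: int
    n_ref_mapped: int
    n_alt_mapped: int
    n_ref_correct: int
    n_alt_correct: int
    sensitivity_ref: float
    sensitivity_alt: float
    alt_fraction: float
    alt_fraction_ci95: tuple[float, float]
    err_per_million_ref: float
    err_per_million_alt: float
    undefined: bool = False  # zero mapped reads

    def as_row(self) -> dict:
        d = self.__dict__.copy()
        lo, hi = d.pop("alt_fraction_ci95")
        d["alt_ci_lo"], d["alt_ci_hi"] = lo, hi
        return d


def _columns(alignments) -> tuple[np.ndarray, ...]:
    """(mapped, chrom list, pos, strand_rev, mapq, lead_clip, m_bases) columns."""
    if isinstance(alignments, AlignmentTable):
        t = alignments
        return t.mapped, t.chroms, t.pos, t.strand, t.mapq, t.lead_clip, t.m_bases
    alns = list(alignments)
    n = len(alns)
    mapped = np.array([a.mapped for a in alns], dtype=bool)
    chroms = [a.chrom for a in alns]
    pos = np.array([a.pos if a.mapped else -1 for a in alns], dtype=np.int64)
    strand = np.array([a.strand == "-" for a in alns], dtype=bool)
    mapq = np.array([a.mapq for a in alns], dtype=np.int32)
    clip = np.array([a.lead_clip if a.mapped else 0 for a in alns], dtype=np.int32)
    mb = np.array([a.m_bases if a.mapped else 0 for a in alns], dtype=np.int32)
    return mapped, chroms, pos, strand, mapq, clip, mb


def assess_read_placement(aln: Alignment, truth: SimulatedRead) -> str:
    """'correct', 'incorrect' or 'unmapped' for one alignment.

    The adjusted origin is the reported position minus the leading softclip;
    a placement is correct when it equals the truth start with matching
    chromosome and strand and at least half the read is in M state (the
    "major part" rule).
    """
    if truth is None:
        raise ValueError(f"missing truth record for {aln.read_id}")
    if not aln.mapped:
        return "unmapped"
    adjusted = aln.pos - aln.lead_clip
    ok = (
        aln.chrom == truth.chrom
        and aln.strand == truth.strand
        and adjusted == truth.ref_start
        and aln.m_bases * 2 >= len(truth.sequence)
    )
    return "correct" if ok else "incorrect"


def assess_placements(alignments, truths: list[SimulatedRead]) -> np.ndarray:
    """Vectorised placement assessment: 0 correct, 1 incorrect, 2 unmapped."""
    mapped, chroms, pos, strand, _, clip, mb = _columns(alignments)
    n = len(truths)
    out = np.full(n, 2, dtype=np.int8)
    t_start = np.array([t.ref_start for t in truths], dtype=np.int64)
    t_strand = np.array([t.strand == "-" for t in truths], dtype=bool)
    t_len = np.array([len(t.sequence) for t in truths], dtype=np.int32)
    same_chrom = np.array(
        [mapped[i] and chroms[i] == truths[i].chrom for i in range(n)], dtype=bool
    )
    good = (
        same_chrom
        & (strand == t_strand)
        & (pos - clip == t_start)
        & (mb * 2 >= t_len)
    )
    out[mapped & good] = 0
    out[mapped & ~good] = 1
    return out


def bias_report(
    alignments, truths: list[SimulatedRead], mapq_min: int, condition: str = ""
) -> BiasReport:
    """Per-condition sensitivity / allele balance / error-rate summary.

    Only reads with mapq >= mapq_min count as mapped.  The CI on the
    alternate-allele fraction is the Wald binomial interval over pooled
    reads; error rates are incorrect placements per million mapped reads of
    each allele class.
    """
    mapped, _, _, _, mapq, _, _ = _columns(alignments)
    verdict = assess_placements(alignments, truths)
    passed = mapped & (mapq >= mapq_min)
    is_alt = np.array([t.carried_allele == "alt" for t in truths], dtype=bool)
    is_ref = np.array([t.carried_allele == "ref" for t in truths], dtype=bool)

    n_ref, n_alt = int(is_ref.sum()), int(is_alt.sum())
    ref_m = int((passed & is_ref).sum())
    alt_m = int((passed & is_alt).sum())
    ref_bad = int((passed & is_ref & (verdict == 1)).sum())
    alt_bad = int((passed & is_alt & (verdict == 1)).sum())

    total = ref_m + alt_m
    undefined = total == 0
    f = alt_m / total if total else float("nan")
    if total:
        half = 1.96 * float(np.sqrt(max(f * (1 - f), 0.0) / total))
        ci = (f - half, f + half)
    else:
        ci = (float("nan"), float("nan"))
    return BiasReport(
        condition=condition,
        n_ref_reads=n_ref,
        n_alt_reads=n_alt,
        n_ref_mapped=ref_m,
        n_alt_mapped=alt_m,
        n_ref_correct=ref_m - ref_bad,
        n_alt_correct=alt_m - alt_bad,
        sensitivity_ref=ref_m / n_ref if n_ref else float("nan"),
        sensitivity_alt=alt_m / n_alt if n_alt else float("nan"),
        alt_fraction=f,
        alt_fraction_ci95=ci,
        err_per_million_ref=1e6 * ref_bad / ref_m if ref_m else 0.0,
        err_per_million_alt=1e6 * alt_bad / alt_m if alt_m else 0.0,
        undefined=undefined,
    )


def sensitivity_by_damage(
    damage_rates, reports: list[BiasReport]
) -> dict[str, dict[str, float]]:
    """Per-allele OLS of mapped percentage against deamination rate.

    Returns {'ref': {...}, 'alt': {...}} with slope (percentage points per
    unit rate), intercept, r2 and the slope's standard error.
    """
    if len(reports) < 3:
        raise ValueError("need at least three damage levels for a regression")
    x = np.asarray(damage_rates, dtype=float)
    out: dict[str, dict[str, float]] = {}
    for allele in ("ref", "alt"):
        y = np.array(
            [getattr(r, f"sensitivity_{allele}") * 100.0 for r in reports], dtype=float
        )
        res = sps.linregress(x, y)
        out[allele] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r2": float(res.rvalue**2),
            "slope_se": float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        }
    return out


def contaminant_mapping_rate(
    contaminant_reads: list[SimulatedRead],
    aligner,
    mapq_min: int,
) -> pd.DataFrame:
    """Fraction of contaminant reads mapped (at mapq >= mapq_min) per length."""
    if not contaminant_reads:
        return pd.DataFrame(columns=["read_len", "n", "n_mapped", "rate"])
    tab = aligner.align_batch(contaminant_reads)
    mapped, _, _, _, mapq, _, _ = _columns(tab)
    ok = mapped & (mapq >= mapq_min)
    lens = np.array([len(r.sequence) for r in contaminant_reads])
    rows = []
    for L in sorted(set(lens.tolist())):
        m = lens == L
        rows.append(
            {"read_len": L, "n": int(m.sum()), "n_mapped": int(ok[m].sum()),
             "rate": float(ok[m].mean())}
        )
    return pd.DataFrame(rows)


def damage_profile(
    alignments, reads: list[SimulatedRead], ref: ReferenceGenome, max_pos: int = 25
) -> pd.DataFrame:
    """Observed C->T (5') and G->A (3') rates by position from each read end.

    Counts are restricted to M-aligned bases (softclips excluded) of mapped
    reads; the denominator at each position is the number of reference Cs
    (resp. Gs) observed there.  Forward-strand alignments only, matching the
    forward-only exhaustive simulation.
    """
    codes = {c: encode_dna(ref[c]) for c in ref.chroms}
    c5 = np.zeros(max_pos, dtype=np.int64)  # ref C at 5' offset i
    t5 = np.zeros(max_pos, dtype=np.int64)  # .. read T
    g3 = np.zeros(max_pos, dtype=np.int64)
    a3 = np.zeros(max_pos, dtype=np.int64)
    it = alignments if isinstance(alignments, AlignmentTable) else list(alignments)
    for i, truth in enumerate(reads):
        aln = it[i]
        if not aln.mapped or aln.strand == "-":
            continue
        rd = encode_dna(truth.sequence)
        L = len(rd)
        rp, ro = aln.pos, 0
        ref_arr = codes[aln.chrom]
        for op, ln in aln.cigar:
            if op in ("S", "I"):
                ro += ln
            elif op == "D":
                rp += ln
            else:  # M
                for k in range(ln):
                    rb = ref_arr[rp + k]
                    qb = rd[ro + k]
                    p5 = ro + k
                    p3 = L - 1 - (ro + k)
                    if rb == 1 and p5 < max_pos:  # ref C
                        c5[p5] += 1
                        if qb == 3:
                            t5[p5] += 1
                    if rb == 2 and p3 < max_pos:  # ref G
                        g3[p3] += 1
                        if qb == 0:
                            a3[p3] += 1
                rp += ln
                ro += ln
    with np.errstate(invalid="ignore", divide="ignore"):
        return pd.DataFrame(
            {
                "position": np.arange(max_pos),
                "n_ref_C_5p": c5,
                "ct_rate_5p": np.where(c5 > 0, t5 / np.maximum(c5, 1), np.nan),
                "n_ref_G_3p": g3,
                "ga_rate_3p": np.where(g3 > 0, a3 / np.maximum(g3, 1), np.nan),
            }
        )
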