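"""Two published reference-bias mitigation workflows.

Both operate on linear-reference alignments over a biallelic SNP panel:

* modified reads: every aligned read overlapping a panel SNP is duplicated
  with the allele flipped and realigned; the original is kept only if the
  flipped copy maps to exactly the same (chrom, pos, strand).
* alternate-reference merging: reads are aligned both to the reference and
  to a copy with every panel SNP substituted by its alternate allele;
  per read, one copy is kept at random when both agree on coordinates,
  the single mapped copy when only one maps, and nothing when they
  disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import ReferenceGenome, VariantPanel, VariantRecord
from .util import rng_stream
from .aligners import Alignment, AlignmentTable, LinearAligner


@dataclass
class DebiasStats:
    n_input: int = 0
    n_no_snp: int = 0
    n_kept: int = 0
    n_copy_displaced: int = 0
    n_copy_unmapped: int = 0
    n_not_modifiable: int = 0
    n_discordant: int = 0  # alt_ref_merge: mapped to different coordinates
    n_rescued: int = 0  # alt_ref_merge: mapped only to the alternate reference


def _read_offset_of(aln: Alignment, ref_pos: int) -> int | None:
    """Read offset aligned (M) to ``ref_pos``; None if under S/I/D."""
    rp = aln.pos
    ro = 0
    for op, ln in aln.cigar:
        if op == "S" or op == "I":
            ro += ln
        elif op == "D":
            if rp <= ref_pos < rp + ln:
                return None
            rp += ln
        else:  # M
            if rp <= ref_pos < rp + ln:
                return ro + (ref_pos - rp)
            rp += ln
            ro += ln
    return None


def modify_read_allele(
    read_seq: str, read_alignment: Alignment, variant: VariantRecord
) -> str | None:
    """Copy of ``read_seq`` with the base at the SNP flipped ref<->alt.

    Returns None when the read is not modifiable: the variant position is
    not under an M operation, or the read base matches neither panel allele
    (e.g. a deamination artifact at the site).
    """
    if variant.vtype != "snp":
        raise ValueError("read modification is defined for biallelic SNPs only")
    off = _read_offset_of(read_alignment, variant.start0)
    if off is None:
        return None
    base = read_seq[off]
    if base == variant.ref_allele:
        new = variant.alt_allele
    elif base == variant.alt_allele:
        new = variant.ref_allele
    else:
        return None
    return read_seq[:off] + new + read_seq[off + 1 :]


def _snp_lookup(panel: VariantPanel):
    by_chrom: dict[str, tuple[np.ndarray, list[VariantRecord]]] = {}
    for chrom in {r.chrom for r in panel}:
        recs = [r for r in panel if r.chrom == chrom and r.vtype == "snp"]
        by_chrom[chrom] = (np.asarray([r.start0 for r in recs]), recs)
    return by_chrom


def modified_read_filter(
    alignments,
    reads,
    panel: VariantPanel,
    aligner: LinearAligner,
) -> tuple[np.ndarray, DebiasStats]:
    """Keep mask over ``alignments`` after the duplicate-flip-realign test.

    ``alignments`` must come from ``aligner`` (same parameters) over the
    same ``reads``.  Reads overlapping no panel SNP are kept unconditionally;
    reads whose flipped copy is unmapped, displaced, or cannot be
    constructed are dropped.
    """
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    alns = list(alignments) if not isinstance(alignments, AlignmentTable) else alignments
    n = len(seqs)
    stats = DebiasStats(n_input=n)
    lookup = _snp_lookup(panel)
    keep = np.zeros(n, dtype=bool)

    mod_seqs: list[str] = []
    mod_rows: list[int] = []
    originals: list[Alignment] = []
    for i in range(n):
        aln = alns[i]
        if not aln.mapped:
            continue
        chrom = aln.chrom
        pos_arr, recs = lookup.get(chrom, (np.empty(0), []))
        lo = int(np.searchsorted(pos_arr, aln.pos))
        hi = int(np.searchsorted(pos_arr, aln.end_pos))
        if lo == hi:
            keep[i] = True
            stats.n_no_snp += 1
            continue
        seq = seqs[i]
        modified = seq
        ok = True
        for rec in recs[lo:hi]:
            out = modify_read_allele(modified, aln, rec)
            if out is None:
                ok = False
                break
            modified = out
        if not ok:
            stats.n_not_modifiable += 1
            continue
        mod_seqs.append(modified)
        mod_rows.append(i)
        originals.append(aln)

    if mod_rows:
        copies = aligner.align_batch(mod_seqs)
        for k, i in enumerate(mod_rows):
            orig = originals[k]
            if not copies.mapped[k]:
                stats.n_copy_unmapped += 1
            elif (
                copies.chroms[k] == orig.chrom
                and int(copies.pos[k]) == orig.pos
                and ("-" if copies.strand[k] else "+") == orig.strand
            ):
                keep[i] = True
            else:
                stats.n_copy_displaced += 1
    stats.n_kept = int(keep.sum())
    return keep, stats


def build_alt_reference(ref: ReferenceGenome, panel: VariantPanel) -> ReferenceGenome:
    """Reference copy with every panel SNP substituted by its alternate."""
    seqs = {c: bytearray(ref[c], "ascii") for c in ref.chroms}
    for rec in panel:
        if rec.vtype != "snp":
            raise ValueError(
                "alternate-reference construction is defined for SNP-only panels"
            )
        if seqs[rec.chrom][rec.start0 : rec.start0 + 1].decode() != rec.ref_allele:
            raise ValueError(f"panel/reference mismatch at {rec.chrom}:{rec.pos}")
        seqs[rec.chrom][rec.start0] = ord(rec.alt_allele)
    return ReferenceGenome({c: s.decode("ascii") for c, s in seqs.items()})


def alt_ref_merge(
    reads,
    ref: ReferenceGenome,
    altref: ReferenceGenome,
    params,
    seed: int = 0,
) -> tuple[list[Alignment], DebiasStats]:
    """Align to both references and merge by the published rule.

    Coordinates are directly comparable because both references have equal
    lengths (SNP substitutions only).  The kept read's mapq is the minimum
    of the two copies' (conservative).  Reads mapping to different
    coordinates in the two references are dropped and counted.
    """
    for c in ref.chroms:
        if ref.length(c) != altref.length(c):
            raise ValueError("references differ in length; panel was not SNP-only")
    rng = rng_stream(seed, "alt-ref-merge")
    t_ref = LinearAligner(ref, params).align_batch(reads)
    t_alt = LinearAligner(altref, params).align_batch(reads)
    n = len(t_ref)
    stats = DebiasStats(n_input=n)

    same_chrom = np.asarray(
        [t_ref.chroms[i] == t_alt.chroms[i] for i in range(n)], dtype=bool
    )
    both = t_ref.mapped & t_alt.mapped
    agree = (
        both & same_chrom & (t_ref.pos == t_alt.pos) & (t_ref.strand == t_alt.strand)
    )
    discord = both & ~agree
    only_ref = t_ref.mapped & ~t_alt.mapped
    only_alt = t_alt.mapped & ~t_ref.mapped
    pick_alt = (rng.random(n) < 0.5) & agree

    kept = agree | only_ref | only_alt
    use_alt = pick_alt | only_alt
    mapq = np.where(agree, np.minimum(t_ref.mapq, t_alt.mapq),
                    np.where(use_alt, t_alt.mapq, t_ref.mapq)).astype(np.int32)
    src = [t_alt if use_alt[i] else t_ref for i in range(n)]
    merged = AlignmentTable(
        read_ids=t_ref.read_ids,
        mapped=kept,
        chroms=[src[i].chroms[i] if kept[i] else None for i in range(n)],
        pos=np.where(use_alt, t_alt.pos, t_ref.pos),
        strand=np.where(use_alt, t_alt.strand, t_ref.strand),
        mapq=mapq,
        score=np.where(use_alt, t_alt.score, t_ref.score),
        nm=np.where(use_alt, t_alt.nm, t_ref.nm),
        cigars=[src[i].cigars[i] for i in range(n)],
        n_best=np.where(use_alt, t_alt.n_best, t_ref.n_best),
        n_subopt=np.where(use_alt, t_alt.n_subopt, t_ref.n_subopt),
        reasons=["discordant" if discord[i] else None for i in range(n)],
    )
    stats.n_kept = int(kept.sum())
    stats.n_discordant = int(discord.sum())
    stats.n_rescued = int(only_alt.sum())
    return merged, stats
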