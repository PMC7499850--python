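"""Synthetic inputs with known ground truth.

Everything the pipeline consumes is generated here: a haploid reference
genome, a biallelic SNP/indel panel with allele frequencies, a diploid
individual with phased haplotypes and exact coordinate liftover, an
unrelated contaminant genome, and four-population pseudo-haploid call sets
for D-statistics.  All generators are deterministic given a seed.

Coordinates: variant positions are 1-based (VCF convention) at the first
reference-allele base; all internal arithmetic is 0-based half-open and
each boundary-crossing helper says which it uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import BASES, decode_dna, encode_dna, rng_stream

VTYPES = ("snp", "insertion", "deletion")


@dataclass
class ReferenceGenome:
    """Haploid reference: chromosome name -> uppercase DNA string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference must contain at least one sequence")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            if set(seq) - set(BASES):
                raise ValueError(f"sequence {name!r} contains non-ACGT characters")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant, VCF-style left-anchored.

    ``pos`` is the 1-based position of the first reference-allele base.  For
    indels exactly one of ref/alt has length 1 (the shared anchor base).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    maf: float

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("maf outside [0, 1]")
        if self.vtype == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snp alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("snp alleles identical")
        else:
            if min(len(self.ref_allele), len(self.alt_allele)) != 1:
                raise ValueError("indel must be left-anchored (one allele of length 1)")
            if self.ref_allele[0] != self.alt_allele[0]:
                raise ValueError("indel alleles must share the anchor base")

    @property
    def start0(self) -> int:
        """0-based start of the ref-allele interval."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the ref-allele interval."""
        return self.pos - 1 + len(self.ref_allele)

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def is_transition(self) -> bool:
        """C<->T or G<->A SNP (the classes confounded by deamination)."""
        return self.vtype == "snp" and {self.ref_allele, self.alt_allele} in ({"C", "T"}, {"G", "A"})


@dataclass
class VariantPanel:
    """Sorted, non-overlapping biallelic variants."""

    records: list[VariantRecord]

    def __post_init__(self) -> None:
        recs = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        for a, b in zip(recs, recs[1:]):
            if a.chrom == b.chrom and b.start0 < a.end0:
                raise ValueError(f"overlapping variants at {a.chrom}:{a.pos} and {b.chrom}:{b.pos}")
        self.records = recs

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> VariantRecord:
        return self.records[i]

    def validate_against(self, ref: ReferenceGenome) -> None:
        for r in self.records:
            seg = ref[r.chrom][r.start0 : r.end0]
            if seg != r.ref_allele:
                raise ValueError(
                    f"panel/reference mismatch at {r.chrom}:{r.pos}: ref allele "
                    f"{r.ref_allele!r} vs reference {seg!r}"
                )

    def snps(self) -> "VariantPanel":
        return VariantPanel([r for r in self.records if r.vtype == "snp"])

    def indels(self) -> "VariantPanel":
        return VariantPanel([r for r in self.records if r.vtype != "snp"])


def make_reference(
    chrom_lengths: dict[str, int], gc_fraction: float = 0.41, seed: int = 0
) -> ReferenceGenome:
    """I.i.d. random genome with the requested GC content.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2 independently per base.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = rng_stream(seed, "reference")
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    seqs: dict[str, str] = {}
    for name, length in chrom_lengths.items():
        if length < 1000:
            raise ValueError(f"chromosome {name!r} length {length} below minimum 1000")
        codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
        seqs[name] = decode_dna(codes)
    return ReferenceGenome(seqs)


def make_contaminant_genome(length: int, gc_fraction: float = 0.45, seed: int = 0) -> ReferenceGenome:
    """Unrelated single-sequence genome (microbial stand-in).

    Drawn from an RNG stream independent of :func:`make_reference`, so even
    the same seed yields a sequence sharing only chance substrings with the
    target reference.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    if length < 1000:
        raise ValueError(f"contaminant length {length} below minimum 1000")
    rng = rng_stream(seed, "contaminant")
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return ReferenceGenome({"contig1": decode_dna(codes)})


def _maf_spectrum(rng: np.random.Generator, n: int, floor: float) -> np.ndarray:
    # The real panel's frequency spectrum is not pinned down beyond its floor;
    # a Beta(0.8, 2) rescaled to [floor, 0.5] gives the rare-skewed shape
    # typical of site-frequency spectra while keeping every site above floor.
    raw = rng.beta(0.8, 2.0, size=n)
    return floor + raw * (0.5 - floor)


def make_variant_panel(
    ref: ReferenceGenome,
    n_snps: int,
    n_indels: int = 0,
    indel_len_max: int = 18,
    maf_floor: float = 0.001,
    min_spacing: int = 60,
    seed: int = 0,
    edge_margin: int = 120,
) -> VariantPanel:
    """Place non-overlapping biallelic variants on the reference.

    Sites are at least ``min_spacing`` apart (anchor to anchor) and at least
    ``edge_margin`` from chromosome ends so that fixed-length reads spanning
    any site stay inside the chromosome.  Indel lengths are uniform on
    [1, indel_len_max]; insertions and deletions are equally likely.
    """
    n_total = n_snps + n_indels
    if n_total <= 0:
        return VariantPanel([])
    if min_spacing <= indel_len_max + 1:
        raise ValueError("min_spacing must exceed indel_len_max + 1 to forbid overlap")
    rng = rng_stream(seed, "panel")

    capacity = {
        c: max(0, (ref.length(c) - 2 * edge_margin) // min_spacing) for c in ref.chroms
    }
    if sum(capacity.values()) < n_total:
        raise ValueError(
            f"cannot place {n_total} variants at spacing {min_spacing}: "
            f"capacity is {sum(capacity.values())}"
        )

    # allocate counts per chromosome proportional to capacity
    chroms = ref.chroms
    counts = {c: 0 for c in chroms}
    weights = np.array([capacity[c] for c in chroms], dtype=float)
    for idx in rng.choice(len(chroms), size=n_total, p=weights / weights.sum()):
        c = chroms[idx]
        if counts[c] >= capacity[c]:  # spill into any chromosome with room
            c = next(cc for cc in chroms if counts[cc] < capacity[cc])
        counts[c] += 1

    positions: list[tuple[str, int]] = []  # (chrom, 0-based anchor)
    for c in chroms:
        k = counts[c]
        if k == 0:
            continue
        span = ref.length(c) - 2 * edge_margin - (k - 1) * min_spacing
        offs = np.sort(rng.integers(0, span, size=k))
        anchors = edge_margin + offs + np.arange(k) * min_spacing
        positions.extend((c, int(a)) for a in anchors)

    is_snp = np.zeros(n_total, dtype=bool)
    is_snp[rng.permutation(n_total)[:n_snps]] = True
    mafs = _maf_spectrum(rng, n_total, maf_floor)

    records: list[VariantRecord] = []
    for i, (chrom, a0) in enumerate(positions):
        seq = ref[chrom]
        anchor = seq[a0]
        if is_snp[i]:
            alt = BASES[(encode_dna(anchor)[0] + rng.integers(1, 4)) % 4]
            rec = VariantRecord(chrom, a0 + 1, anchor, alt, "snp", float(mafs[i]))
        else:
            ilen = int(rng.integers(1, indel_len_max + 1))
            if rng.random() < 0.5:  # deletion: ref = anchor + deleted bases
                rec = VariantRecord(
                    chrom, a0 + 1, seq[a0 : a0 + 1 + ilen], anchor, "deletion", float(mafs[i])
                )
            else:  # insertion: alt = anchor + novel bases
                ins = decode_dna(rng.integers(0, 4, size=ilen).astype(np.uint8))
                rec = VariantRecord(chrom, a0 + 1, anchor, anchor + ins, "insertion", float(mafs[i]))
        records.append(rec)

    panel = VariantPanel(records)
    panel.validate_against(ref)
    return panel


class Liftover:
    """Piecewise-linear haplotype -> reference coordinate map (0-based).

    Segments are maximal runs where the haplotype copies the reference with a
    constant offset (slope 1).  Haplotype bases inside insertion alleles have
    no reference image; they form slope-0 segments mapping to the position of
    the next reference base.
    """

    def __init__(
        self,
        hap_starts: np.ndarray,
        ref_starts: np.ndarray,
        slopes: np.ndarray,
        hap_len: int,
        ref_len: int,
    ):
        self.hap_starts = hap_starts  # segment start in haplotype coords
        self.ref_starts = ref_starts  # corresponding reference coord (or next ref base)
        self.slopes = slopes  # 1 for copied segments, 0 inside insertions
        self.hap_len = hap_len
        self.ref_len = ref_len

    def _segment(self, hp: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.hap_starts, hp, side="right") - 1

    def hap_to_ref(self, hap_pos: int | np.ndarray) -> np.ndarray:
        """Reference position(s) of haplotype position(s); vectorised."""
        hp = np.atleast_1d(np.asarray(hap_pos, dtype=np.int64))
        if hp.size and (hp.min() < 0 or hp.max() >= self.hap_len):
            raise IndexError("haplotype position out of range")
        seg = self._segment(hp)
        return self.ref_starts[seg] + self.slopes[seg] * (hp - self.hap_starts[seg])

    def interval_to_ref(self, start: int, end: int) -> tuple[int, int]:
        """Reference span [start, end) of a half-open haplotype interval.

        For an interval whose last base sits inside an insertion allele, the
        span ends at the insertion point (no reference base is consumed).
        """
        if not 0 <= start < end <= self.hap_len:
            raise IndexError("bad haplotype interval")
        r0 = int(self.hap_to_ref(start)[0])
        last = np.asarray([end - 1], dtype=np.int64)
        seg = int(self._segment(last)[0])
        if self.slopes[seg] == 0:
            r1 = int(self.ref_starts[seg])
        else:
            r1 = int(self.hap_to_ref(end - 1)[0]) + 1
        return r0, max(r1, r0)


@dataclass
class DiploidSample:
    """Diploid individual: genotypes over a panel plus the implied haplotypes.

    Phase convention: at heterozygous sites haplotype A carries the reference
    allele and haplotype B the alternate.  Allele-balance statistics are
    phase-invariant, and the fixed convention keeps truth bookkeeping exact.
    """

    panel: VariantPanel
    genotypes: dict[tuple[str, int], str]  # (chrom, pos) -> hom_ref | het | hom_alt
    haplotypes: dict[str, tuple[str, str]] = field(repr=False)
    liftovers: dict[tuple[str, int], Liftover] = field(repr=False)

    def genotype(self, rec: VariantRecord) -> str:
        return self.genotypes[rec.key]

    def het_sites(self) -> list[VariantRecord]:
        return [r for r in self.panel if self.genotypes[r.key] == "het"]


def _apply_alleles(
    ref_seq: str, records: list[VariantRecord], carry_alt: list[bool]
) -> tuple[str, Liftover]:
    """Splice alt alleles into a reference chromosome; build the liftover."""
    parts: list[str] = []
    hap_starts = [0]
    ref_starts = [0]
    slopes = [1]
    hap_pos = 0
    ref_pos = 0
    for rec, alt in zip(records, carry_alt):
        if not alt:
            continue
        # copy reference up to and including the anchor base
        a0 = rec.start0
        chunk = ref_seq[ref_pos : a0 + 1]
        parts.append(chunk)
        hap_pos += len(chunk)
        ref_pos = a0 + 1
        if rec.vtype == "snp":
            parts[-1] = parts[-1][:-1] + rec.alt_allele
        elif rec.vtype == "insertion":
            ins = rec.alt_allele[1:]
            parts.append(ins)
            # inserted bases: slope-0 segment pointing at the next ref base
            hap_starts.append(hap_pos)
            ref_starts.append(ref_pos)
            slopes.append(0)
            hap_pos += len(ins)
            hap_starts.append(hap_pos)
            ref_starts.append(ref_pos)
            slopes.append(1)
        else:  # deletion: skip deleted reference bases
            ref_pos += len(rec.ref_allele) - 1
            hap_starts.append(hap_pos)
            ref_starts.append(ref_pos)
            slopes.append(1)
    parts.append(ref_seq[ref_pos:])
    hap = "".join(parts)
    lift = Liftover(
        np.asarray(hap_starts, dtype=np.int64),
        np.asarray(ref_starts, dtype=np.int64),
        np.asarray(slopes, dtype=np.int64),
        len(hap),
        len(ref_seq),
    )
    return hap, lift


def make_diploid_sample(
    ref: ReferenceGenome,
    panel: VariantPanel,
    het_rate: float = 0.5,
    hom_alt_rate: float = 0.25,
    seed: int = 0,
) -> DiploidSample:
    if het_rate < 0 or hom_alt_rate < 0 or het_rate + hom_alt_rate > 1:
        raise ValueError("het_rate and hom_alt_rate must be non-negative and sum to <= 1")
    rng = rng_stream(seed, "diploid")
    genotypes: dict[tuple[str, int], str] = {}
    for rec in panel:
        u = rng.random()
        if u < het_rate:
            g = "het"
        elif u < het_rate + hom_alt_rate:
            g = "hom_alt"
        else:
            g = "hom_ref"
        genotypes[rec.key] = g

    haplotypes: dict[str, tuple[str, str]] = {}
    liftovers: dict[tuple[str, int], Liftover] = {}
    for chrom in ref.chroms:
        recs = [r for r in panel if r.chrom == chrom]
        # hap A: alt only at hom_alt; hap B: alt at het and hom_alt
        alt_a = [genotypes[r.key] == "hom_alt" for r in recs]
        alt_b = [genotypes[r.key] in ("het", "hom_alt") for r in recs]
        hap_a, lift_a = _apply_alleles(ref[chrom], recs, alt_a)
        hap_b, lift_b = _apply_alleles(ref[chrom], recs, alt_b)
        haplotypes[chrom] = (hap_a, hap_b)
        liftovers[(chrom, 0)] = lift_a
        liftovers[(chrom, 1)] = lift_b
    return DiploidSample(panel, genotypes, haplotypes, liftovers)


@dataclass
class PopulationQuartet:
    """Pseudo-haploid allele matrix for four populations over panel sites.

    ``alleles`` has shape (4, n_sites) with 0 = reference allele,
    1 = alternate allele, -1 = missing.  Row 3 (P4) is the outgroup and
    carries the ancestral allele at every site.
    """

    alleles: np.ndarray
    ancestral: np.ndarray  # per-site ancestral allele, 0 = ref, 1 = alt
    site_keys: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if self.alleles.shape[0] != 4:
            raise ValueError("quartet requires exactly four populations")
        if not np.isin(self.alleles, (-1, 0, 1)).all():
            raise ValueError("alleles must be 0 (ref), 1 (alt) or -1 (missing)")


def make_population_quartet(
    panel: VariantPanel,
    branch_drift: tuple[float, float, float, float] = (0.02, 0.02, 0.1, 0.0),
    bias_toward_ref: float = 0.0,
    seed: int = 0,
) -> PopulationQuartet:
    """Balding-Nichols style quartet with optional reference-biased calling on P1.

    Per site an ancestral allele (ref or alt, equally likely) and a root
    derived-allele frequency p ~ U(0.05, 0.95) are drawn; each of P1..P3
    drifts independently with its Balding-Nichols F, and one pseudo-haploid
    allele per population is sampled from the drifted frequency.  P4 is fixed
    to the ancestral allele (outgroup).  ``bias_toward_ref`` then flips each
    alternate allele of P1 to reference with that probability, modelling a
    reference-biased caller.
    """
    drifts = np.asarray(branch_drift, dtype=float)
    if drifts.shape != (4,) or (drifts < 0).any() or (drifts >= 1).any():
        raise ValueError("branch_drift must be four values in [0, 1)")
    if not 0.0 <= bias_toward_ref <= 1.0:
        raise ValueError("bias_toward_ref must be in [0, 1]")
    rng = rng_stream(seed, "quartet")
    n = len(panel)
    if n == 0:
        raise ValueError("empty panel")

    ancestral = (rng.random(n) < 0.5).astype(np.int8)
    p_derived = rng.uniform(0.05, 0.95, size=n)
    # alt-allele frequency at the root
    alt_root = np.where(ancestral == 0, p_derived, 1.0 - p_derived)

    alleles = np.empty((4, n), dtype=np.int8)
    for i in range(3):
        f = drifts[i]
        if f == 0.0:
            q = alt_root
        else:
            a = alt_root * (1 - f) / f
            b = (1 - alt_root) * (1 - f) / f
            q = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
        alleles[i] = (rng.random(n) < q).astype(np.int8)
    alleles[3] = ancestral

    if bias_toward_ref > 0:
        flip = (alleles[0] == 1) & (rng.random(n) < bias_toward_ref)
        alleles[0, flip] = 0

    return PopulationQuartet(alleles, ancestral, [r.key for r in panel])
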