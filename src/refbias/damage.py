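"""Read simulation with ancient-DNA post-mortem damage.

Two read sources are provided: an exhaustive enumeration of every placement
of a fixed-length read over each panel site (half carrying the alternate
allele), and coverage-based shotgun sampling from a diploid individual with
optional contaminant admixture.  Terminal deamination is applied to either
source as independent per-base Bernoulli events: C->T with probability
``d5[i]`` at distance i from the 5' end and G->A with probability ``d3[j]``
at distance j from the 3' end (double-strand library model; a single-strand
mode applies C->T at both ends).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synth import DiploidSample, ReferenceGenome, VariantPanel
from .util import encode_dna, decode_dna, revcomp, rng_stream

logger = logging.getLogger(__name__)

_C, _G, _T, _A = 1, 2, 3, 0


@dataclass
class DamageModel:
    """Per-position terminal misincorporation probabilities.

    ``d5[i]`` is the C->T probability at read position i from the 5' end,
    ``d3[j]`` the G->A probability at position j from the 3' end.  Positions
    beyond the stored vectors fall back to ``d_background``.
    """

    d5: np.ndarray
    d3: np.ndarray
    d_background: float = 0.0

    def __post_init__(self) -> None:
        self.d5 = np.asarray(self.d5, dtype=float)
        self.d3 = np.asarray(self.d3, dtype=float)
        for v in (self.d5, self.d3):
            if v.ndim != 1 or v.size == 0:
                raise ValueError("profiles must be non-empty vectors")
            if (v < 0).any() or (v > 1).any():
                raise ValueError("damage probabilities must lie in [0, 1]")
        if not 0.0 <= self.d_background <= 1.0:
            raise ValueError("d_background must lie in [0, 1]")

    @classmethod
    def exponential(
        cls,
        d_max: float = 1.0,
        lambda_decay: float = 0.75,
        d_background: float = 0.01,
        length: int = 100,
    ) -> "DamageModel":
        """Exponential-decay profile d5[i] = bg + (d_max - bg) * lambda**i.

        With the default ``d_max = 1`` the ``rate_scale`` argument of
        :func:`apply_deamination` equals the terminal deamination rate
        directly (0.2 -> 20% C->T at the first base).
        """
        if not 0.0 < lambda_decay < 1.0:
            raise ValueError("lambda_decay must be in (0, 1)")
        if not 0.0 <= d_background <= d_max <= 1.0:
            raise ValueError("require 0 <= d_background <= d_max <= 1")
        i = np.arange(length)
        d5 = d_background + (d_max - d_background) * lambda_decay**i
        return cls(d5, d5.copy(), d_background)

    @classmethod
    def from_tsv(cls, path5: str, path3: str, d_background: float = 0.0) -> "DamageModel":
        """Load per-position profiles from two-column position/rate tables
        (the mapDamage misincorporation dialect: 0-based position, rate)."""
        vecs = []
        for path in (path5, path3):
            tab = np.loadtxt(path, dtype=float, ndmin=2)
            if tab.shape[1] < 2:
                raise ValueError(f"{path}: expected two columns (position, rate)")
            order = np.argsort(tab[:, 0])
            vecs.append(tab[order, 1])
        return cls(vecs[0], vecs[1], d_background)

    def profile_for_length(self, read_len: int, rate_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Scaled (d5, d3) vectors padded with the background rate."""

        def pad(v: np.ndarray) -> np.ndarray:
            if len(v) >= read_len:
                return v[:read_len]
            return np.concatenate([v, np.full(read_len - len(v), self.d_background)])

        d5 = pad(self.d5) * rate_scale
        d3 = pad(self.d3) * rate_scale
        if (d5 > 1).any() or (d3 > 1).any():
            raise ValueError("rate_scale pushes a damage probability above 1")
        return d5, d3


@dataclass(slots=True)
class SimulatedRead:
    """A read plus the ground truth needed for bias accounting.

    ``ref_start``/``ref_end`` are the 0-based half-open reference-coordinate
    span of the originating fragment (longer than the read over a deletion
    allele, shorter over an insertion).
    """

    read_id: str
    sequence: str
    source: str = "target"  # target | contaminant
    chrom: str = ""
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    site_id: str | None = None
    carried_allele: str | None = None  # ref | alt | None
    damage_positions: list[int] = field(default_factory=list)
    qual: int = 30  # constant base quality

    def __len__(self) -> int:
        return len(self.sequence)


def enumerate_site_reads(
    ref: ReferenceGenome,
    panel: VariantPanel,
    read_len: int = 50,
    both_strands: bool = False,
) -> list[SimulatedRead]:
    """All placements of a ``read_len`` read spanning each panel site.

    For a SNP every placement fully containing the site is emitted twice,
    once with the reference and once with the alternate allele (read_len
    placements each).  For indels every placement containing the complete
    allele plus at least one anchoring base on each side is emitted.  The
    enumeration is deterministic and forward-strand by default;
    ``both_strands`` adds reverse-complement duplicates.
    """
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    reads: list[SimulatedRead] = []
    for rec in panel:
        seq = ref[rec.chrom]
        L = len(seq)
        p0 = rec.start0
        site_id = f"{rec.chrom}:{rec.pos}"
        glen = rec.indel_len

        if rec.vtype == "snp":
            # every placement fully containing the site
            starts = range(p0 - read_len + 1, p0 + 1)
            ref_windows = [(s, seq[s : s + read_len]) for s in starts]
            alt_windows = [
                (s, w[: p0 - s] + rec.alt_allele + w[p0 - s + 1 :]) for s, w in ref_windows
            ]
            spans = {"ref": read_len, "alt": read_len}
        elif rec.vtype == "deletion":
            # alt haplotype lacks the deleted bases; coordinates left of the
            # junction coincide with reference coordinates
            alt_hap = seq[: p0 + 1] + seq[p0 + 1 + glen :]
            # ref reads contain the full ref allele [p0, p0+1+glen) + 1 anchor each side
            ref_windows = [
                (s, seq[s : s + read_len])
                for s in range(p0 + glen + 2 - read_len, p0)
            ]
            # alt reads contain the anchor + >=1 base past the junction
            alt_windows = [
                (s, alt_hap[s : s + read_len]) for s in range(p0 + 2 - read_len, p0)
            ]
            spans = {"ref": read_len, "alt": read_len + glen}
        else:  # insertion
            ins = rec.alt_allele[1:]
            alt_hap = seq[: p0 + 1] + ins + seq[p0 + 1 :]
            # ref reads contain the anchor base + 1 each side
            ref_windows = [(s, seq[s : s + read_len]) for s in range(p0 + 2 - read_len, p0)]
            # alt allele occupies [p0, p0+glen+1) in insertion-haplotype coords
            alt_windows = [
                (s, alt_hap[s : s + read_len]) for s in range(p0 + glen + 2 - read_len, p0)
            ]
            spans = {"ref": read_len, "alt": read_len - glen}

        skipped = False
        for allele, windows in (("ref", ref_windows), ("alt", alt_windows)):
            for s, w in windows:
                if s < 0 or len(w) < read_len:
                    skipped = True
                    continue
                ref_span = spans[allele]
                rd = SimulatedRead(
                    read_id=f"{site_id}:{allele}:{s}",
                    sequence=w,
                    chrom=rec.chrom,
                    ref_start=s,
                    ref_end=s + ref_span,
                    site_id=site_id,
                    carried_allele=allele,
                )
                reads.append(rd)
                if both_strands:
                    reads.append(
                        SimulatedRead(
                            read_id=f"{site_id}:{allele}:{s}:rc",
                            sequence=revcomp(w),
                            chrom=rec.chrom,
                            ref_start=s,
                            ref_end=s + ref_span,
                            strand="-",
                            site_id=site_id,
                            carried_allele=allele,
                        )
                    )
        if skipped:
            logger.warning("site %s too close to a chromosome end; some placements skipped", site_id)
    return reads


def apply_deamination(
    reads: list[SimulatedRead],
    model: DamageModel,
    rate_scale: float = 1.0,
    seed: int = 0,
    single_strand: bool = False,
) -> list[SimulatedRead]:
    """Return damaged copies of ``reads`` (inputs are not modified).

    ``rate_scale`` multiplies the whole profile, so with the default
    exponential model (d_max = 1) it equals the terminal deamination rate.
    Only C (5' rule) and G (3' rule; C in single-strand mode) bases are
    eligible; every change is recorded in ``damage_positions``.
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be >= 0")
    rng = rng_stream(seed, "deamination")
    if rate_scale == 0.0:
        return [
            SimulatedRead(
                r.read_id, r.sequence, r.source, r.chrom, r.ref_start, r.ref_end,
                r.strand, r.site_id, r.carried_allele, [], r.qual,
            )
            for r in reads
        ]

    profiles: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    out: list[SimulatedRead] = []
    for r in reads:
        n = len(r.sequence)
        if n not in profiles:
            profiles[n] = model.profile_for_length(n, rate_scale)
        d5, d3 = profiles[n]
        codes = encode_dna(r.sequence)
        u = rng.random(n)
        hit5 = (codes == _C) & (u < d5)
        u2 = rng.random(n)
        src3 = _C if single_strand else _G
        hit3 = (codes == src3) & (u2 < d3[::-1]) & ~hit5
        new = codes.copy()
        new[hit5] = _T
        new[hit3] = _T if single_strand else _A
        dmg = np.flatnonzero(hit5 | hit3)
        out.append(
            SimulatedRead(
                r.read_id,
                decode_dna(new) if dmg.size else r.sequence,
                r.source, r.chrom, r.ref_start, r.ref_end, r.strand,
                r.site_id, r.carried_allele, dmg.tolist(), r.qual,
            )
        )
    return out


def sample_shotgun_reads(
    sample: DiploidSample,
    coverage: float,
    fraglen_mean: float = 60.0,
    fraglen_sd: float = 12.0,
    min_len: int = 35,
    model: DamageModel | None = None,
    rate_scale: float = 0.0,
    contaminant: ReferenceGenome | None = None,
    endogenous_fraction: float = 1.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Shotgun fragments from both haplotypes at the requested mean coverage.

    Fragment lengths follow a normal truncated at ``min_len``; starts and
    strands are uniform.  If a contaminant genome is given, contaminant
    reads are added so that endogenous reads make up ``endogenous_fraction``
    of the total.  Truth coordinates are reference-space via the sample's
    liftover tables.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if fraglen_mean < min_len:
        raise ValueError("fraglen_mean below min_len")
    if not 0.0 < endogenous_fraction <= 1.0:
        raise ValueError("endogenous_fraction must be in (0, 1]")
    rng = rng_stream(seed, "shotgun")

    chroms = list(sample.haplotypes)
    hap_lens = np.array(
        [[len(sample.haplotypes[c][h]) for h in (0, 1)] for c in chroms], dtype=float
    )
    ref_total = sum(lift.ref_len for (c, h), lift in sample.liftovers.items() if h == 0)
    n_endo = int(round(coverage * ref_total / fraglen_mean))

    def draw_lengths(n: int) -> np.ndarray:
        lens = rng.normal(fraglen_mean, fraglen_sd, size=int(n * 1.6) + 16)
        lens = lens[lens >= min_len][:n].astype(np.int64)
        while lens.size < n:
            extra = rng.normal(fraglen_mean, fraglen_sd, size=n)
            lens = np.concatenate([lens, extra[extra >= min_len].astype(np.int64)])[:n]
        return lens

    reads: list[SimulatedRead] = []
    flat = hap_lens.ravel()
    picks = rng.choice(flat.size, size=n_endo, p=flat / flat.sum())
    lens = draw_lengths(n_endo)
    strands = rng.random(n_endo) < 0.5
    for i in range(n_endo):
        ci, hi = divmod(int(picks[i]), 2)
        chrom = chroms[ci]
        hap = sample.haplotypes[chrom][hi]
        flen = int(min(lens[i], len(hap)))
        start = int(rng.integers(0, len(hap) - flen + 1))
        frag = hap[start : start + flen]
        lift = sample.liftovers[(chrom, hi)]
        r0, r1 = lift.interval_to_ref(start, start + flen)
        strand = "-" if strands[i] else "+"
        reads.append(
            SimulatedRead(
                read_id=f"shot{i}:h{hi}",
                sequence=revcomp(frag) if strand == "-" else frag,
                chrom=chrom,
                ref_start=r0,
                ref_end=r1,
                strand=strand,
            )
        )

    if contaminant is not None and endogenous_fraction < 1.0:
        n_cont = int(round(n_endo * (1.0 - endogenous_fraction) / endogenous_fraction))
        cchrom = contaminant.chroms[0]
        cseq = contaminant[cchrom]
        clens = draw_lengths(n_cont)
        if clens.size and clens.max() > len(cseq):
            raise ValueError("contaminant genome shorter than a requested fragment")
        cstrands = rng.random(n_cont) < 0.5
        for i in range(n_cont):
            flen = int(clens[i])
            start = int(rng.integers(0, len(cseq) - flen + 1))
            frag = cseq[start : start + flen]
            strand = "-" if cstrands[i] else "+"
            reads.append(
                SimulatedRead(
                    read_id=f"cont{i}",
                    sequence=revcomp(frag) if strand == "-" else frag,
                    source="contaminant",
                    chrom=cchrom,
                    ref_start=start,
                    ref_end=start + flen,
                    strand=strand,
                )
            )

    if model is not None and rate_scale > 0:
        reads = apply_deamination(reads, model, rate_scale, seed=seed)
    return reads
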