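"""Shared aligner types: parameters, the Alignment record, mapping quality."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson


@dataclass
class LinearAlignerParams:
    """Parameters of the edit-distance-limited linear aligner.

    ``n_frac`` is the missing-probability threshold controlling the maximum
    number of differences (mismatches + gap opens) accepted for a read of a
    given length; ``seed_len >= read length`` disables seeding so candidate
    anchors are taken from anywhere in the read.  Each gap may extend to at
    most ``1 + max_gap_extensions`` bases.
    """

    n_frac: float = 0.02
    max_gap_opens: int = 1
    max_gap_extensions: int = 6
    seed_len: int = 1024
    mapq_cap: int = 37
    base_err: float = 0.02
    # penalty weights ranking acceptable placements (a gap is much more
    # expensive than a mismatch, as in the emulated aligner)
    pen_mismatch: int = 3
    pen_gap_open: int = 11
    pen_gap_extend: int = 4
    mapq_temperature: float = 3.0  # = mismatch penalty: one mismatch ~ e-fold weight

    def __post_init__(self) -> None:
        if not 0.0 < self.n_frac < 1.0:
            raise ValueError("n_frac must be in (0, 1)")
        if self.max_gap_opens < 0 or self.max_gap_extensions < 0:
            raise ValueError("gap budgets must be non-negative")

    @property
    def max_gap_len(self) -> int:
        return 1 + self.max_gap_extensions if self.max_gap_opens > 0 else 0


@dataclass
class GraphAlignerParams:
    """Parameters of the seed-and-extend graph aligner (local, affine gaps)."""

    k: int = 15
    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    mapq_cap: int = 60
    min_score_frac: float = 0.65  # mapped iff best local score >= frac * match * read length

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if min(self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("penalties must be positive")

    @property
    def mapq_temperature(self) -> float:
        return float(self.mismatch)


@dataclass(slots=True)
class Alignment:
    """Placement of one read against reference coordinates.

    ``pos`` is the 0-based leftmost reference position consumed by an M or D
    operation; CIGAR operations are (op, length) with op in {M, I, D, S}.
    ``nm`` is the edit distance to the reference over the aligned span.
    """

    read_id: str
    mapped: bool
    chrom: str | None = None
    pos: int | None = None
    strand: str = "+"
    cigar: tuple = ()
    nm: int = 0
    score: float = 0.0
    mapq: int = 0
    n_best: int = 1
    n_subopt: int = 0
    reason: str | None = None  # why unmapped

    def __post_init__(self) -> None:
        if self.mapped:
            read_span = sum(ln for op, ln in self.cigar if op in ("M", "I", "S"))
            if read_span == 0:
                raise ValueError(f"{self.read_id}: mapped alignment with empty CIGAR")
        elif self.pos is not None:
            raise ValueError(f"{self.read_id}: unmapped alignment carries coordinates")

    @property
    def read_len(self) -> int:
        return sum(ln for op, ln in self.cigar if op in ("M", "I", "S"))

    @property
    def ref_span(self) -> int:
        return sum(ln for op, ln in self.cigar if op in ("M", "D"))

    @property
    def lead_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def m_bases(self) -> int:
        return sum(ln for op, ln in self.cigar if op == "M")

    @property
    def end_pos(self) -> int:
        """0-based exclusive end on the reference."""
        return (self.pos or 0) + self.ref_span


class AlignmentTable:
    """Column-oriented batch of alignments (one row per input read).

    The batch aligners return this; it exposes the same information as a
    list of :class:`Alignment` records but keeps large runs in numpy arrays.
    ``cigars`` holds per-row cigar tuples (shared objects for the common
    all-M case, so the list is cheap).
    """

    def __init__(
        self,
        read_ids: list[str],
        mapped: np.ndarray,
        chroms: list[str | None],
        pos: np.ndarray,
        strand: np.ndarray,  # bool, True = reverse
        mapq: np.ndarray,
        score: np.ndarray,
        nm: np.ndarray,
        cigars: list[tuple],
        n_best: np.ndarray,
        n_subopt: np.ndarray,
        reasons: list[str | None] | None = None,
    ):
        self.read_ids = read_ids
        self.mapped = mapped
        self.chroms = chroms
        self.pos = pos
        self.strand = strand
        self.mapq = mapq
        self.score = score
        self.nm = nm
        self.cigars = cigars
        self.n_best = n_best
        self.n_subopt = n_subopt
        self.reasons = reasons or [None] * len(read_ids)

    def __len__(self) -> int:
        return len(self.read_ids)

    def __getitem__(self, i: int) -> Alignment:
        if not self.mapped[i]:
            return Alignment(self.read_ids[i], False, reason=self.reasons[i])
        return Alignment(
            read_id=self.read_ids[i],
            mapped=True,
            chrom=self.chroms[i],
            pos=int(self.pos[i]),
            strand="-" if self.strand[i] else "+",
            cigar=self.cigars[i],
            nm=int(self.nm[i]),
            score=float(self.score[i]),
            mapq=int(self.mapq[i]),
            n_best=int(self.n_best[i]),
            n_subopt=int(self.n_subopt[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def to_alignments(self) -> list[Alignment]:
        return list(self)

    @property
    def lead_clip(self) -> np.ndarray:
        out = np.zeros(len(self), dtype=np.int32)
        for i, cg in enumerate(self.cigars):
            if cg and cg[0][0] == "S":
                out[i] = cg[0][1]
        return out

    @property
    def m_bases(self) -> np.ndarray:
        out = np.zeros(len(self), dtype=np.int32)
        for i, cg in enumerate(self.cigars):
            out[i] = sum(ln for op, ln in cg if op == "M")
        return out


def max_edit_distance(read_len: int, n_frac: float, base_err: float = 0.02) -> int:
    """Smallest k with upper-tail P(X > k) < n_frac for X ~ Poisson(err * len).

    This is the published rule mapping the fractional ``-n`` style threshold
    to an integer difference budget per read length.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    lam = base_err * read_len
    k = 0
    while poisson.sf(k, lam) >= n_frac:
        k += 1
        if k > read_len:  # pragma: no cover - defensive
            break
    return k


def compute_mapq(
    best_score: float,
    candidate_scores: list[float] | np.ndarray,
    cap: int,
    temperature: float,
) -> int:
    """Phred-scaled posterior that the best-scoring candidate is correct.

    P(best) = exp(best/T) / sum_i exp(score_i/T) over the candidate list;
    mapq = min(cap, round(-10 log10(1 - P))).  A single candidate gets the
    cap.  Ties split the posterior (two equal candidates -> mapq 3).
    """
    scores = np.asarray(candidate_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty candidate list")
    if best_score not in scores:
        raise ValueError("best_score not among candidate_scores")
    if scores.size == 1:
        return int(cap)
    w = np.exp((scores - best_score) / temperature)
    p = 1.0 / w.sum()
    if p >= 1.0:
        return int(cap)
    q = -10.0 * math.log10(1.0 - p)
    return int(min(cap, round(q)))


def mapq_from_weight_sum(total_weight: np.ndarray, cap: int) -> np.ndarray:
    """Vectorised mapq for batches: total_weight = sum exp((s_i - best)/T)."""
    with np.errstate(divide="ignore"):
        p = 1.0 / total_weight
        q = np.where(p >= 1.0, np.inf, -10.0 * np.log10(np.maximum(1.0 - p, 1e-300)))
    return np.minimum(cap, np.round(q)).astype(np.int32)
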