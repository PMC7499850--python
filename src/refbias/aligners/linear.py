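"""Edit-distance-limited linear aligner (bwa aln style semantics).

Candidate placements come from exact anchor k-mers taken at evenly spaced
read offsets (enough anchors that any placement within the difference
budget retains an exact hit when mismatches and a single gap are spread
adversarially).  Each candidate diagonal is scored exactly over the class
of global-in-read alignments with at most one gap of bounded length; no
softclipping.

Two quantities are kept separate, as in the emulated aligner: the
*difference count* (mismatches + gap opens; gap length is bounded by
1 + max_gap_extensions but extension bases do not consume the budget)
decides whether a placement is acceptable at all — a read whose best
acceptable placement would exceed the Poisson-derived budget is unmapped —
while the *penalty score* (weighted mismatch / gap-open / gap-extension
costs) ranks acceptable placements and feeds the mapping-quality
posterior.  Under the penalty a gap is far more expensive than a mismatch,
so gaps are only chosen when they genuinely explain an indel.
"""

from __future__ import annotations

import numpy as np

from ..synth import ReferenceGenome
from ..util import encode_dna
from .base import (
    Alignment,
    AlignmentTable,
    LinearAlignerParams,
    max_edit_distance,
    mapq_from_weight_sum,
)
from ._seeds import SeqIndex, anchor_offsets, candidate_diagonals

_INF = np.int64(10**9)
_CHUNK = 200_000


class LinearAligner:
    """Reusable aligner over one reference (index built once)."""

    def __init__(self, ref: ReferenceGenome, params: LinearAlignerParams | None = None):
        self.ref = ref
        self.params = params or LinearAlignerParams()
        self.chrom_names = ref.chroms
        starts = [0]
        codes = []
        for c in self.chrom_names:
            codes.append(encode_dna(ref[c]))
            starts.append(starts[-1] + len(codes[-1]))
        self._codes = np.concatenate(codes)
        self._seg_starts = np.asarray(starts[:-1], dtype=np.int64)
        self._index_cache: dict[int, SeqIndex] = {}

    # -- seeding ---------------------------------------------------------
    def _index(self, k: int) -> SeqIndex:
        if k not in self._index_cache:
            self._index_cache[k] = SeqIndex(self._codes, self._seg_starts, (k,))
        return self._index_cache[k]

    def _anchor_plan(self, read_len: int) -> tuple[int, list[int]]:
        """Anchor count/length guaranteeing an intact anchor within budget.

        k_max + 2 disjoint anchors make the guarantee exact even with one
        gap; when the read is too short for that at anchor length >= 10,
        k_max + 1 anchors are used instead (exact for ungapped placements,
        near-exact for gapped ones).
        """
        k_max = max_edit_distance(read_len, self.params.n_frac, self.params.base_err)
        limit = min(read_len, self.params.seed_len)  # seeding region
        n1 = max(2, k_max + 2)
        if limit // n1 >= 10:
            a_len = min(13, limit // n1)
            return a_len, anchor_offsets(limit, n1, a_len)
        n2 = max(2, k_max + 1)
        a_len = int(np.clip(limit // n2, 8, 13))
        return a_len, anchor_offsets(limit, n2, a_len)

    # -- public API ------------------------------------------------------
    def align(self, read) -> Alignment:
        return self.align_batch([read])[0]

    def align_batch(self, reads) -> AlignmentTable:
        seqs = [r if isinstance(r, str) else r.sequence for r in reads]
        ids = [
            f"read{i}" if isinstance(r, str) else r.read_id for i, r in enumerate(reads)
        ]
        n = len(seqs)
        out_mapped = np.zeros(n, dtype=bool)
        out_pos = np.full(n, -1, dtype=np.int64)
        out_strand = np.zeros(n, dtype=bool)
        out_mapq = np.zeros(n, dtype=np.int32)
        out_score = np.zeros(n, dtype=np.float64)
        out_nm = np.zeros(n, dtype=np.int32)
        out_nbest = np.ones(n, dtype=np.int32)
        out_nsub = np.zeros(n, dtype=np.int32)
        out_chrom: list[str | None] = [None] * n
        out_cigars: list[tuple] = [()] * n
        out_reason: list[str | None] = [None] * n

        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            by_len.setdefault(len(s), []).append(i)
        for L, idxs in sorted(by_len.items()):
            if L < 12:
                for i in idxs:
                    out_reason[i] = "read_too_short"
                continue
            self._align_group(
                L, idxs, seqs,
                out_mapped, out_pos, out_strand, out_mapq, out_score, out_nm,
                out_nbest, out_nsub, out_chrom, out_cigars, out_reason,
            )
        return AlignmentTable(
            ids, out_mapped, out_chrom, out_pos, out_strand, out_mapq,
            out_score, out_nm, out_cigars, out_nbest, out_nsub, out_reason,
        )

    # -- core ------------------------------------------------------------
    def _align_group(
        self, L, idxs, seqs,
        out_mapped, out_pos, out_strand, out_mapq, out_score, out_nm,
        out_nbest, out_nsub, out_chrom, out_cigars, out_reason,
    ) -> None:
        p = self.params
        k_max = max_edit_distance(L, p.n_frac, p.base_err)
        G = p.max_gap_len
        a_len, offsets = self._anchor_plan(L)
        index = self._index(a_len)

        N = len(idxs)
        mat = np.empty((2 * N, L), dtype=np.uint8)
        for r, i in enumerate(idxs):
            mat[r] = encode_dna(seqs[i])
        mat[N:] = 3 - mat[:N, ::-1]  # reverse complements

        rows, diags = candidate_diagonals(mat, index, [(a_len, o) for o in offsets])

        had_cand = np.zeros(2 * N, dtype=bool)
        if rows.size:
            had_cand[np.unique(rows)] = True
            pen, mm, gleft, gtype, gpos, glen = self._score_candidates(
                mat, rows, diags, L, k_max, G
            )
            start = diags - gleft  # gapped alignments may start left of the diagonal
            # drop candidates with no acceptable alignment (over budget)
            ok = pen < _INF
            rows, start = rows[ok], start[ok]
            pen, mm = pen[ok], mm[ok]
            gtype, gpos, glen = gtype[ok], gpos[ok], glen[ok]
        if rows.size:
            # dedup by (row, start) keeping the lowest penalty
            order = np.lexsort((gtype, pen, start, rows))
            rows, start = rows[order], start[order]
            pen, mm = pen[order], mm[order]
            gtype, gpos, glen = gtype[order], gpos[order], glen[order]
            key = rows * np.int64(len(self._codes) + 2 * G + 2) + start
            keep = np.concatenate(([True], key[1:] != key[:-1]))
            rows, start = rows[keep], start[keep]
            pen, mm = pen[keep], mm[keep]
            gtype, gpos, glen = gtype[keep], gpos[keep], glen[keep]
            # re-sort by (row, penalty, start) so the first entry per row wins
            order = np.lexsort((start, pen, rows))
            rows, start = rows[order], start[order]
            pen, mm = pen[order], mm[order]
            gtype, gpos, glen = gtype[order], gpos[order], glen[order]
        else:
            start = rows
            pen = mm = rows

        # per-strand-row aggregation
        best = np.full(2 * N, _INF, dtype=np.int64)
        best_at = np.zeros(2 * N, dtype=np.int64)
        wsum = np.zeros(2 * N, dtype=np.float64)
        nbest = np.zeros(2 * N, dtype=np.int64)
        nsub = np.zeros(2 * N, dtype=np.int64)
        if rows.size:
            firsts = np.flatnonzero(
                np.concatenate(([True], rows[1:] != rows[:-1]))
            )
            seg_rows = rows[firsts]
            best[seg_rows] = pen[firsts]
            best_at[seg_rows] = firsts
            w = np.exp(-(pen - best[rows]) / p.mapq_temperature)
            np.add.at(wsum, rows, w)
            np.add.at(nbest, rows, pen == best[rows])
            np.add.at(
                nsub, rows, (pen > best[rows]) & (pen <= best[rows] + p.pen_mismatch)
            )

        # merge forward / reverse per read; ties go to the lower position,
        # then to the forward strand
        fb, rb = best[:N], best[N:]
        if rows.size:
            fpos = np.where(fb < _INF, start[best_at[:N]], np.int64(2**62))
            rpos = np.where(rb < _INF, start[best_at[N:]], np.int64(2**62))
        else:
            fpos = rpos = np.full(N, 2**62, dtype=np.int64)
        use_rc = (rb < fb) | ((rb == fb) & (rpos < fpos))
        rbest = np.where(use_rc, rb, fb)
        has = rbest < _INF
        sel = np.where(use_rc, np.arange(N) + N, np.arange(N))
        wtot = wsum[:N] * np.exp(-(fb - rbest) / p.mapq_temperature) + wsum[N:] * np.exp(
            -(rb - rbest) / p.mapq_temperature
        )
        wtot[~has] = 1.0
        mapqs = mapq_from_weight_sum(wtot, p.mapq_cap)

        for j, i in enumerate(idxs):
            if not has[j]:
                out_reason[i] = (
                    "over_budget" if had_cand[j] or had_cand[j + N] else "no_seed"
                )
                continue
            ci = int(best_at[sel[j]])
            s = int(start[ci])
            seg = int(np.searchsorted(self._seg_starts, s, side="right") - 1)
            out_mapped[i] = True
            out_chrom[i] = self.chrom_names[seg]
            out_pos[i] = s - int(self._seg_starts[seg])
            out_strand[i] = bool(sel[j] >= N)
            out_score[i] = -int(rbest[j])
            out_mapq[i] = int(mapqs[j])
            out_nbest[i] = int(nbest[sel[j]])
            out_nsub[i] = int(nsub[sel[j]])
            gt = int(gtype[ci])
            if gt == 0:
                out_cigars[i] = (("M", L),)
                out_nm[i] = int(mm[ci])
            else:
                jj, g = int(gpos[ci]), int(glen[ci])
                if gt == 1:  # deletion in read vs reference
                    out_cigars[i] = (("M", jj), ("D", g), ("M", L - jj))
                else:
                    out_cigars[i] = (("M", jj), ("I", g), ("M", L - jj - g))
                out_nm[i] = int(mm[ci]) + g

    def _score_candidates(self, mat, rows, diags, L, k_max, G):
        """Best acceptable alignment per candidate over <=1-gap placements.

        Returns (penalty, mismatches, gap_left_shift, gtype, gpos, glen);
        gtype is 0 = ungapped, 1 = deletion (ref gap), 2 = insertion (read
        gap); gap_left_shift is how far the alignment start lies left of
        the candidate diagonal.  Penalty is _INF when no alignment at this
        diagonal fits the difference budget.
        """
        p = self.params
        M = rows.size
        pen = np.full(M, _INF, dtype=np.int64)
        mm = np.zeros(M, dtype=np.int64)
        gleft = np.zeros(M, dtype=np.int64)
        gtype = np.zeros(M, dtype=np.int8)
        gpos = np.zeros(M, dtype=np.int64)
        glen = np.zeros(M, dtype=np.int64)
        codes = self._codes
        seg = np.searchsorted(self._seg_starts, diags, side="right") - 1
        seg_lo = self._seg_starts[seg]
        seg_hi = np.concatenate([self._seg_starts[1:], [len(codes)]])[seg]

        A = 8  # precheck window at each read end
        for c0 in range(0, M, _CHUNK):
            c1 = min(M, c0 + _CHUNK)
            r = rows[c0:c1]
            d = diags[c0:c1]
            neq = codes[d[:, None] + np.arange(L)] != mat[r]
            mm0 = neq.sum(axis=1).astype(np.int64)
            within = mm0 <= k_max
            pen[c0:c1] = np.where(within, p.pen_mismatch * mm0, _INF)
            mm[c0:c1] = mm0
            if G == 0 or k_max < 1:
                continue
            # a gap can win only when it is cheaper than the ungapped
            # penalty, or when the ungapped placement is over budget;
            # additionally, a single-gap alignment anchored here must keep
            # one end of the read nearly matching this diagonal
            pre_ok = neq[:, :A].sum(axis=1) <= k_max - 1
            suf_ok = neq[:, L - A :].sum(axis=1) <= k_max - 1
            elig = np.flatnonzero(
                ((p.pen_mismatch * mm0 > p.pen_gap_open) | ~within)
                & (pre_ok | suf_ok)
            )
            for g0 in range(0, elig.size, 25_000):
                sub = elig[g0 : g0 + 25_000]
                self._gap_refine(
                    mat, r, d, seg_lo[c0:c1], seg_hi[c0:c1], sub, L, G, k_max,
                    pre_ok, suf_ok,
                    pen, mm, gleft, gtype, gpos, glen, c0,
                )
        return pen, mm, gleft, gtype, gpos, glen

    def _gap_refine(
        self, mat, r, d, lo, hi, elig, L, G, k_max, pre_ok, suf_ok,
        pen, mm, gleft, gtype, gpos, glen, base,
    ) -> None:
        """Single-gap alignments anchored on (or shifted around) each diagonal."""
        p = self.params
        codes = self._codes
        e = elig
        if e.size == 0:
            return
        pre_e, suf_e = pre_ok[e], suf_ok[e]
        re_, de = r[e], d[e]
        lo_e, hi_e = lo[e], hi[e]
        reads = mat[re_]
        # mismatch cumulative sums for every shift t in [-G, G]
        # cum[t][j] = mismatches of read[0:j] against ref[d+t : d+t+j]
        cums = {}
        valid = {}
        for t in range(-G, G + 1):
            s = de + t
            ok = (s >= lo_e) & (s + L <= hi_e)
            ss = np.where(ok, s, lo_e)
            Wt = codes[ss[:, None] + np.arange(L)]
            mmv = Wt != reads
            cums[t] = np.concatenate(
                [np.zeros((e.size, 1), np.int32), np.cumsum(mmv, axis=1, dtype=np.int32)],
                axis=1,
            )
            valid[t] = ok
        p_best = pen[base + e].copy()
        m_best = mm[base + e].copy()
        sh_best = np.zeros(e.size, np.int64)
        ty_best = np.zeros(e.size, np.int8)
        j_best = np.zeros(e.size, np.int64)
        g_best = np.zeros(e.size, np.int64)
        j_idx = np.arange(1, L)  # gap strictly inside the read

        def consider(mm_gap, shift, ty, g, jvec, okmask):
            nonlocal p_best, m_best, sh_best, ty_best, j_best, g_best
            # budget: 1 open + mismatches; penalty: weighted
            cand_pen = (
                p.pen_gap_open + p.pen_gap_extend * (g - 1) + p.pen_mismatch * mm_gap
            )
            bad = ~okmask[:, None] | (1 + mm_gap > k_max)
            cand_pen = np.where(bad, _INF, cand_pen)
            jm = np.argmin(cand_pen, axis=1)
            rows_loc = np.arange(e.size)
            cp = cand_pen[rows_loc, jm]
            upd = cp < p_best
            p_best[upd] = cp[upd]
            m_best[upd] = mm_gap[rows_loc, jm][upd]
            sh_best[upd] = shift
            ty_best[upd] = ty
            j_best[upd] = jvec[jm[upd]]
            g_best[upd] = g

        for g in range(1, G + 1):
            c0 = cums[0]
            # deletion, prefix on d: read[0:j] at d, read[j:] at d+g
            suf = cums[g][:, L][:, None] - cums[g][:, j_idx]
            consider(c0[:, j_idx] + suf, 0, 1, g, j_idx, pre_e & valid[0] & valid[g])
            # deletion, suffix on d: start = d - g
            pre = cums[-g][:, j_idx]
            suf0 = c0[:, L][:, None] - c0[:, j_idx]
            consider(pre + suf0, g, 1, g, j_idx, suf_e & valid[0] & valid[-g])
            # insertion, prefix on d: read[0:j] at d, read[j+g:] at d+j
            jmax = L - g
            if jmax >= 2:
                ji = np.arange(1, jmax)
                suf = cums[-g][:, L][:, None] - cums[-g][:, ji + g]
                consider(c0[:, ji] + suf, 0, 2, g, ji, pre_e & valid[0] & valid[-g])
                # insertion, suffix on d: prefix at d + g, start = d + g
                pre = cums[g][:, ji]
                suf0 = c0[:, L][:, None] - c0[:, ji + g]
                consider(pre + suf0, -g, 2, g, ji, suf_e & valid[0] & valid[g])

        upd = p_best < pen[base + e]
        tgt = base + e[upd]
        pen[tgt] = p_best[upd]
        mm[tgt] = m_best[upd]
        gleft[tgt] = sh_best[upd]
        gtype[tgt] = ty_best[upd]
        gpos[tgt] = j_best[upd]
        glen[tgt] = g_best[upd]


def align_linear(read, ref: ReferenceGenome, params: LinearAlignerParams | None = None) -> Alignment:
    """Align one read; convenience wrapper building a throwaway index."""
    return LinearAligner(ref, params).align(read)
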