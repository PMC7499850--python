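"""Seed-and-extend graph aligner with surjection to reference coordinates.

Seeds are exact k-mers located in an index over the graph's sequence space:
the reference path plus one local "allele context" per variant bubble (left
flank + alternate allele + right flank).  Because panel variants are
non-overlapping and well separated, every path a read of bounded length can
take through the graph is spelled by one of these targets, so extension
over the DAG reduces to banded extension within a target; candidates whose
ungapped score leaves room for a gapped alignment to win are re-aligned
exactly with the affine DAG dynamic program on a windowed subgraph.  Small
graphs skip the seeding machinery entirely and run the full DAG DP.

Shorter rescue anchors supplement the primary k-mers so that a placement
survives seeding even when damage breaks every full-length k-mer.
"""

from __future__ import annotations

import numpy as np

from ..synth import ReferenceGenome, VariantPanel, VariantRecord
from ..util import encode_dna, revcomp
from ..vargraph import VariationGraph, build_graph, spell_path
from .base import (
    Alignment,
    AlignmentTable,
    GraphAlignerParams,
    compute_mapq,
    mapq_from_weight_sum,
)
from .dagdp import dag_align
from ._seeds import SeqIndex, anchor_offsets, candidate_diagonals

_CHUNK = 150_000
_SMALL_GRAPH_BASES = 20_000
_RESCUE_K = 10


class GraphAligner:
    """Aligner over one variation graph (targets and index built once)."""

    def __init__(
        self,
        graph: VariationGraph,
        params: GraphAlignerParams | None = None,
        max_read_len: int = 100,
    ):
        self.graph = graph
        self.params = params or GraphAlignerParams()
        self.max_read_len = max_read_len
        self.chrom_names = list(graph.ref_paths)
        self._ref = ReferenceGenome(
            {c: spell_path(graph, graph.ref_paths[c]) for c in self.chrom_names}
        )
        recs = {r.key: r for r in graph.alt_node_site.values()}
        recs.update({r.key: r for r in graph.deletion_edges.values()})
        self._records = sorted(recs.values(), key=lambda r: (r.chrom, r.pos))
        self._total_bases = sum(len(s) for s in graph.nodes.values())
        self._build_targets()

    # ------------------------------------------------------------------
    def _build_targets(self) -> None:
        F = self.max_read_len
        codes_parts: list[np.ndarray] = []
        seg_starts = [0]
        kind: list[int] = []
        chrom_idx: list[int] = []
        origin: list[int] = []
        llen: list[int] = []
        gl: list[int] = []
        cursor = 0

        def add(seq_codes: np.ndarray, k: int, ci: int, org: int, ll: int, g: int) -> None:
            nonlocal cursor
            codes_parts.append(seq_codes)
            kind.append(k)
            chrom_idx.append(ci)
            origin.append(org)
            llen.append(ll)
            gl.append(g)
            cursor += len(seq_codes)
            seg_starts.append(cursor)

        for ci, c in enumerate(self.chrom_names):
            add(encode_dna(self._ref[c]), 0, ci, 0, 2**40, 0)
        for rec in self._records:
            ci = self.chrom_names.index(rec.chrom)
            seq = self._ref[rec.chrom]
            p0 = rec.start0
            a = max(0, p0 - F)
            b = min(len(seq), rec.end0 + F)
            if rec.vtype == "snp":
                t = seq[a:p0] + rec.alt_allele + seq[p0 + 1 : b]
                add(encode_dna(t), 1, ci, a, p0 - a, 0)
            elif rec.vtype == "deletion":
                g = rec.indel_len
                t = seq[a : p0 + 1] + seq[p0 + 1 + g : b]
                add(encode_dna(t), 2, ci, a, p0 + 1 - a, g)
            else:
                g = rec.indel_len
                t = seq[a : p0 + 1] + rec.alt_allele[1:] + seq[p0 + 1 : b]
                add(encode_dna(t), 3, ci, a, p0 + 1 - a, g)

        self._codes = (
            np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint8)
        )
        self._seg_starts = np.asarray(seg_starts[:-1], dtype=np.int64)
        self._kind = np.asarray(kind, dtype=np.int8)
        self._chrom_idx = np.asarray(chrom_idx, dtype=np.int64)
        self._origin = np.asarray(origin, dtype=np.int64)
        self._llen = np.asarray(llen, dtype=np.int64)
        self._g = np.asarray(gl, dtype=np.int64)
        self._index = SeqIndex(self._codes, self._seg_starts, (self.params.k, _RESCUE_K))

    # ------------------------------------------------------------------
    def align(self, read, read_id: str | None = None) -> Alignment:
        seq = read if isinstance(read, str) else read.sequence
        rid = read_id or (f"read0" if isinstance(read, str) else read.read_id)
        if len(seq) < self.params.k:
            raise ValueError("read shorter than seed length k")
        if self._total_bases <= _SMALL_GRAPH_BASES:
            return self._align_full_dp(seq, rid)
        return self.align_batch([read])[0]

    def _align_full_dp(self, seq: str, rid: str) -> Alignment:
        from ..vargraph import surject_alignment, UnplaceableAlignment

        results: list[tuple[Alignment, list[float]]] = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            galn, cands = dag_align(self.graph, s, self.params, rid, strand)
            if galn is None:
                continue
            try:
                aln = surject_alignment(self.graph, galn)
            except UnplaceableAlignment:
                continue
            results.append((aln, cands))
        if not results:
            return Alignment(rid, False, reason="no_alignment")
        results.sort(key=lambda t: (-t[0].score, t[0].pos, t[0].strand))
        best_aln = results[0][0]
        min_score = int(np.ceil(self.params.min_score_frac * self.params.match * len(seq)))
        if best_aln.score < min_score:
            return Alignment(rid, False, reason="low_score")
        others = results[0][1][1:] + [a.score for a, _ in results[1:]]
        scores = [best_aln.score] + others
        best_aln.mapq = compute_mapq(
            best_aln.score, scores, self.params.mapq_cap, self.params.mapq_temperature
        )
        return best_aln

    # ------------------------------------------------------------------
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
            if L < self.params.k:
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

    # ------------------------------------------------------------------
    def _align_group(
        self, L, idxs, seqs,
        out_mapped, out_pos, out_strand, out_mapq, out_score, out_nm,
        out_nbest, out_nsub, out_chrom, out_cigars, out_reason,
    ) -> None:
        p = self.params
        N = len(idxs)
        mat = np.empty((2 * N, L), dtype=np.uint8)
        for r, i in enumerate(idxs):
            mat[r] = encode_dna(seqs[i])
        mat[N:] = 3 - mat[:N, ::-1]

        n_primary = int(np.clip((L - p.k) // 5 + 1, 2, 8))
        anchors = [(p.k, o) for o in anchor_offsets(L, n_primary, p.k)]
        anchors += [(_RESCUE_K, o) for o in anchor_offsets(L, 5, _RESCUE_K)]
        rows, diags = candidate_diagonals(mat, self._index, anchors)

        M = rows.size
        score = np.full(M, -1, dtype=np.int64)
        s0 = np.zeros(M, dtype=np.int64)
        e0 = np.zeros(M, dtype=np.int64)
        seg = self._index.segment_of(diags) if M else np.empty(0, np.int64)
        for c0 in range(0, M, _CHUNK):
            c1 = min(M, c0 + _CHUNK)
            W = self._codes[diags[c0:c1, None] + np.arange(L)]
            sc = np.where(W == mat[rows[c0:c1]], p.match, -p.mismatch).astype(np.int32)
            cum = np.concatenate(
                [np.zeros((c1 - c0, 1), np.int32), np.cumsum(sc, axis=1, dtype=np.int32)],
                axis=1,
            )
            runmin = np.minimum.accumulate(cum, axis=1)
            prev = np.concatenate(
                [np.full((c1 - c0, 1), 2**30, np.int32), runmin[:, :-1]], axis=1
            )
            is_new = cum < prev
            start_at = np.maximum.accumulate(
                np.where(is_new, np.arange(L + 1), 0), axis=1
            )
            vals = cum[:, 1:] - runmin[:, :-1]  # best subarray ending at j (1..L)
            j_best = np.argmax(vals, axis=1)
            rows_loc = np.arange(c1 - c0)
            score[c0:c1] = vals[rows_loc, j_best]
            e0[c0:c1] = j_best + 1
            s0[c0:c1] = start_at[rows_loc, j_best]

        # surjected start position and validity
        if M:
            loc = diags - self._seg_starts[seg] + s0
            loc_end = loc + (e0 - s0)
            kind = self._kind[seg]
            g = self._g[seg]
            ll = self._llen[seg]
            refpos = self._origin[seg] + loc
            refpos = np.where((kind == 2) & (loc >= ll), refpos + g, refpos)
            refpos = np.where((kind == 3) & (loc >= ll + g), refpos - g, refpos)
            # start inside an inserted segment: first ref base is the right flank
            in_ins = (kind == 3) & (loc >= ll) & (loc < ll + g)
            refpos = np.where(in_ins, self._origin[seg] + ll, refpos)
            # candidates below the mapped-score gate are not viable placements
            # and do not enter the mapping-quality posterior either
            valid = score >= int(np.ceil(p.min_score_frac * p.match * L))
            # alignment entirely inside an inserted segment is unplaceable
            valid &= ~((kind == 3) & (loc >= ll) & (loc_end <= ll + g))
            chrom_key = self._chrom_idx[seg]
            # dedup / tie-break key: the position the *full* read projects to,
            # so clipped variants of one physical placement collapse together
            gkey = chrom_key * np.int64(2**40) + (refpos - s0)
            # aligned reference interval (for overlap suppression below)
            ref_lo = chrom_key * np.int64(2**40) + refpos
            ref_hi = ref_lo + (e0 - s0) + np.where((kind == 2) & (loc < ll) & (loc_end > ll), g, 0)
        else:
            valid = np.zeros(0, dtype=bool)
            gkey = ref_lo = ref_hi = np.empty(0, np.int64)

        rows_v = rows[valid]
        score_v = score[valid]
        gkey_v = gkey[valid]
        lo_v = ref_lo[valid]
        hi_v = ref_hi[valid]
        cand_idx = np.flatnonzero(valid)

        # dedup by (row, surjected position), keep the best score
        order = np.lexsort((-score_v, gkey_v, rows_v))
        rows_v, score_v, gkey_v, lo_v, hi_v, cand_idx = (
            rows_v[order], score_v[order], gkey_v[order],
            lo_v[order], hi_v[order], cand_idx[order]
        )
        keep = np.concatenate(
            ([True], (rows_v[1:] != rows_v[:-1]) | (gkey_v[1:] != gkey_v[:-1]))
        ) if rows_v.size else np.zeros(0, bool)
        rows_v, score_v, gkey_v, lo_v, hi_v, cand_idx = (
            rows_v[keep], score_v[keep], gkey_v[keep],
            lo_v[keep], hi_v[keep], cand_idx[keep]
        )
        # order by (row, -score, position) so the first entry per row is best
        order = np.lexsort((gkey_v, -score_v, rows_v))
        rows_v, score_v, gkey_v, lo_v, hi_v, cand_idx = (
            rows_v[order], score_v[order], gkey_v[order],
            lo_v[order], hi_v[order], cand_idx[order]
        )

        best = np.full(2 * N, -(10**9), dtype=np.int64)
        best_ci = np.full(2 * N, -1, dtype=np.int64)
        best_key = np.full(2 * N, 2**62, dtype=np.int64)
        wsum = np.ones(2 * N, dtype=np.float64)  # the best candidate itself
        nbest = np.ones(2 * N, dtype=np.int64)
        nsub = np.zeros(2 * N, dtype=np.int64)
        if rows_v.size:
            firsts = np.flatnonzero(
                np.concatenate(([True], rows_v[1:] != rows_v[:-1]))
            )
            fr = rows_v[firsts]
            best[fr] = score_v[firsts]
            best_ci[fr] = cand_idx[firsts]
            best_key[fr] = gkey_v[firsts]
            # secondary candidates whose aligned reference span overlaps the
            # best candidate's span are clipped fragments of the same
            # physical placement, not alternative origins: suppress them
            # from the posterior and the best/subopt counts
            blo = np.zeros(2 * N, dtype=np.int64)
            bhi = np.zeros(2 * N, dtype=np.int64)
            blo[fr] = lo_v[firsts]
            bhi[fr] = hi_v[firsts]
            alt_mask = (hi_v <= blo[rows_v]) | (lo_v >= bhi[rows_v])
            w = np.where(
                alt_mask, np.exp((score_v - best[rows_v]) / p.mapq_temperature), 0.0
            )
            np.add.at(wsum, rows_v, w)
            np.add.at(nbest, rows_v, alt_mask & (score_v == best[rows_v]))
            np.add.at(nsub, rows_v, alt_mask & (score_v == best[rows_v] - 1))

        # merge strands (higher score wins; ties to lower position, then '+')
        fb, rb = best[:N], best[N:]
        fk, rk = best_key[:N], best_key[N:]
        use_rc = (rb > fb) | ((rb == fb) & (rk < fk))
        rbest = np.where(use_rc, rb, fb)
        has = rbest > 0
        sel = np.where(use_rc, np.arange(N) + N, np.arange(N))
        wtot = wsum[:N] * np.exp((fb - rbest) / p.mapq_temperature) + wsum[N:] * np.exp(
            (rb - rbest) / p.mapq_temperature
        )
        wtot[~has] = 1.0
        mapqs = mapq_from_weight_sum(wtot, p.mapq_cap)

        # exact DP refinement where a gapped alignment could outscore the
        # ungapped extension
        perfect = L * p.match
        need_dp = has & (rbest < perfect - (p.gap_open + p.gap_extend))

        for j, i in enumerate(idxs):
            if not has[j]:
                out_reason[i] = "low_score" if rbest[j] > 0 else "no_alignment"
                continue
            ci = int(best_ci[sel[j]])
            refined = None
            if need_dp[j]:
                refined = self._dp_refine(
                    seqs[i], row=int(sel[j]), N=N,
                    cand_gkey=int(best_key[sel[j]]), L=L,
                )
            if refined is not None and refined.score > rbest[j]:
                aln = refined
                out_mapped[i] = True
                out_chrom[i] = aln.chrom
                out_pos[i] = aln.pos
                out_strand[i] = aln.strand == "-"
                out_score[i] = aln.score
                out_nm[i] = aln.nm
                out_cigars[i] = tuple(aln.cigar)
                scores = [aln.score, float(rbest[j]), 0.0]
                out_mapq[i] = compute_mapq(
                    aln.score, scores, p.mapq_cap, p.mapq_temperature
                )
                out_nbest[i] = 1
                continue
            self._emit_winner(
                i, j, ci, L, mat, rows, diags, seg, score, s0, e0, sel, N,
                out_mapped, out_chrom, out_pos, out_strand, out_score, out_nm,
                out_cigars, out_mapq, mapqs, out_nbest, nbest, out_nsub, nsub,
            )

    # ------------------------------------------------------------------
    def _emit_winner(
        self, i, j, ci, L, mat, rows, diags, seg, score, s0, e0, sel, N,
        out_mapped, out_chrom, out_pos, out_strand, out_score, out_nm,
        out_cigars, out_mapq, mapqs, out_nbest, nbest, out_nsub, nsub,
    ) -> None:
        p = self.params
        sg = int(seg[ci])
        kind = int(self._kind[sg])
        g = int(self._g[sg])
        ll = int(self._llen[sg])
        origin = int(self._origin[sg])
        sc = int(score[ci])
        a0, a1 = int(s0[ci]), int(e0[ci])
        span = a1 - a0
        mm = (p.match * span - sc) // (p.match + p.mismatch)
        loc = int(diags[ci] - self._seg_starts[sg]) + a0
        loc_end = loc + span

        cig: list[tuple[str, int]] = []
        if a0:
            cig.append(("S", a0))
        nm = mm
        if kind in (0, 1):
            cig.append(("M", span))
            pos = origin + loc
            if kind == 1 and loc <= ll < loc_end:
                nm += 1
        elif kind == 2:  # deletion context
            if loc < ll < loc_end:
                cig.append(("M", ll - loc))
                cig.append(("D", g))
                cig.append(("M", loc_end - ll))
                nm += g
                pos = origin + loc
            elif loc_end <= ll:
                cig.append(("M", span))
                pos = origin + loc
            else:
                cig.append(("M", span))
                pos = origin + loc + g
        else:  # insertion context
            i0, i1 = ll, ll + g
            pre = max(0, min(loc_end, i0) - loc)
            overlap = max(0, min(loc_end, i1) - max(loc, i0))
            post = max(0, loc_end - max(loc, i1))
            if pre and post:
                cig.append(("M", pre))
                cig.append(("I", overlap))
                cig.append(("M", post))
                nm += overlap
                pos = origin + loc
            elif pre:
                # alignment ends inside the insertion: clip those bases
                cig.append(("M", pre))
                a1 -= overlap
                pos = origin + loc
            elif post:
                # starts inside the insertion: clip, report next ref base
                a0 += overlap
                if cig and cig[0][0] == "S":
                    cig[0] = ("S", a0)
                else:
                    cig.insert(0, ("S", a0))
                cig.append(("M", post))
                pos = origin + ll
            else:  # pragma: no cover - filtered as invalid earlier
                out_mapped[i] = False
                return
        if a1 < L:
            cig.append(("S", L - a1))

        out_mapped[i] = True
        out_chrom[i] = self.chrom_names[int(self._chrom_idx[sg])]
        out_pos[i] = pos
        out_strand[i] = bool(sel[j] >= N)
        out_score[i] = sc
        out_nm[i] = nm
        out_cigars[i] = tuple(cig)
        out_mapq[i] = int(mapqs[j])
        out_nbest[i] = int(nbest[sel[j]])
        out_nsub[i] = int(nsub[sel[j]])

    # ------------------------------------------------------------------
    def _dp_refine(self, seq: str, row: int, N: int, cand_gkey: int, L: int):
        """Exact affine DP on a windowed subgraph around the best candidate."""
        chrom_i = cand_gkey // 2**40
        refpos = cand_gkey % 2**40
        chrom = self.chrom_names[int(chrom_i)]
        G = 2 * L
        a = max(0, int(refpos) - L)
        b = min(self._ref.length(chrom), int(refpos) + G)
        sub = self._window_graph(chrom, a, b)
        if sub is None:
            return None
        oriented = seq if row < N else revcomp(seq)
        strand = "+" if row < N else "-"
        galn, _ = dag_align(sub, oriented, self.params, "r", strand)
        if galn is None:
            return None
        from ..vargraph import surject_alignment, UnplaceableAlignment

        try:
            aln = surject_alignment(sub, galn)
        except UnplaceableAlignment:
            return None
        aln.chrom = chrom
        aln.pos += a
        return aln

    def _window_graph(self, chrom: str, a: int, b: int) -> VariationGraph | None:
        recs = []
        for r in self._records:
            if r.chrom != chrom:
                continue
            if r.start0 >= a + 1 and r.end0 < b - 1:
                recs.append(
                    VariantRecord(
                        r.chrom, r.pos - a, r.ref_allele, r.alt_allele, r.vtype, r.maf
                    )
                )
        try:
            panel = VariantPanel(recs)
            return build_graph(
                ReferenceGenome({chrom: self._ref[chrom][a:b]}), panel
            )
        except ValueError:
            return None


def align_graph(
    read, graph: VariationGraph, params: GraphAlignerParams | None = None
) -> Alignment:
    """Align one read to a variation graph (convenience wrapper)."""
    return GraphAligner(graph, params).align(read)
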