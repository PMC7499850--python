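"""Brute-force alignment oracles for small instances.

Independent implementations used in tests: every placement is scored
exhaustively, with none of the seeding or candidate machinery of the
production aligners.  The linear oracle scores every start position on both
strands directly; the graph oracle enumerates every source-to-sink path and
runs a plain local Gotoh alignment against each spelled sequence.
"""

from __future__ import annotations

import numpy as np

from ..synth import ReferenceGenome
from ..util import encode_dna, revcomp
from ..vargraph import VariationGraph
from .base import GraphAlignerParams, LinearAlignerParams

_BIG = 10**6


def oracle_align(read: str, target, params):
    """Exhaustive optimum for ``read`` against a small reference or graph.

    For :class:`LinearAlignerParams` returns ``(best_cost, placements)``
    where cost counts mismatches plus gap opens (at most one gap, length
    <= 1 + max_gap_extensions) and placements is the sorted list of optimal
    ``(chrom, pos, strand)``.  For :class:`GraphAlignerParams` returns
    ``(best_score, placements)`` under local affine-gap scoring over every
    source-to-sink path.
    """
    if not read:
        raise ValueError("empty read")
    if len(read) > 60:
        raise ValueError("oracle instance too large: read > 60 bp")
    if isinstance(params, LinearAlignerParams):
        if not isinstance(target, ReferenceGenome):
            raise TypeError("linear oracle needs a ReferenceGenome")
        return _oracle_linear(read, target, params)
    if isinstance(params, GraphAlignerParams):
        if not isinstance(target, VariationGraph):
            raise TypeError("graph oracle needs a VariationGraph")
        return _oracle_graph(read, target, params)
    raise TypeError("params must be LinearAlignerParams or GraphAlignerParams")


# ---------------------------------------------------------------------------
def _oracle_linear(read: str, ref: ReferenceGenome, params: LinearAlignerParams):
    """Best penalty among placements within the difference budget.

    Differences (mismatches + gap opens, one gap at most, length
    <= 1 + max_gap_extensions) must stay within the Poisson budget for the
    read length; among acceptable placements the weighted penalty
    (pen_mismatch / pen_gap_open / pen_gap_extend) is minimised.  Returns
    (best_penalty, placements); best_penalty is None when no placement
    fits the budget (the read is unmappable).
    """
    from .base import max_edit_distance

    total = sum(ref.length(c) for c in ref.chroms)
    if total > 2000:
        raise ValueError("oracle instance too large: reference > 2 kb")
    L = len(read)
    G = params.max_gap_len
    k_max = max_edit_distance(L, params.n_frac, params.base_err)
    best = _BIG
    places: list[tuple[str, int, str]] = []

    for chrom in ref.chroms:
        codes = encode_dna(ref[chrom])
        n = len(codes)
        S = n - L + 1
        if S <= 0:
            continue
        for strand in ("+", "-"):
            rd = encode_dna(read if strand == "+" else revcomp(read))
            idx = np.arange(S)[:, None] + np.arange(L)
            mm = (codes[idx] != rd).astype(np.int32)
            cum = np.concatenate(
                [np.zeros((S, 1), np.int32), np.cumsum(mm, axis=1, dtype=np.int32)],
                axis=1,
            )
            mm0 = cum[:, L].astype(np.int64)
            pen = np.where(mm0 <= k_max, params.pen_mismatch * mm0, _BIG)
            if params.max_gap_opens >= 1:
                j = np.arange(1, L)
                for g in range(1, G + 1):
                    gp = params.pen_gap_open + params.pen_gap_extend * (g - 1)
                    # deletion of g ref bases after read position j
                    if S > g:
                        mg = cum[: S - g, j] + (cum[g:, [L]] - cum[g:, j])
                        mg = np.where(1 + mg <= k_max, mg, _BIG)
                        np.minimum(
                            pen[: S - g],
                            np.minimum(gp + params.pen_mismatch * mg, _BIG).min(axis=1),
                            out=pen[: S - g],
                        )
                    # insertion: read[j:j+g] unaligned, suffix resumes on the
                    # same diagonal minus g
                    ji = np.arange(1, L - g)
                    if ji.size and S > g:
                        mg = cum[g:, ji] + (cum[: S - g, [L]] - cum[: S - g, ji + g])
                        mg = np.where(1 + mg <= k_max, mg, _BIG)
                        np.minimum(
                            pen[g:],
                            np.minimum(gp + params.pen_mismatch * mg, _BIG).min(axis=1),
                            out=pen[g:],
                        )
            cmin = int(pen.min())
            if cmin >= _BIG:
                continue
            if cmin < best:
                best = cmin
                places = [(chrom, int(s), strand) for s in np.flatnonzero(pen == cmin)]
            elif cmin == best:
                places.extend(
                    (chrom, int(s), strand) for s in np.flatnonzero(pen == cmin)
                )
    if best >= _BIG:
        return None, []
    return best, sorted(set(places))


# ---------------------------------------------------------------------------
def _enumerate_paths(graph: VariationGraph) -> list[list[int]]:
    sources = [n for n in graph.nodes if not graph.pred[n]]
    paths: list[list[int]] = []

    def walk(node: int, acc: list[int]) -> None:
        acc = acc + [node]
        succ = graph.succ[node]
        if not succ:
            paths.append(acc)
            return
        for m in sorted(succ):
            walk(m, acc)

    for s in sorted(sources):
        walk(s, [])
        if len(paths) > 512:
            raise ValueError("oracle instance too large: too many paths")
    return paths


def _path_ref_positions(graph: VariationGraph, path: list[int]) -> list[tuple[str, int]]:
    """(chrom, ref position) of every base along a path; insertion bases map
    to the next reference base (the surjection convention)."""
    out: list[tuple[str, int]] = []
    for node in path:
        label = graph.nodes[node]
        if node in graph.node_ref:
            chrom, off = graph.node_ref[node]
            out.extend((chrom, off + i) for i in range(len(label)))
        else:
            rec = graph.alt_node_site[node]
            if rec.vtype == "snp":
                out.extend((rec.chrom, rec.start0 + i) for i in range(len(label)))
            else:  # insertion node
                out.extend((rec.chrom, rec.start0 + 1) for _ in range(len(label)))
    return out


def _sw_best(rd: np.ndarray, tg: np.ndarray, p: GraphAlignerParams):
    """Local Gotoh score matrix maxima: (best, end_target_idx, end_read_idx)."""
    L, n = len(rd), len(tg)
    NEG = np.int32(-(10**9))
    jj = np.arange(L + 1)
    H_prev = np.zeros(L + 1, dtype=np.int32)
    E_prev = np.full(L + 1, NEG, dtype=np.int32)
    best, bb, bj = 0, -1, -1
    for b in range(1, n + 1):
        sub = np.where(rd == tg[b - 1], p.match, -p.mismatch).astype(np.int32)
        E = np.maximum(H_prev - p.gap_open, E_prev - p.gap_extend)
        h = np.maximum(E, 0)
        h[1:] = np.maximum(h[1:], H_prev[:-1] + sub)
        acc = np.maximum.accumulate(h + p.gap_extend * jj)
        f = np.full(L + 1, NEG, dtype=np.int32)
        f[1:] = acc[:-1] - p.gap_open + p.gap_extend - p.gap_extend * jj[1:]
        h = np.maximum(h, f)
        m = int(h.max())
        if m > best:
            best, bb, bj = m, b, int(np.argmax(h))
        H_prev, E_prev = h, E
    return best, bb, bj


def _oracle_graph(read: str, graph: VariationGraph, params: GraphAlignerParams):
    if len(graph.nodes) > 200:
        raise ValueError("oracle instance too large: graph > 200 nodes")
    paths = _enumerate_paths(graph)
    best = 0
    places: list[tuple[str, int, str]] = []
    for path in paths:
        seq = "".join(graph.nodes[n] for n in path)
        refpos = _path_ref_positions(graph, path)
        tg = encode_dna(seq)
        for strand in ("+", "-"):
            rd = encode_dna(read if strand == "+" else revcomp(read))
            score, eb, ej = _sw_best(rd, tg, params)
            if score <= 0 or score < best:
                continue
            # recover the start by aligning the reversed prefixes
            s2, rb, _ = _sw_best(rd[:ej][::-1], tg[:eb][::-1], params)
            start = eb - rb
            place = (refpos[start][0], refpos[start][1], strand)
            if score > best:
                best = score
                places = [place]
            elif place not in places:
                places.append(place)
    return best, sorted(places)
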