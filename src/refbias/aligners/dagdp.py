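"""Affine-gap local alignment of a read against a variation graph.

Gotoh-style dynamic programming over the graph's bases in topological
order.  Alignment may start and end anywhere (softclips at both read ends);
deletion bypass edges are ordinary edges, so deletion alleles cost nothing
beyond the path choice.  Used directly for small graphs and as the exact
refinement step of the batch graph aligner on windowed subgraphs.
"""

from __future__ import annotations

import numpy as np

from ..util import encode_dna
from ..vargraph import GraphAlignment, VariationGraph
from .base import GraphAlignerParams

_NEG = -(10**9)


class _Bases:
    """Flattened base-level view of a graph in topological order."""

    def __init__(self, graph: VariationGraph):
        self.graph = graph
        order = graph.topological_order()
        self.node_of: list[int] = []
        self.off_of: list[int] = []
        self.code: list[int] = []
        self.preds: list[list[int]] = []
        first_base: dict[int, int] = {}
        last_base: dict[int, int] = {}
        for node in order:
            label = encode_dna(graph.nodes[node])
            for off, c in enumerate(label):
                b = len(self.code)
                self.node_of.append(node)
                self.off_of.append(off)
                self.code.append(int(c))
                if off == 0:
                    first_base[node] = b
                    self.preds.append(
                        [last_base[p] for p in sorted(graph.pred[node]) if p in last_base]
                    )
                else:
                    self.preds.append([b - 1])
            last_base[node] = len(self.code) - 1
        self.n = len(self.code)
        self.codes = np.asarray(self.code, dtype=np.uint8)


def dag_align(
    graph: VariationGraph,
    read: str,
    params: GraphAlignerParams,
    read_id: str = "read",
    strand: str = "+",
) -> tuple[GraphAlignment | None, list[float]]:
    """Best local alignment of ``read`` (already oriented) to the graph.

    Returns the alignment (None if no positive-scoring cell exists) and a
    list of candidate scores — the best end-cell score of each
    non-overlapping placement — used for mapping-quality estimation.
    """
    if not read:
        raise ValueError("empty read")
    rd = encode_dna(read)
    L = len(rd)
    p = params
    B = _Bases(graph)
    n = B.n
    H = np.zeros((n, L + 1), dtype=np.int32)
    E = np.full((n, L + 1), _NEG, dtype=np.int32)
    j_idx = np.arange(L + 1)

    for b in range(n):
        preds = B.preds[b]
        sub = np.where(rd == B.codes[b], p.match, -p.mismatch).astype(np.int32)
        diag = np.full(L + 1, _NEG, dtype=np.int32)
        e_here = np.full(L + 1, _NEG, dtype=np.int32)
        if preds:
            for pb in preds:
                np.maximum(diag[1:], H[pb][:-1] + sub, out=diag[1:])
                np.maximum(
                    e_here, np.maximum(H[pb] - p.gap_open, E[pb] - p.gap_extend), out=e_here
                )
        else:  # source base: a local alignment may begin here
            diag[1:] = sub
        E[b] = e_here
        h = np.maximum.reduce([np.zeros(L + 1, np.int32), diag, e_here])
        # F (insertion: consume read bases) within this column, vectorised:
        # F[j] = max_{j'<j} h[j'] - open - (j-j'-1)*ext
        acc = np.maximum.accumulate(h + p.gap_extend * j_idx)
        f = np.full(L + 1, _NEG, dtype=np.int32)
        f[1:] = acc[:-1] - p.gap_open + p.gap_extend - p.gap_extend * j_idx[1:]
        h = np.maximum(h, f)
        H[b] = h

    best = int(H.max())
    if best <= 0:
        return None, []

    # candidate scores: greedy non-overlapping placements by end position
    end_best = H.max(axis=1)
    order = np.argsort(-end_best, kind="stable")
    chosen: list[tuple[int, float]] = []
    for b in order:
        s = int(end_best[b])
        if s <= 0 or len(chosen) >= 8:
            break
        if all(abs(int(b) - cb) >= L for cb, _ in chosen):
            chosen.append((int(b), float(s)))
    cand_scores = [s for _, s in chosen]

    galn = _traceback(B, rd, H, E, p, read_id, strand, best)
    galn.score = float(best)
    return galn, cand_scores


def _traceback(B, rd, H, E, p, read_id, strand, best) -> GraphAlignment:
    L = len(rd)
    # best cell: lowest base index, then lowest j (deterministic)
    flat = int(np.flatnonzero(H == best)[0])
    b, j = divmod(flat, L + 1)
    clip_right = L - j
    steps: list[tuple[str, int]] = []  # (op, base index or -1 for I)
    mismatches = 0
    state = "H"
    while True:
        if state == "H":
            v = int(H[b][j])
            if v == 0:
                break
            sub = p.match if rd[j - 1] == B.codes[b] else -p.mismatch if j >= 1 else None
            # insertion (gap in graph target consuming read bases)?
            moved = False
            for jp in range(j - 1, 0, -1):
                gaplen = j - jp
                if v == int(H[b][jp]) - p.gap_open - (gaplen - 1) * p.gap_extend:
                    steps.extend([("I", -1)] * gaplen)
                    j = jp
                    moved = True
                    break
            if moved:
                continue
            if j >= 1 and v == int(E[b][j]):
                state = "E"
                continue
            # diagonal from some predecessor
            found = False
            for pb in B.preds[b]:
                if j >= 1 and v == int(H[pb][j - 1]) + sub:
                    if sub < 0:
                        mismatches += 1
                    steps.append(("M", b))
                    b, j = pb, j - 1
                    found = True
                    break
            if not found:
                # start of alignment: the diagonal step had no predecessor
                # (first base of a source node)
                if j >= 1 and v == sub and sub > 0:
                    steps.append(("M", b))
                    j -= 1
                    break
                if j >= 1 and v == sub:
                    steps.append(("M", b))
                    mismatches += 1
                    j -= 1
                    break
                raise AssertionError("traceback failed in H state")
        else:  # E: deletion, consume graph base b without read base
            v = int(E[b][j])
            steps.append(("D", b))
            found = False
            for pb in B.preds[b]:
                if v == int(H[pb][j]) - p.gap_open:
                    state = "H"
                    b = pb
                    found = True
                    break
                if v == int(E[pb][j]) - p.gap_extend:
                    b = pb
                    found = True
                    break
            if not found:
                raise AssertionError("traceback failed in E state")

    clip_left = j
    steps.reverse()

    # group steps into per-node cigars
    path: list[int] = []
    per_node: list[list[tuple[str, int]]] = []
    first_off = 0
    for op, bi in steps:
        if op == "I":
            node = path[-1] if path else None
            if node is None:
                # leading insertion before any node: fold into clip
                clip_left += 1
                continue
            ops = per_node[-1]
        else:
            node = B.node_of[bi]
            if not path or node != path[-1]:
                path.append(node)
                per_node.append([])
                if len(path) == 1:
                    first_off = B.off_of[bi]
            ops = per_node[-1]
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    return GraphAlignment(
        read_id=read_id,
        path=path,
        per_node_cigar=per_node,
        label_mismatches=mismatches,
        score=float(best),
        strand=strand,
        clip_left=clip_left,
        clip_right=clip_right,
        first_node_offset=first_off,
    )
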