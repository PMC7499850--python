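"""Variation graph: bubble construction from a variant panel, path spelling,
and surjection of graph alignments onto reference coordinates.

The graph is a DAG of non-empty DNA-labelled nodes.  Each chromosome
contributes a chain of reference nodes split at variant boundaries; a SNP
adds one parallel single-base node, an insertion one extra node between the
split, and a deletion a bypass edge skipping the deleted reference segment
(no empty-label nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synth import ReferenceGenome, VariantPanel, VariantRecord


@dataclass
class VariationGraph:
    nodes: dict[int, str]  # id -> DNA label
    edges: set[tuple[int, int]]
    ref_paths: dict[str, list[int]]  # chromosome -> ordered ref-path node ids
    node_ref: dict[int, tuple[str, int]]  # ref-path node -> (chrom, 0-based ref offset)
    alt_node_site: dict[int, VariantRecord] = field(default_factory=dict)
    deletion_edges: dict[tuple[int, int], VariantRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.succ: dict[int, list[int]] = {n: [] for n in self.nodes}
        self.pred: dict[int, list[int]] = {n: [] for n in self.nodes}
        for u, v in sorted(self.edges):
            self.succ[u].append(v)
            self.pred[v].append(u)

    def label(self, node: int) -> str:
        return self.nodes[node]

    def topological_order(self) -> list[int]:
        indeg = {n: len(self.pred[n]) for n in self.nodes}
        stack = sorted(n for n, d in indeg.items() if d == 0)
        order: list[int] = []
        while stack:
            n = stack.pop(0)
            order.append(n)
            for m in self.succ[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    stack.append(m)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order


def build_graph(ref: ReferenceGenome, panel: VariantPanel) -> VariationGraph:
    """One bubble per variant; errors on overlapping panel records."""
    panel.validate_against(ref)
    nodes: dict[int, str] = {}
    edges: set[tuple[int, int]] = set()
    ref_paths: dict[str, list[int]] = {}
    node_ref: dict[int, tuple[str, int]] = {}
    alt_node_site: dict[int, VariantRecord] = {}
    deletion_edges: dict[tuple[int, int], VariantRecord] = {}
    next_id = 1

    def new_node(label: str) -> int:
        nonlocal next_id
        if not label:
            raise ValueError("empty node label")
        nid = next_id
        nodes[nid] = label
        next_id += 1
        return nid

    for chrom in ref.chroms:
        seq = ref[chrom]
        recs = [r for r in panel if r.chrom == chrom]
        path: list[int] = []
        cursor = 0

        # pending alt nodes whose outgoing edge attaches to the next ref node
        pending_to_next: list[int] = []
        pending_deletion: list[tuple[int, VariantRecord]] = []

        def attach_pending(target: int) -> None:
            for nid in pending_to_next:
                edges.add((nid, target))
            pending_to_next.clear()
            for src, rec in pending_deletion:
                edges.add((src, target))
                deletion_edges[(src, target)] = rec
            pending_deletion.clear()

        def emit_ref(upto: int) -> None:
            """Append the reference node [cursor, upto) to the ref path."""
            nonlocal cursor
            if upto > cursor:
                nid = new_node(seq[cursor:upto])
                node_ref[nid] = (chrom, cursor)
                if path:
                    edges.add((path[-1], nid))
                attach_pending(nid)
                path.append(nid)
                cursor = upto

        for rec in recs:
            p0 = rec.start0
            if rec.vtype == "snp":
                emit_ref(p0)
                before = path[-1] if path else None
                ref_node = new_node(seq[p0 : p0 + 1])
                node_ref[ref_node] = (chrom, p0)
                alt_node = new_node(rec.alt_allele)
                alt_node_site[alt_node] = rec
                if before is not None:
                    edges.add((before, ref_node))
                    edges.add((before, alt_node))
                if pending_to_next or pending_deletion:
                    for nid in list(pending_to_next):
                        edges.add((nid, alt_node))
                    for src, drec in list(pending_deletion):
                        edges.add((src, alt_node))
                        deletion_edges[(src, alt_node)] = drec
                    attach_pending(ref_node)
                path.append(ref_node)
                cursor = p0 + 1
                pending_to_next.append(alt_node)
            elif rec.vtype == "insertion":
                emit_ref(p0 + 1)  # anchor ends the left ref node
                attach_pending(path[-1])
                anchor = path[-1]
                ins_node = new_node(rec.alt_allele[1:])
                alt_node_site[ins_node] = rec
                edges.add((anchor, ins_node))
                pending_to_next.append(ins_node)
            else:  # deletion
                emit_ref(p0 + 1)  # left ref node ends at the anchor
                attach_pending(path[-1])
                anchor = path[-1]
                glen = len(rec.ref_allele) - 1
                # deleted segment as its own ref node
                del_node = new_node(seq[p0 + 1 : p0 + 1 + glen])
                node_ref[del_node] = (chrom, p0 + 1)
                edges.add((anchor, del_node))
                path.append(del_node)
                cursor = p0 + 1 + glen
                pending_deletion.append((anchor, rec))

        emit_ref(len(seq))
        if pending_to_next or pending_deletion:
            # variant at the very end of the chromosome: nothing to attach to
            raise ValueError(f"variant too close to the end of {chrom}")
        ref_paths[chrom] = path

    return VariationGraph(nodes, edges, ref_paths, node_ref, alt_node_site, deletion_edges)


@dataclass
class GraphAlignment:
    """Alignment of a read to a node path, before surjection.

    ``per_node_cigar`` holds, for each path node, operations of the read
    against that node's label: M (aligned base, match or mismatch), I (read
    base absent from the label), D (label base skipped).  The alignment
    enters the first node at label offset ``first_node_offset`` and may end
    before the last node's label does; intermediate nodes are fully
    traversed.  ``label_mismatches`` counts M positions whose read base
    differs from the label.  Unaligned read ends are softclips.
    """

    read_id: str
    path: list[int]
    per_node_cigar: list[list[tuple[str, int]]]
    label_mismatches: int
    score: float
    mapq: int = 0
    strand: str = "+"
    clip_left: int = 0
    clip_right: int = 0
    first_node_offset: int = 0

    def read_bases_aligned(self) -> int:
        return sum(
            ln for ops in self.per_node_cigar for op, ln in ops if op in ("M", "I")
        )


def spell_path(graph: VariationGraph, node_path: list[int]) -> str:
    """Concatenated labels of an edge-connected node path."""
    if not node_path:
        return ""
    for u, v in zip(node_path, node_path[1:]):
        if (u, v) not in graph.edges:
            raise ValueError(f"path not edge-connected at {u}->{v}")
    return "".join(graph.nodes[n] for n in node_path)


class UnplaceableAlignment(ValueError):
    """Raised when a graph alignment touches no reference-path node."""


def surject_alignment(graph: VariationGraph, galn: GraphAlignment):
    """Project a graph alignment onto the reference path.

    Alt-SNP node bases become reference mismatches (M, NM incremented),
    insertion-node bases become I, bypassed reference nodes become D, and
    unaligned read ends become S.  The reported position is the reference
    offset of the first M/D base; an alignment entirely inside alt nodes is
    unplaceable.
    """
    from .aligners import Alignment  # local import to avoid a cycle

    cigar: list[tuple[str, int]] = []
    nm = galn.label_mismatches
    pos: int | None = None
    chrom: str | None = None
    ref_cursor: int | None = None  # expected next ref offset along the path

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    push("S", galn.clip_left)
    for k, (node, ops) in enumerate(zip(galn.path, galn.per_node_cigar)):
        used_label = sum(ln for op, ln in ops if op in ("M", "D"))
        in_offset = galn.first_node_offset if k == 0 else 0
        if node in graph.node_ref:
            nchrom, noff = graph.node_ref[node]
            node_start = noff + in_offset
            if ref_cursor is not None and chrom == nchrom and node_start > ref_cursor:
                # deletion-bypass edge skipped [ref_cursor, node_start)
                dlen = node_start - ref_cursor
                push("D", dlen)
                nm += dlen
            if pos is None and used_label > 0:
                chrom, pos = nchrom, node_start
            for op, ln in ops:
                push(op, ln)
                if op in ("I", "D"):
                    nm += ln
            ref_cursor = node_start + used_label
            chrom = nchrom
        else:
            rec = graph.alt_node_site.get(node)
            if rec is None:
                raise ValueError(f"node {node} is neither on the ref path nor an alt node")
            if rec.vtype == "snp":
                # alt base aligns to the reference base it replaces
                if pos is None and used_label > 0:
                    chrom, pos = rec.chrom, rec.start0 + in_offset
                for op, ln in ops:
                    push(op, ln)
                    nm += ln  # M here is a reference mismatch; I/D as usual
                ref_cursor = rec.start0 + in_offset + used_label
                chrom = rec.chrom
            else:  # insertion node: aligned bases are insertions vs reference
                ilen = sum(ln for op, ln in ops if op in ("M", "I"))
                if pos is None:
                    # read starts inside the insertion: clip those bases and
                    # report the following reference base (SAM-conformant)
                    push("S", ilen)
                else:
                    push("I", ilen)
                    nm += ilen
                # insertion consumes no reference bases
                if ref_cursor is None:
                    ref_cursor = rec.start0 + 1
                chrom = rec.chrom

    push("S", galn.clip_right)
    if pos is None or chrom is None:
        raise UnplaceableAlignment(f"read {galn.read_id}: alignment touches no reference base")

    # leading S before the first M must absorb any I that never reached ref
    read_len = galn.clip_left + galn.read_bases_aligned() + galn.clip_right
    return Alignment(
        read_id=galn.read_id,
        mapped=True,
        chrom=chrom,
        pos=pos,
        strand=galn.strand,
        cigar=tuple(cigar),
        nm=nm,
        score=galn.score,
        mapq=galn.mapq,
    )
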