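"""Exact k-mer seeding over a concatenated target space.

Both aligners locate candidate placements from exact anchor matches.  The
target space is one uint8 code array containing every alignable sequence
(reference chromosomes, and for the graph aligner also per-variant allele
contexts) laid out back to back; k-mer windows crossing a segment boundary
are excluded from the index.
"""

from __future__ import annotations

import numpy as np


def pack_kmers(mat: np.ndarray, k: int, offset: int) -> np.ndarray:
    """Pack the k-mer starting at ``offset`` of every row into an int64."""
    out = np.zeros(mat.shape[0], dtype=np.int64)
    for j in range(k):
        out = (out << 2) | mat[:, offset + j].astype(np.int64)
    return out


def ragged_take(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Indices [s, s+c) for each (start, count) pair, concatenated."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    reps = np.repeat(starts - np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
    return reps + np.arange(total, dtype=np.int64)


class SeqIndex:
    """Sorted k-mer tables over a segmented code array."""

    def __init__(self, codes: np.ndarray, seg_starts: np.ndarray, ks: tuple[int, ...]):
        self.codes = codes
        self.seg_starts = np.asarray(seg_starts, dtype=np.int64)  # includes 0
        self.seg_ends = np.concatenate([self.seg_starts[1:], [len(codes)]])
        self.tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in sorted(set(ks)):
            self._build(k)

    def _build(self, k: int) -> None:
        n = len(self.codes) - k + 1
        if n <= 0:
            self.tables[k] = (np.empty(0, np.int64), np.empty(0, np.int64))
            return
        vals = np.zeros(n, dtype=np.int64)
        for j in range(k):
            vals = (vals << 2) | self.codes[j : j + n].astype(np.int64)
        valid = np.ones(n, dtype=bool)
        for b in self.seg_starts[1:]:
            valid[max(0, b - k + 1) : b] = False
        pos = np.flatnonzero(valid)
        v = vals[pos]
        order = np.argsort(v, kind="stable")
        self.tables[k] = (v[order], pos[order])

    def lookup(self, queries: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Positions of each query k-mer: (query_index, target_position)."""
        vals, pos = self.tables[k]
        lo = np.searchsorted(vals, queries, side="left")
        hi = np.searchsorted(vals, queries, side="right")
        counts = hi - lo
        qidx = np.repeat(np.arange(len(queries), dtype=np.int64), counts)
        return qidx, pos[ragged_take(lo, counts)]

    def segment_of(self, positions: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.seg_starts, positions, side="right") - 1


def anchor_offsets(read_len: int, n_anchors: int, anchor_len: int) -> list[int]:
    """Evenly spaced anchor start offsets covering the read."""
    n_anchors = max(1, n_anchors)
    anchor_len = min(anchor_len, read_len)
    if n_anchors == 1:
        return [0]
    span = read_len - anchor_len
    return sorted({round(i * span / (n_anchors - 1)) for i in range(n_anchors)})


def candidate_diagonals(
    mat: np.ndarray,
    index: SeqIndex,
    anchors: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate (row, diagonal) pairs from exact anchor hits.

    ``anchors`` is a list of (k, read_offset).  A diagonal is the target-space
    position at which the read's first base would sit; only diagonals whose
    full read window stays inside one target segment are kept.  Result is
    deduplicated and sorted by (row, diagonal).
    """
    L = mat.shape[1]
    rows_all: list[np.ndarray] = []
    diags_all: list[np.ndarray] = []
    for k, off in anchors:
        q = pack_kmers(mat, k, off)
        qidx, tpos = index.lookup(q, k)
        diag = tpos - off
        keep = diag >= 0
        rows_all.append(qidx[keep])
        diags_all.append(diag[keep])
    rows = np.concatenate(rows_all) if rows_all else np.empty(0, np.int64)
    diags = np.concatenate(diags_all) if diags_all else np.empty(0, np.int64)
    if rows.size == 0:
        return rows, diags
    # window must stay inside one segment
    seg = index.segment_of(diags)
    keep = diags + L <= index.seg_ends[seg]
    rows, diags = rows[keep], diags[keep]
    # dedup (row, diag)
    key = rows * (int(index.seg_ends[-1]) + 1) + diags
    _, first = np.unique(key, return_index=True)
    first.sort()
    return rows[first], diags[first]
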