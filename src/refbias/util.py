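"""Small shared helpers: DNA encoding, reverse complement, seeded RNG streams."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"

# 256-entry lookup: ASCII byte -> 2-bit code (A=0 C=1 G=2 T=3), 255 for anything else
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_dna(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array of 2-bit codes."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = int(np.argmax(arr > 3))
        raise ValueError(f"non-ACGT base {seq[bad]!r} at position {bad}")
    return arr


def decode_dna(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def rng_stream(seed: int, *tags: str) -> np.random.Generator:
    """Named child RNG stream derived from a single master seed.

    Every source of randomness in the package draws from one of these, so a
    run is fully reproducible from one integer seed and independent stages
    do not share a stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(t.encode()) & 0x7FFFFFFF for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every length-k window of a 2-bit code array into one integer.

    Returns an int64 array of length ``len(codes) - k + 1``.
    """
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = (out << 2) | codes[j : j + n].astype(np.int64)
    return out
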