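"""ABBA-BABA D-statistic with a block jackknife.

Tests whether a calling condition drags pseudo-haploid genotypes toward the
reference: for quartets (P1, P2; P3, P4) with P4 the outgroup, an excess of
ABBA over BABA patterns (D < 0 with P3 an all-reference "sample") indicates
that P1's calls share more alleles with the reference than P2's do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import PopulationQuartet


@dataclass
class DStatResult:
    n_abba: int
    n_baba: int
    D: float
    jackknife_se: float
    Z: float
    n_blocks: int
    undefined: bool = False  # no informative sites

    def as_row(self) -> dict:
        return {
            "ABBA": self.n_abba,
            "BABA": self.n_baba,
            "D": self.D,
            "SE": self.jackknife_se,
            "Z": self.Z,
            "n_blocks": self.n_blocks,
        }


def site_patterns(q: PopulationQuartet) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-site ABBA and BABA indicators (complete cases only).

    ABBA: p1 = p4 != p2 = p3;  BABA: p2 = p4 != p1 = p3.
    Sites with any missing allele are uninformative.
    """
    p1, p2, p3, p4 = q.alleles
    complete = (q.alleles >= 0).all(axis=0)
    abba = complete & (p1 == p4) & (p2 == p3) & (p1 != p2)
    baba = complete & (p2 == p4) & (p1 == p3) & (p1 != p2)
    return abba, baba


def block_jackknife(
    per_site_num: np.ndarray, per_site_den: np.ndarray, block_size_sites: int = 100
) -> tuple[float, int]:
    """Delete-one-block jackknife standard error of sum(num)/sum(den).

    Blocks are consecutive runs of ``block_size_sites`` sites; blocks with
    zero denominator are dropped.  Requires at least two non-empty blocks.
    """
    num = np.asarray(per_site_num, dtype=float)
    den = np.asarray(per_site_den, dtype=float)
    if block_size_sites < 1:
        raise ValueError("block_size_sites must be >= 1")
    n_sites = num.size
    edges = np.arange(0, n_sites + block_size_sites, block_size_sites)
    bn = []
    bd = []
    for a, b in zip(edges[:-1], edges[1:]):
        d = den[a:b].sum()
        if d > 0:
            bn.append(num[a:b].sum())
            bd.append(d)
    B = len(bn)
    if B < 2:
        raise ValueError("need at least two non-empty blocks")
    bn_arr = np.asarray(bn)
    bd_arr = np.asarray(bd)
    tot_n, tot_d = bn_arr.sum(), bd_arr.sum()
    d_jack = (tot_n - bn_arr) / (tot_d - bd_arr)  # delete-one estimates
    se = float(np.sqrt((B - 1) / B * np.sum((d_jack - d_jack.mean()) ** 2)))
    return se, B


def dstat_abba_baba(q: PopulationQuartet, block_size_sites: int = 100) -> DStatResult:
    """D = (ABBA - BABA) / (ABBA + BABA) with jackknife SE and Z = D/SE."""
    abba, baba = site_patterns(q)
    n_abba = int(abba.sum())
    n_baba = int(baba.sum())
    total = n_abba + n_baba
    if total == 0:
        return DStatResult(0, 0, float("nan"), float("nan"), float("nan"), 0, True)
    d = (n_abba - n_baba) / total
    num = abba.astype(float) - baba.astype(float)
    den = abba.astype(float) + baba.astype(float)
    try:
        se, n_blocks = block_jackknife(num, den, block_size_sites)
    except ValueError:
        return DStatResult(n_abba, n_baba, d, float("nan"), float("nan"), 1, False)
    z = d / se if se > 0 else float("inf") if d != 0 else 0.0
    return DStatResult(n_abba, n_baba, d, se, z, n_blocks)


def swap_p1_p2(q: PopulationQuartet) -> PopulationQuartet:
    """Quartet with P1 and P2 exchanged (negates D exactly)."""
    alleles = q.alleles.copy()
    alleles[[0, 1]] = alleles[[1, 0]]
    return PopulationQuartet(alleles, q.ancestral.copy(), list(q.site_keys))


def with_reference_p3(q: PopulationQuartet) -> PopulationQuartet:
    """Quartet whose P3 is replaced by an all-reference 'sample'.

    This is the configuration used to detect reference bias: excess allele
    sharing between P1 and the reference genome drives D negative.
    """
    alleles = q.alleles.copy()
    alleles[2] = 0
    return PopulationQuartet(alleles, q.ancestral.copy(), list(q.site_keys))
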