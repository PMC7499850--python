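"""Readers and writers for the formats the pipeline touches.

FASTA / FASTQ / VCF / SAM / GFA, lossless for the fields this pipeline
uses.  Reading goes through the ecosystem parsers (pyfaidx, pysam, cyvcf2)
wherever one exists; writers emit minimal, valid text.  Malformed records
raise with the offending record named — never a silent skip.

The GFA writer stores variant metadata in optional ``va``/``vd`` tags so a
graph round-trips completely (S/L/P lines alone cannot carry allele
provenance).
"""

from __future__ import annotations

import numpy as np
import pysam
from cyvcf2 import VCF
from pyfaidx import Fasta

from .aligners import Alignment
from .damage import SimulatedRead
from .genotype import GenotypeCall
from .synth import DiploidSample, ReferenceGenome, VariantPanel, VariantRecord
from .vargraph import VariationGraph


# ---------------------------------------------------------------- FASTA
def write_fasta(ref: ReferenceGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in ref.chroms:
            fh.write(f">{name}\n")
            seq = ref[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> ReferenceGenome:
    fa = Fasta(path, sequence_always_upper=True, rebuild=True)
    try:
        return ReferenceGenome({name: str(fa[name][:]) for name in fa.keys()})
    finally:
        fa.close()


# ---------------------------------------------------------------- FASTQ
def write_fastq(reads: list[SimulatedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = chr(r.qual + 33) * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{q}\n")


def read_fastq(path: str) -> list[SimulatedRead]:
    reads: list[SimulatedRead] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ (line count {len(lines)})")
    for i in range(0, len(lines), 4):
        if not lines[i].startswith("@") or lines[i + 2][:1] != "+":
            raise ValueError(f"{path}: malformed record at line {i + 1}")
        seq = lines[i + 1]
        quals = lines[i + 3]
        if len(seq) != len(quals):
            raise ValueError(f"{path}: SEQ/QUAL length mismatch at line {i + 1}")
        qual = ord(quals[0]) - 33 if quals else 30
        reads.append(SimulatedRead(lines[i][1:].split()[0], seq, qual=qual))
    return reads


def write_truth_table(reads: list[SimulatedRead], path: str) -> None:
    """Tab-separated truth sidecar for a FASTQ (one row per read)."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsource\tchrom\tref_start\tref_end\tstrand\tsite_id\t"
            "allele\tn_damage\n"
        )
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.source}\t{r.chrom}\t{r.ref_start}\t{r.ref_end}\t"
                f"{r.strand}\t{r.site_id or '.'}\t{r.carried_allele or '.'}\t"
                f"{len(r.damage_positions)}\n"
            )


# ---------------------------------------------------------------- VCF
def write_panel_vcf(panel: VariantPanel, path: str) -> None:
    """Minimal VCF 4.2 with the AF INFO tag."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in panel:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t"
                f"AF={r.maf:.6g}\n"
            )


def _vtype_of(ref_a: str, alt_a: str) -> str:
    if len(ref_a) == 1 and len(alt_a) == 1:
        return "snp"
    return "deletion" if len(ref_a) > len(alt_a) else "insertion"


def read_panel_vcf(path: str, ref: ReferenceGenome | None = None) -> VariantPanel:
    """Load a biallelic panel; rejects multi-allelic records and indels that
    are not left-anchored."""
    records: list[VariantRecord] = []
    for v in VCF(path):
        if len(v.ALT) != 1:
            raise ValueError(f"{path}: multi-allelic record at {v.CHROM}:{v.POS}")
        ref_a, alt_a = v.REF, v.ALT[0]
        vtype = _vtype_of(ref_a, alt_a)
        if vtype != "snp":
            if min(len(ref_a), len(alt_a)) != 1 or ref_a[0] != alt_a[0]:
                raise ValueError(
                    f"{path}: indel at {v.CHROM}:{v.POS} is not left-anchored"
                )
        af = v.INFO.get("AF")
        maf = float(af if af is not None else 0.0)
        records.append(VariantRecord(v.CHROM, v.POS, ref_a, alt_a, vtype, maf))
    panel = VariantPanel(records)
    if ref is not None:
        panel.validate_against(ref)
    return panel


def write_diploid_vcf(sample: DiploidSample, path: str) -> None:
    """Phased-GT truth VCF for the synthetic diploid (hap A | hap B)."""
    gt_map = {"hom_ref": "0|0", "het": "0|1", "hom_alt": "1|1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in sample.panel:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.\t"
                f"GT\t{gt_map[sample.genotypes[r.key]]}\n"
            )


def write_calls_vcf(calls: list[GenotypeCall], path: str) -> None:
    gt_map = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "no_call": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in (
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        ):
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in calls:
            r = c.site
            gq = "." if np.isnan(c.qual) else str(int(round(min(c.qual, 99))))
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.\t"
                f"GT:DP:AD:GQ\t{gt_map[c.genotype]}:{c.depth}:{c.ad_ref},{c.ad_alt}:{gq}\n"
            )


# ---------------------------------------------------------------- SAM
def _cigar_str(cigar) -> str:
    return "".join(f"{ln}{op}" for op, ln in cigar) if cigar else "*"


def write_sam(
    alignments,
    ref: ReferenceGenome,
    path: str,
    reads: list[SimulatedRead] | None = None,
    sort: bool = False,
) -> None:
    """SAM text with @HD/@SQ headers, NM and AS tags.

    ``reads`` (same order) supplies SEQ/QUAL; '*' is written otherwise.
    ``sort=True`` orders records by coordinate.
    """
    rows = []
    for i, a in enumerate(alignments):
        seq = "*"
        qual = "*"
        if reads is not None:
            r = reads[i]
            seq = r.sequence
            qual = chr(r.qual + 33) * len(seq)
        if a.mapped:
            flag = 16 if a.strand == "-" else 0
            rows.append(
                (
                    a.chrom,
                    a.pos,
                    f"{a.read_id}\t{flag}\t{a.chrom}\t{a.pos + 1}\t{a.mapq}\t"
                    f"{_cigar_str(a.cigar)}\t*\t0\t0\t{seq}\t{qual}\t"
                    f"NM:i:{a.nm}\tAS:i:{int(a.score)}",
                )
            )
        else:
            rows.append((None, 0, f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}"))
    if sort:
        chrom_rank = {c: i for i, c in enumerate(ref.chroms)}
        rows.sort(key=lambda r: (r[0] is None, chrom_rank.get(r[0], 0), r[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6" + ("\tSO:coordinate" if sort else "") + "\n")
        for c in ref.chroms:
            fh.write(f"@SQ\tSN:{c}\tLN:{ref.length(c)}\n")
        for _, _, line in rows:
            fh.write(line + "\n")


def read_sam(path: str) -> tuple[list[Alignment], list[SimulatedRead]]:
    """Parse SAM text back into alignments (+ sequence shells).

    Raises on CIGAR/SEQ length disagreement, naming the record.
    """
    alignments: list[Alignment] = []
    reads: list[SimulatedRead] = []
    try:
        fh = pysam.AlignmentFile(path, "r", check_sq=False)
    except (OSError, ValueError) as exc:
        raise ValueError(f"{path}: malformed SAM: {exc}") from exc
    with fh:
        for rec in _iter_sam(fh, path):
            seq = rec.query_sequence or ""
            if rec.is_unmapped:
                alignments.append(Alignment(rec.query_name, False))
            else:
                cigar = tuple(
                    ("MIDNSHP=XB"[op], ln) for op, ln in rec.cigartuples or ()
                )
                read_span = sum(ln for op, ln in cigar if op in ("M", "I", "S"))
                if seq and read_span != len(seq):
                    raise ValueError(
                        f"{path}: CIGAR/SEQ length mismatch for {rec.query_name}"
                    )
                alignments.append(
                    Alignment(
                        read_id=rec.query_name,
                        mapped=True,
                        chrom=rec.reference_name,
                        pos=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        cigar=cigar,
                        nm=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                        score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                        mapq=rec.mapping_quality,
                    )
                )
            q = rec.query_qualities
            reads.append(
                SimulatedRead(rec.query_name, seq, qual=int(q[0]) if q is not None and len(q) else 30)
            )
    return alignments, reads


def _iter_sam(fh, path):
    it = iter(fh)
    while True:
        try:
            yield next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as exc:
            raise ValueError(
                f"{path}: malformed SAM record (CIGAR/SEQ mismatch or parse error): {exc}"
            ) from exc


# ---------------------------------------------------------------- GFA
def write_gfa(graph: VariationGraph, path: str) -> None:
    """GFA 1.0: S lines (with variant tags on alt nodes), L lines, one P
    line per chromosome reference path."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes):
            tags = ""
            if nid in graph.alt_node_site:
                r = graph.alt_node_site[nid]
                tags = f"\tva:Z:{r.chrom},{r.pos},{r.ref_allele},{r.alt_allele},{r.vtype},{r.maf:.6g}"
            elif nid in graph.node_ref:
                chrom, off = graph.node_ref[nid]
                tags = f"\tvr:Z:{chrom},{off}"
            fh.write(f"S\t{nid}\t{graph.nodes[nid]}{tags}\n")
        for u, v in sorted(graph.edges):
            tags = ""
            if (u, v) in graph.deletion_edges:
                r = graph.deletion_edges[(u, v)]
                tags = f"\tvd:Z:{r.chrom},{r.pos},{r.ref_allele},{r.alt_allele},{r.vtype},{r.maf:.6g}"
            fh.write(f"L\t{u}\t+\t{v}\t+\t0M{tags}\n")
        for chrom, path_nodes in graph.ref_paths.items():
            fh.write(
                f"P\t{chrom}\t{','.join(f'{n}+' for n in path_nodes)}\t*\n"
            )


def _parse_variant_tag(val: str) -> VariantRecord:
    chrom, pos, ref_a, alt_a, vtype, maf = val.split(",")
    return VariantRecord(chrom, int(pos), ref_a, alt_a, vtype, float(maf))


def read_gfa(path: str) -> VariationGraph:
    nodes: dict[int, str] = {}
    edges: set[tuple[int, int]] = set()
    ref_paths: dict[str, list[int]] = {}
    node_ref: dict[int, tuple[str, int]] = {}
    alt_node_site: dict[int, VariantRecord] = {}
    deletion_edges: dict[tuple[int, int], VariantRecord] = {}
    with open(path) as fh:
        for ln_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("H", ""):
                continue
            try:
                if parts[0] == "S":
                    nid = int(parts[1])
                    nodes[nid] = parts[2]
                    for tag in parts[3:]:
                        if tag.startswith("va:Z:"):
                            alt_node_site[nid] = _parse_variant_tag(tag[5:])
                        elif tag.startswith("vr:Z:"):
                            chrom, off = tag[5:].rsplit(",", 1)
                            node_ref[nid] = (chrom, int(off))
                elif parts[0] == "L":
                    u, v = int(parts[1]), int(parts[3])
                    edges.add((u, v))
                    for tag in parts[6:]:
                        if tag.startswith("vd:Z:"):
                            deletion_edges[(u, v)] = _parse_variant_tag(tag[5:])
                elif parts[0] == "P":
                    ref_paths[parts[1]] = [
                        int(x[:-1]) for x in parts[2].split(",") if x
                    ]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed GFA line {ln_no}: {line!r}") from exc
    return VariationGraph(nodes, edges, ref_paths, node_ref, alt_node_site, deletion_edges)
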