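"""End-to-end experiments: fixtures, conditions, and report tables.

Each experiment function is deterministic given its seed and returns plain
data (dataclasses / DataFrames); :func:`run_experiment` bundles them and
writes the TSV reports.  The same functions back the command-line interface
and the acceptance script, so numbers quoted anywhere are produced by this
code path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aligners import (
    GraphAligner,
    GraphAlignerParams,
    LinearAligner,
    LinearAlignerParams,
)
from .damage import (
    DamageModel,
    apply_deamination,
    enumerate_site_reads,
    sample_shotgun_reads,
)
from .debias import alt_ref_merge, build_alt_reference, modified_read_filter
from .evaluate import BiasReport, bias_report, contaminant_mapping_rate, damage_profile, sensitivity_by_damage
from .genotype import (
    call_diploid_genotypes,
    downsample_alignments,
    het_recovery,
    indel_support_by_length,
    pileup_sites,
)
from .popgen import dstat_abba_baba, with_reference_p3
from .synth import (
    VariantPanel,
    VariantRecord,
    make_contaminant_genome,
    make_diploid_sample,
    make_population_quartet,
    make_reference,
    make_variant_panel,
)
from .util import rng_stream
from .vargraph import build_graph

logger = logging.getLogger(__name__)

RELAXED_LINEAR = dict(n_frac=0.01, max_gap_opens=2)


@dataclass
class RunConfig:
    """Scale and thresholds of a full pipeline run.

    ``from_file`` reads a flat key=value text file with the same names as
    the fields (and CLI flags); values given on the command line win.
    """

    seed: int
    outdir: str = "refbias_out"
    read_len: int = 50
    n_snps: int = 2000
    chrom_len: int = 220_000
    min_spacing: int = 100
    damage_grid: tuple = (0.0, 0.1, 0.2, 0.3)
    mapq_graph: int = 50
    mapq_linear: int = 30
    mapq_relaxed: int = 25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.mapq_linear <= 37 or not 0 <= self.mapq_graph <= 60:
            raise ValueError("mapq thresholds outside the aligner caps")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        values: dict = {}
        with open(path) as fh:
            for ln_no, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln_no}: expected key=value")
                key, val = (x.strip() for x in line.split("=", 1))
                if key == "damage_grid":
                    values[key] = tuple(float(x) for x in val.split(","))
                elif key == "outdir":
                    values[key] = val
                elif "." in val:
                    values[key] = float(val)
                else:
                    values[key] = int(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _subset(tab, idx):
    """Row subset of an AlignmentTable."""
    from .aligners import AlignmentTable

    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    return AlignmentTable(
        [tab.read_ids[i] for i in idx],
        tab.mapped[idx],
        [tab.chroms[i] for i in idx],
        tab.pos[idx],
        tab.strand[idx],
        tab.mapq[idx],
        tab.score[idx],
        tab.nm[idx],
        [tab.cigars[i] for i in idx],
        tab.n_best[idx],
        tab.n_subopt[idx],
        [tab.reasons[i] for i in idx],
    )


def _pooled_fraction(reports: list[BiasReport]) -> tuple[float, tuple[float, float]]:
    alt = sum(r.n_alt_mapped for r in reports)
    ref = sum(r.n_ref_mapped for r in reports)
    total = alt + ref
    if total == 0:
        return float("nan"), (float("nan"), float("nan"))
    f = alt / total
    half = 1.96 * float(np.sqrt(max(f * (1 - f), 0.0) / total))
    return f, (f - half, f + half)


# ---------------------------------------------------------------- fixtures
def build_snp_fixture(seed: int, n_snps: int, chrom_len: int, min_spacing: int = 100):
    ref = make_reference({"chr1": chrom_len}, gc_fraction=0.41, seed=seed)
    panel = make_variant_panel(
        ref, n_snps=n_snps, n_indels=0, min_spacing=min_spacing, seed=seed
    )
    graph = build_graph(ref, panel)
    return ref, panel, graph


# ---------------------------------------------------------------- Fig 2 analogue
def allele_balance_experiment(cfg: RunConfig) -> dict:
    """Exhaustive allele-swapped simulation under every condition.

    Conditions: graph aligner (mapq >= 50), plain linear aligner at the
    strict difference budget (mapq >= 30), read-modification filtering on
    the strict alignments, and alternate-reference merging with relaxed
    parameters (mapq >= 25).  Reports are per damage level plus pooled
    alternate-allele fractions.
    """
    ref, panel, graph = build_snp_fixture(
        cfg.seed, cfg.n_snps, cfg.chrom_len, cfg.min_spacing
    )
    ga = GraphAligner(graph)
    strict = LinearAlignerParams()
    relaxed = LinearAlignerParams(**RELAXED_LINEAR)
    la = LinearAligner(ref, strict)
    altref = build_alt_reference(ref, panel)
    base_reads = enumerate_site_reads(ref, panel, cfg.read_len)
    model = DamageModel.exponential()

    per_level: dict[str, list[BiasReport]] = {
        "graph": [], "linear": [], "modreads": [], "altref": []
    }
    for li, rate in enumerate(cfg.damage_grid):
        reads = apply_deamination(
            base_reads, model, rate, seed=int(rng_stream(cfg.seed, "damage-level", str(li)).integers(2**31))
        )
        gtab = ga.align_batch(reads)
        per_level["graph"].append(
            bias_report(gtab, reads, cfg.mapq_graph, f"graph@{rate}")
        )
        ltab = la.align_batch(reads)
        per_level["linear"].append(
            bias_report(ltab, reads, cfg.mapq_linear, f"linear@{rate}")
        )
        keep, _ = modified_read_filter(ltab, reads, panel, la)
        idx = np.flatnonzero(keep)
        per_level["modreads"].append(
            bias_report(
                _subset(ltab, idx), [reads[i] for i in idx], cfg.mapq_linear,
                f"modreads@{rate}",
            )
        )
        merged, _ = alt_ref_merge(reads, ref, altref, relaxed, seed=cfg.seed + li)
        per_level["altref"].append(
            bias_report(merged, reads, cfg.mapq_relaxed, f"altref@{rate}")
        )
        logger.info("damage level %.2f done", rate)

    pooled = {}
    for cond, reports in per_level.items():
        f, ci = _pooled_fraction(reports)
        pooled[cond] = {"alt_fraction": f, "ci_lo": ci[0], "ci_hi": ci[1]}
    if len(set(cfg.damage_grid)) >= 2:
        slopes = {
            "graph": sensitivity_by_damage(cfg.damage_grid, per_level["graph"]),
            "linear": sensitivity_by_damage(cfg.damage_grid, per_level["linear"]),
        }
    else:
        slopes = None  # a flat grid supports no damage-response regression
    table = pd.DataFrame(
        [r.as_row() for reports in per_level.values() for r in reports]
    )
    return {"per_level": per_level, "pooled": pooled, "slopes": slopes, "table": table}


# ---------------------------------------------------------------- Fig 4 analogue
def indel_detection_experiment(
    seed: int,
    n_per_length: int = 4,
    indel_len_max: int = 18,
    read_len: int = 50,
    chrom_len: int = 120_000,
) -> dict:
    """Alternate-allele support by indel length for both aligners.

    The panel carries ``n_per_length`` indels of every length 1..max; all
    enumerated reads are piled up per aligner and alternate support
    averaged per length.  The linear aligner's single-gap budget should
    truncate support beyond 1 + max_gap_extensions; the graph pipeline
    should stay roughly flat.
    """
    ref = make_reference({"chr1": chrom_len}, 0.41, seed=seed)
    rng = rng_stream(seed, "indel-panel")
    seq = ref["chr1"]
    records = []
    pos = 300
    lengths = [l for l in range(1, indel_len_max + 1) for _ in range(n_per_length)]
    rng.shuffle(lengths)
    for g in lengths:
        anchor = seq[pos]
        if rng.random() < 0.5:
            rec = VariantRecord(
                "chr1", pos + 1, seq[pos : pos + 1 + g], anchor, "deletion", 0.1
            )
        else:
            ins = "".join("ACGT"[k] for k in rng.integers(0, 4, size=g))
            rec = VariantRecord("chr1", pos + 1, anchor, anchor + ins, "insertion", 0.1)
        records.append(rec)
        pos += 150
    panel = VariantPanel(records)
    graph = build_graph(ref, panel)
    reads = enumerate_site_reads(ref, panel, read_len)

    # simulated alternate reads per site, for normalised recovery
    n_alt = {}
    for r in reads:
        if r.carried_allele == "alt":
            n_alt[r.site_id] = n_alt.get(r.site_id, 0) + 1
    per_len_alt = {}
    for rec in panel:
        sid = f"{rec.chrom}:{rec.pos}"
        per_len_alt.setdefault(rec.indel_len, []).append(n_alt.get(sid, 0))

    out = {}
    gtab = GraphAligner(graph).align_batch(reads)
    out["graph"] = indel_support_by_length(
        pileup_sites(gtab, reads, panel, min_mapq=50, ref=ref), panel
    )
    ltab = LinearAligner(ref).align_batch(reads)
    out["linear"] = indel_support_by_length(
        pileup_sites(ltab, reads, panel, min_mapq=30, ref=ref), panel
    )
    for df in out.values():
        df["n_alt_simulated"] = [float(np.mean(per_len_alt[ln])) for ln in df["indel_len"]]
        df["alt_recovery"] = df["mean_ad_alt"] / df["n_alt_simulated"]
    return out


def long_deletion_experiment(seed: int, del_len: int = 32, read_len: int = 50) -> dict:
    """Synthetic long-deletion fixture (a 32-bp CCR5-style allele).

    Reads drawn across the deletion junction map through the graph (which
    carries the allele) but exceed the linear aligner's gap budget.
    """
    ref = make_reference({"chr1": 20_000}, 0.41, seed=seed)
    seq = ref["chr1"]
    p0 = 10_000
    rec = VariantRecord(
        "chr1", p0 + 1, seq[p0 : p0 + 1 + del_len], seq[p0], "deletion", 0.1
    )
    panel = VariantPanel([rec])
    graph = build_graph(ref, panel)
    reads = [r for r in enumerate_site_reads(ref, panel, read_len) if r.carried_allele == "alt"]
    gtab = GraphAligner(graph).align_batch(reads)
    ltab = LinearAligner(ref).align_batch(reads)
    g_ok = gtab.mapped & (gtab.mapq >= 50)
    correct = g_ok & (gtab.pos == np.array([r.ref_start for r in reads]))
    return {
        "n_reads": len(reads),
        "graph_mapped_frac": float(g_ok.mean()),
        "graph_correct_frac": float(correct.mean()),
        "linear_mapped_frac": float(ltab.mapped.mean()),
    }


# ---------------------------------------------------------------- D statistics
def dstat_null_experiment(
    seed: int, n_reps: int = 100, n_sites: int = 2000, block: int = 100
) -> dict:
    """Unbiased symmetric quartets: |Z| should stay below 3 almost always."""
    ref = make_reference({"chr1": max(1000, n_sites) * 40}, 0.41, seed=seed)
    panel = make_variant_panel(ref, n_snps=n_sites, min_spacing=35, seed=seed, edge_margin=60)
    zs = []
    for rep in range(n_reps):
        q = make_population_quartet(
            panel, (0.02, 0.02, 0.1, 0.0), bias_toward_ref=0.0,
            seed=int(rng_stream(seed, "dstat-null", str(rep)).integers(2**31)),
        )
        res = dstat_abba_baba(q, block)
        zs.append(res.Z)
    zs = np.asarray(zs)
    return {
        "n_reps": n_reps,
        "frac_abs_z_below_3": float(np.mean(np.abs(zs) < 3)),
        "mean_z": float(zs.mean()),
    }


def dstat_bias_experiment(
    seed: int, n_reps: int = 25, n_sites: int = 2000, bias: float = 0.2, block: int = 100
) -> dict:
    """Reference-biased P1 with an all-reference P3: E[D] < 0 expected."""
    ref = make_reference({"chr1": max(1000, n_sites) * 40}, 0.41, seed=seed)
    panel = make_variant_panel(ref, n_snps=n_sites, min_spacing=35, seed=seed, edge_margin=60)
    ds = []
    for rep in range(n_reps):
        q = make_population_quartet(
            panel, (0.02, 0.02, 0.1, 0.0), bias_toward_ref=bias,
            seed=int(rng_stream(seed, "dstat-bias", str(rep)).integers(2**31)),
        )
        res = dstat_abba_baba(with_reference_p3(q), block)
        ds.append(res.D)
    ds = np.asarray(ds)
    return {"n_reps": n_reps, "mean_D": float(ds.mean()), "frac_negative": float(np.mean(ds < 0))}


# ---------------------------------------------------------------- recovery
def damage_profile_recovery(
    seed: int, rate: float = 0.2, n_snps: int = 200, chrom_len: int = 40_000
) -> dict:
    """Simulate, align permissively, and re-measure the damage profile.

    A permissive difference budget keeps heavily damaged reads mapped, so
    the observed terminal C->T / G->A rates estimate the simulated profile
    without survivor bias; global-in-read alignment (no softclips) keeps
    damaged terminal bases in the counts.
    """
    ref = make_reference({"chr1": chrom_len}, 0.41, seed=seed)
    panel = make_variant_panel(ref, n_snps=n_snps, min_spacing=100, seed=seed)
    base = enumerate_site_reads(ref, panel, 50)
    model = DamageModel.exponential()
    reads = apply_deamination(base, model, rate, seed=seed)
    la = LinearAligner(ref, LinearAlignerParams(n_frac=1e-6))
    tab = la.align_batch(reads)
    prof = damage_profile(tab, reads, ref, max_pos=15)
    d5, d3 = model.profile_for_length(50, rate)
    prof["expected_5p"] = d5[:15]
    prof["expected_3p"] = d3[:15]
    return {"profile": prof, "mapped_frac": float(tab.mapped.mean())}


def caller_recovery_experiment(
    seed: int,
    coverage: float = 30.0,
    n_snps: int = 400,
    chrom_len: int = 100_000,
    qual_min: float = 30.0,
) -> dict:
    """Heterozygote recovery from unbiased (graph-aligned) pileups.

    Undamaged shotgun reads at high coverage; the fraction of truth
    heterozygous transversion SNPs called het at the quality threshold
    measures caller parameter recovery in the absence of mapping bias.
    """
    ref = make_reference({"chr1": chrom_len}, 0.41, seed=seed)
    panel = make_variant_panel(ref, n_snps=n_snps, n_indels=0, min_spacing=150, seed=seed)
    sample = make_diploid_sample(ref, panel, het_rate=0.5, hom_alt_rate=0.25, seed=seed)
    reads = sample_shotgun_reads(sample, coverage=coverage, seed=seed)
    graph = build_graph(ref, panel)
    tab = GraphAligner(graph).align_batch(reads)
    pile = pileup_sites(tab, reads, panel, min_mapq=50, ref=ref)
    calls = call_diploid_genotypes(pile)
    truth_het = {
        r.key for r in panel
        if sample.genotypes[r.key] == "het" and not r.is_transition()
    }
    called_het = {
        c.site.key for c in calls if c.genotype == "het" and c.qual >= qual_min
    }
    return {
        "n_truth_het_tv": len(truth_het),
        "recovered_frac": len(truth_het & called_het) / len(truth_het),
        "coverage": coverage,
    }


def het_recovery_curve(
    seed: int,
    coverage_full: float = 20.0,
    fractions: tuple = (0.2, 0.5, 1.0),
    n_snps: int = 300,
    chrom_len: int = 80_000,
) -> pd.DataFrame:
    """Downsampling heterozygote recovery against full-coverage calls."""
    ref = make_reference({"chr1": chrom_len}, 0.41, seed=seed)
    panel = make_variant_panel(ref, n_snps=n_snps, n_indels=0, min_spacing=150, seed=seed)
    sample = make_diploid_sample(ref, panel, het_rate=0.5, hom_alt_rate=0.25, seed=seed)
    reads = sample_shotgun_reads(sample, coverage=coverage_full, seed=seed)
    graph = build_graph(ref, panel)
    tab = GraphAligner(graph).align_batch(reads)
    full_calls = call_diploid_genotypes(pileup_sites(tab, reads, panel, min_mapq=50, ref=ref))
    rows = []
    for frac in fractions:
        mask = downsample_alignments(tab, frac, seed=seed)
        idx = np.flatnonzero(mask)
        sub = _subset(tab, idx)
        calls = call_diploid_genotypes(
            pileup_sites(sub, [reads[i] for i in idx], panel, min_mapq=50, ref=ref)
        )
        rows.append(
            {
                "fraction": frac,
                "coverage": coverage_full * frac,
                "het_recovery": het_recovery(full_calls, calls, "snp"),
            }
        )
    return pd.DataFrame(rows)


def contaminant_experiment(
    seed: int,
    read_lens: tuple = (35, 50, 70, 100),
    n_per_len: int = 2000,
    chrom_len: int = 120_000,
) -> dict:
    """False-mapping rates of unrelated (microbial-like) reads."""
    ref = make_reference({"chr1": chrom_len}, 0.41, seed=seed)
    panel = make_variant_panel(ref, n_snps=300, min_spacing=150, seed=seed)
    graph = build_graph(ref, panel)
    cont = make_contaminant_genome(200_000, 0.45, seed=seed)
    rng = rng_stream(seed, "contaminant-reads")
    seq = cont["contig1"]
    reads = []
    for L in read_lens:
        for i in range(n_per_len):
            s = int(rng.integers(0, len(seq) - L))
            from .damage import SimulatedRead

            reads.append(
                SimulatedRead(f"c{L}:{i}", seq[s : s + L], source="contaminant",
                              chrom="contig1", ref_start=s, ref_end=s + L)
            )
    return {
        "linear": contaminant_mapping_rate(reads, LinearAligner(ref), 30),
        "graph": contaminant_mapping_rate(reads, GraphAligner(graph), 50),
    }


# ---------------------------------------------------------------- bundle
def run_experiment(cfg: RunConfig) -> dict:
    """Run every analysis stage and write TSV reports under cfg.outdir."""
    os.makedirs(cfg.outdir, exist_ok=True)
    logger.info("run_experiment config: %s", dataclasses.asdict(cfg))
    out: dict = {}

    stage = "allele_balance"
    try:
        bal = allele_balance_experiment(cfg)
        bal["table"].to_csv(os.path.join(cfg.outdir, "allele_balance.tsv"), sep="\t", index=False)
        out["allele_balance"] = bal

        stage = "indel_detection"
        ind = indel_detection_experiment(cfg.seed)
        for name, df in ind.items():
            df.to_csv(os.path.join(cfg.outdir, f"indel_support_{name}.tsv"), sep="\t", index=False)
        out["indel_detection"] = ind
        out["long_deletion"] = long_deletion_experiment(cfg.seed)

        stage = "dstat"
        out["dstat_null"] = dstat_null_experiment(cfg.seed, n_reps=50)
        out["dstat_bias"] = dstat_bias_experiment(cfg.seed)

        stage = "recovery"
        rec = damage_profile_recovery(cfg.seed)
        rec["profile"].to_csv(os.path.join(cfg.outdir, "damage_profile.tsv"), sep="\t", index=False)
        out["damage_profile"] = rec
        out["caller_recovery"] = caller_recovery_experiment(cfg.seed)
        het = het_recovery_curve(cfg.seed)
        het.to_csv(os.path.join(cfg.outdir, "het_recovery.tsv"), sep="\t", index=False)
        out["het_recovery"] = het

        stage = "contaminant"
        cont = contaminant_experiment(cfg.seed)
        for name, df in cont.items():
            df.to_csv(os.path.join(cfg.outdir, f"contaminant_{name}.tsv"), sep="\t", index=False)
        out["contaminant"] = cont
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "pooled_alt_fractions": out["allele_balance"]["pooled"],
        "slopes": out["allele_balance"]["slopes"],
        "long_deletion": out["long_deletion"],
        "dstat_null": out["dstat_null"],
        "dstat_bias": out["dstat_bias"],
        "caller_recovery": out["caller_recovery"],
    }
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return out
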