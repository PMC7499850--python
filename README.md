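# refbias

Reference bias in ancient-DNA read mapping, measured end to end on
synthetic data with exact ground truth.

Ancient-DNA reads are short and carry post-mortem deamination (C→T at the
5' end, G→A at the 3' end). When such reads are aligned to a single linear
reference genome, reads carrying a non-reference allele start one mismatch
behind and are preferentially lost by edit-distance-limited mappers, so at
a heterozygous site the mapped alternate-allele fraction falls below the
expected 0.5 — and indel alleles beyond the gap budget vanish entirely.
`refbias` builds the whole measurement apparatus at desk scale:

* **synthetic inputs** — random reference, biallelic SNP/indel panel with
  allele frequencies, a diploid individual with phased haplotypes and
  exact coordinate liftover, a contaminant genome, four-population
  pseudo-haploid call sets (`refbias.synth`);
* **damage-aware read simulation** — every placement of a fixed-length
  read over every panel site, half carrying the alternate allele, plus
  coverage-based shotgun reads; parametric or file-based deamination
  profiles (`refbias.damage`);
* **two aligners with testable contracts** — a `bwa aln`-style linear
  aligner (Poisson difference budget: mismatches + gap opens ≤ k with
  P(Poisson(0.02·L) > k) < n; single gap ≤ 7 bp; no softclips; mapq ≤ 37)
  and a `vg map`-style graph aligner over a variation graph built from the
  panel (local affine-gap alignment with softclips, surjection to
  reference coordinates, mapq ≤ 60), plus brute-force oracles
  (`refbias.vargraph`, `refbias.aligners`);
* **two published debiasing workflows** — allele-flipped read duplication
  with same-position filtering, and alternate-reference merging
  (`refbias.debias`);
* **statistics** — allele balance with Wald 95% CIs, per-allele
  sensitivity and its OLS response to damage, placement-error rates,
  terminal damage profiles, pileup genotyping and heterozygote recovery,
  indel support by allele length, and the ABBA-BABA D-statistic
  D = (ABBA − BABA)/(ABBA + BABA) with a block jackknife
  (`refbias.evaluate`, `refbias.genotype`, `refbias.popgen`).

## Worked example

```python
from refbias import (
    GraphAligner, LinearAligner, DamageModel,
    make_reference, make_variant_panel, build_graph,
    enumerate_site_reads, apply_deamination, bias_report,
)

ref = make_reference({"chr1": 30_000}, gc_fraction=0.41, seed=11)
panel = make_variant_panel(ref, n_snps=40, n_indels=10, min_spacing=150, seed=5)
graph = build_graph(ref, panel)

reads = enumerate_site_reads(ref, panel, read_len=50)
reads = apply_deamination(reads, DamageModel.exponential(), rate_scale=0.3, seed=2)

g = bias_report(GraphAligner(graph).align_batch(reads), reads, mapq_min=50)
l = bias_report(LinearAligner(ref).align_batch(reads), reads, mapq_min=30)
print(f"graph : alt fraction {g.alt_fraction:.4f}  sens(alt) {g.sensitivity_alt:.4f}")
print(f"linear: alt fraction {l.alt_fraction:.4f}  sens(alt) {l.sensitivity_alt:.4f}")
```

prints

```
graph : alt fraction 0.5061  sens(alt) 1.0000
linear: alt fraction 0.4857  sens(alt) 0.9212
```

— at 30% terminal deamination the graph aligner retains every
alternate-allele read, so the mapped alternate fraction equals the
simulated input ratio (0.5061 here; with indels in the panel the
enumeration itself is not exactly 1:1). The linear aligner has already
lost 8% of the alternate reads: damaged alt reads exceed its difference
budget first, and the indel alleles longer than its 7-bp gap budget
contribute nothing at all.

A command-line interface mirrors the library:

```sh
refbias simulate ref --length 100000 --seed 1 --out ref.fa
refbias simulate panel --ref ref.fa --n-snps 500 --seed 1 --out panel.vcf
refbias simulate reads --ref ref.fa --panel panel.vcf --damage-rate 0.2 \
    --seed 1 --out reads.fq --truth-out truth.tsv
refbias build-graph --ref ref.fa --panel panel.vcf --out graph.gfa
refbias map-graph --gfa graph.gfa --reads reads.fq --min-mapq 50 --out out.sam
refbias evaluate --sam out.sam --truth truth.tsv --min-mapq 50
refbias run-experiment --seed 1 --outdir refbias_out
```

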