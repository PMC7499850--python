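# Methods

`refbias` quantifies reference bias in ancient-DNA read mapping on fully
synthetic data with exact ground truth. This note describes the models and
procedures, the defaults and why they were chosen, what the synthetic data
does and does not emulate, and the numerical decisions a maintainer would
want written down.

## The problem being measured

When damaged short reads are aligned to a single linear reference, reads
carrying a non-reference allele start one mismatch behind, so
mismatch-penalised alignment preferentially discards them. At heterozygous
sites this skews the allele balance below 0.5, propagates into genotype
calls, pseudo-haploid sampling and D-statistics, and suppresses indel
alleles entirely once they exceed the aligner's gap budget. Aligning to a
variation graph that contains the alternate alleles removes the asymmetry
at panel sites. The package builds both aligners at desk scale, generates
reads whose origin and allele are known exactly, and reports how each
alignment/debiasing strategy distorts (or preserves) the truth.

## Synthetic data

* **Reference genome** — i.i.d. bases at a chosen GC fraction (default
  0.41, human-like). No repeat structure, so placement is nearly always
  unique; consequences below.
* **Variant panel** — biallelic SNPs and left-anchored indels (uniform
  lengths 1..18 bp), placed with a minimum anchor spacing (default 100 bp)
  and an edge margin so fixed-length reads spanning any site fit the
  chromosome. Spacing at least read length + maximum indel length means no
  read spans two variants, which keeps truth bookkeeping and the graph
  aligner's bubble decomposition exact. Allele frequencies are drawn from
  Beta(0.8, 2) rescaled to [floor, 0.5] (rare-skewed, floor 0.001); the
  pipeline carries but never uses them for alignment.
* **Diploid individual** — per-site genotypes i.i.d. with configurable
  het/hom-alt rates; haplotype A carries the reference allele at
  heterozygous sites (fixed phase so liftover tables are exact; allele
  balance is phase-invariant). Liftover is piecewise linear with slope-0
  segments inside insertion alleles.
* **Contaminant genome** — i.i.d. sequence from an independent RNG stream.
  It shares only chance substrings with the reference, so false-mapping
  rates are near zero rather than the sub-percent values seen with real
  microbial genomes that share homology with the human reference; only the
  monotonicity properties (rate falls with mapq threshold and read length)
  are meaningful here.
* **Population quartet** — Balding–Nichols drift from a shared root
  frequency (ancestral allele ref or alt with probability ½, root derived
  frequency uniform on [0.05, 0.95]), one pseudo-haploid allele per
  population per site, outgroup fixed ancestral. `bias_toward_ref` flips
  P1's alternate alleles to reference with the given probability, the
  caricature of a reference-biased caller.

## Read simulation and damage

The core experiment enumerates **every** placement of a fixed-length read
(default 50 bp) over each panel site, once per allele — deterministic,
forward strand, perfectly balanced by construction. Shotgun simulation
draws fragments uniformly from both haplotypes with truncated-normal
lengths (mean 60 sd 12, min 35 — typical ancient-DNA fragment sizes) and
uniform strands.

Post-mortem deamination is applied as independent Bernoulli events:
C→T with probability `d5[i]` at distance i from the 5' end and G→A with
`d3[j]` from the 3' end (double-strand library model; a single-strand mode
applies C→T at both ends). The default profile is exponential,
`d5[i] = bg + (1-bg)·λ^i` scaled by the requested rate, with λ = 0.75 and
background 0.01 — terminal rates of 10–30% decaying to background within
~10–15 positions, the shape mapDamage reports for untreated libraries. A
file reader accepts two-column position/rate tables for users with real
profiles. Damage is the only error process; sequencing error and base
qualities are not simulated (qualities are constant Q30 so caller filters
are still exercised). With this profile the aggregate bias of the strict
linear aligner (~0.499 pooled alternate fraction) is smaller in magnitude
than with real empirical damage profiles; all orderings and directions are
preserved, and the balanced (~0.5) endpoints reported by the headline
experiments are insensitive to damage strength.

## The linear aligner

A bwa-aln-style global-in-read aligner with two deliberately separate
objectives, because the emulated tool also separates them:

* **Difference budget** (mappability): mismatches + gap opens must not
  exceed the smallest k with Poisson(0.02·L) upper tail below `n_frac`
  (so `n_frac` 0.02 → k = 3 at 50 bp, 0.01 → k = 4). Gap length is capped
  at `1 + max_gap_extensions` (default 7) and extension bases do not
  consume the budget — which is exactly why indel alleles above 7 bp are
  invisible to this aligner while 7 bp ones are not.
* **Penalty score** (placement choice and mapq): mismatch 3, gap open 11,
  gap extend 4. Under a single unit-cost objective a one-difference gap
  could "explain away" a cluster of terminal deamination mismatches and
  relocate the read, visibly corrupting damage profiles; the weighted
  penalty makes gaps expensive relative to mismatches, as in the real
  tool, and the artifact disappears.

Candidates come from exact anchor k-mers at evenly spaced offsets:
`k_max + 2` disjoint anchors when the read affords length-10 anchors
(pigeonhole-exact recall even with one gap), else `k_max + 1`. Each
candidate diagonal is scored exactly over the class of alignments with at
most one gap; alignments with two or more gaps are never produced even
when `max_gap_opens = 2` permits them in the budget (simulated reads carry
at most one indel; the brute-force test oracle enumerates the same class).
Ties are broken by penalty, then ungapped before gapped, then lowest
position, then forward strand. Mapping quality is the phred of the
posterior over candidate placements within budget,
`w ∝ exp(-penalty/3)`, capped at 37; a unique candidate gets the cap.

## The graph aligner

Local alignment with affine gaps (match 1, mismatch 4, gap open 6, extend
1 — standard graph-mapper scoring), softclips at both ends, mapq capped at
60. Two execution paths agree on results:

* **Full DAG dynamic programming** for small graphs (≤20 kb of labels) and
  for the exact refinement of batch candidates: Gotoh over graph bases in
  topological order, with traceback to a node path that is then surjected
  onto the reference path (alt-SNP bases become mismatches, insertion
  nodes become I, bypass edges become D, unaligned ends S).
* **Batch path** for pipeline scale: because panel variants are spaced
  beyond the read length, every ≤read-length walk through the graph is
  spelled either by the reference or by one per-variant allele context
  (left flank + alt allele + right flank). Seeds are exact 15-mers at
  multiple read offsets plus 10-bp rescue anchors (so damaged reads that
  break every 15-mer still seed); ungapped extension with optimal
  softclipping is computed in closed form per diagonal, and candidates
  whose score leaves room for a gapped alignment to win are re-aligned
  with the exact DAG DP on a windowed subgraph.

Two guards that the mapq ≥ 50 filter depends on: a read is mapped only if
its best local score reaches 65% of the maximum (`min_score_frac`), which
removes spurious single-seed hits without distorting mapq for genuinely
placed reads; and secondary candidates whose aligned reference span
overlaps the primary's are suppressed from the mapq posterior — they are
clipped fragments of the same physical placement, not alternative origins.

## Debiasing workflows

* **Modified reads**: every aligned read overlapping panel SNPs is
  duplicated with all overlapped alleles flipped, the copy realigned with
  identical parameters, and the original kept only when the copy maps to
  exactly the same (chrom, pos, strand). Reads whose site base matches
  neither allele (damage artifacts) are dropped as unmodifiable. On the
  symmetric exhaustive simulation the retained set is exactly
  allele-balanced; the price is sensitivity, since either copy exceeding
  the budget removes the read.
* **Alternate-reference merging**: reads are aligned to the reference and
  to a copy with every panel SNP substituted by its alternate; per read,
  one copy is kept at random (seeded) when coordinates agree, the single
  mapped copy otherwise, and nothing when both map discordantly (the
  published rule is silent on that case; discordants are counted in the
  run statistics). The kept read's mapq is the minimum of the two copies'.
  Note that a read mapped by plain alignment can be lost here as
  discordant, so the retained set is not a superset of the plain set in
  pathological cases.

## Evaluation, genotyping, population statistics

Placement is correct when the clip-adjusted origin (reported position
minus leading softclip) equals the truth start with matching chromosome
and strand and at least half the read aligned in M state. Allele-balance
CIs are Wald binomial over pooled reads (per-damage-level rows are also
emitted so either aggregation can be inspected); error rates are
incorrect placements per million mapped reads of each allele class;
damage-response regressions are ordinary least squares of mapped
percentage on deamination rate.

The genotype caller is intentionally plain: per-site likelihoods with
symmetric error (P(alt|het)=½, P(alt|hom)=err or 1−err, err = 0.01), flat
prior, qual = phred of one minus the winning posterior, optional masking
of C↔T/G↔A sites. The flat prior keeps the caller's own bias surface
neutral so mapping is the only bias under test; a consequence worth
knowing is that at qual ≥ 30 a heterozygote needs roughly 25× depth
before ≥99% are recovered (at depth d the call flips or falls below
qual 30 when the minor allele count is ≲0.15·d; two-sided binomial tails
give ~3.5% loss at 15×, ~0.4% at 25×). The recovery experiment therefore
runs at 30×. Indel alleles contribute to pileups only when the complete
allele is spelled with an anchoring base on each side; gap placements
shifted through repeat runs are recognised as equivalent to the canonical
left-anchored allele by sequence reconstruction.

D-statistics use complete-case ABBA/BABA counts with a delete-one block
jackknife over blocks of 100 consecutive sites (synthetic panels have no
linkage structure, so physical distance would be arbitrary).

## Scale of the standard experiments

The headline run uses one 220 kb chromosome, 2,000 SNP sites, all 50-bp
placements (200,000 reads per damage level) and damage rates
{0, 0.1, 0.2, 0.3}; indel detectability uses 4 sites per length 1..18 plus
a separate 32-bp deletion fixture; D-statistic experiments use 2,000-site
quartets over 100 replicates. These sizes put binomial noise on the
reported fractions near 10⁻³ while keeping a full run in minutes on one
CPU.

## Known limitations

* The reference has no repeats, so mapping-quality ambiguity and
  mappability-driven error stratification are essentially absent; error
  rates per million are much lower than on a real genome.
* Contaminant reads share no homology with the reference, so absolute
  false-mapping rates are near zero (direction/monotonicity only).
* bwa aln and vg are emulated behaviourally, not bit-for-bit: percentages
  depend on the synthetic conditions, and only orderings, directions and
  the symmetric ~0.5 endpoints are comparable across implementations.
* Multi-allelic sites, overlapping variants, structural variants beyond
  the indel cap, paired ends, base-quality-aware scoring and UDG chemistry
  are out of scope.
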