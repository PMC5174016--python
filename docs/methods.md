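# Methods

## Overview

`salivalink` analyses whole-ecosystem shotgun sequencing of saliva —
total DNA, so every read pair is either host-derived or
microbiota-derived — through four linked analyses:

1. **Read partition.** After alignment of pairs against the host
   genome, a pair is labelled *host-originating* when both mates'
   mapping qualities strictly exceed a threshold (default 100); all
   other pairs are *microbiota-originating*. "Exceeding" is read as a
   strict inequality: a mate at exactly the threshold fails the rule.
   Pairs with an unmapped mate carry MAPQ 0 for that mate and therefore
   fail the rule; this is a declared choice — a pair for which only one
   mate shows host evidence does not satisfy a both-mates rule.
2. **Functional profiles.** Microbial genes annotated against a
   4-level subsystem hierarchy (hierarchy 1–3 plus "function") are
   aggregated into per-sample count and relative-abundance tables at
   any level. On top of the profiles: the functional **core**
   (functions present in every sample) and **pan** (union) sets,
   pairwise enrichment/depletion signatures, pathway-level
   unique-protein comparisons, PCA ordination and hierarchical
   clustering.
3. **Genome–function linkage.** Each gene also carries its originating
   genome, yielding a genome × function count matrix per level plus
   per-genome mapped-read abundances. From this the dominance structure
   follows: top-k genomes by read abundance, top-k categories by gene
   hits, per-genome functional diversity, the contribution of dominant
   genomes to each category, the rank correlation between abundance and
   diversity, and per-category genome breadth (functional redundancy).
4. **Host variants.** Host-derived reads support SNP calling by two
   independent callers; the final call set is their allele-exact
   intersection, depth-filtered, then classified by genomic region and
   coding effect and summarised as per-chromosome density.

## Definitions and conventions

- **Relative abundance** at a level is a category's summed gene hit
  count divided by the sample's total known-function hit count.
  Unknown-function genes are excluded from relative abundances but
  tracked as an `unknown_fraction` (large unknown components are normal
  in metagenome annotation, and excluding them keeps profiles
  comparable across samples with different unknown rates).
- **Core/pan gene-sequence counts** are defined as the across-sample
  sum of hit counts of genes annotated to core (respectively any)
  functions. The pairing of a function-set size with a gene-sequence
  count has no unique formula; this definition is declared and tested.
- **Enrichment** of sample *a* over *b* for category *c* is
  `100 × (RAa(c) − RAb(c)) / RAb(c)` — a signed percent satisfying the
  antisymmetry `(1 + e_ab/100)(1 + e_ba/100) = 1`. Categories present
  in *a* but absent from *b* have no finite percent and are flagged
  exclusive-to-a instead of being given a sentinel number.
- **PCA** operates on relative-abundance vectors over the zero-filled
  union of categories, centred but not scaled (abundances are already
  on a common scale); coordinates are deterministic up to component
  sign. When all profiles are identical the decomposition is degenerate
  and coordinates are reported as zeros.
- **Clustering** is agglomerative (single/complete/average/ward) on
  Euclidean distances between relative-abundance vectors; the
  dendrogram is exported as Newick.
- **Dominance** is measured by mapped-read abundance for genomes and by
  gene-hit column sums for functions; top-k ties break
  lexicographically by identifier and k defaults to 5.
- **Functional diversity** of a genome at a level is the fraction of
  the microbiota's observed categories the genome encodes (presence,
  not Shannon). The diversity–abundance trend is a Spearman rank
  correlation with average ranks for ties; when either margin is
  constant the correlation is defined as 0 (the 0/0 case).
- **Consensus variants** require identical (chrom, pos, ref, alt) in
  both callsets; the consensus depth is the minimum of the two callers'
  depths (conservative, since which caller's depth the filter should
  use is otherwise arbitrary). The depth filter is inclusive: a minimal
  depth of 30 retains depth-30 calls. Only SNVs are considered.
- **Region classes** are exonic (inside CDS), splicing (within 2
  intronic bases of an exon boundary), UTR (exon outside CDS), intronic,
  intergenic — assigned with that precedence when transcripts overlap,
  so the classes are exhaustive and mutually exclusive.
- **Coding effects** translate the reference and alternate codon under
  the standard genetic code (minus-strand transcripts use
  reverse-complemented alleles): synonymous, nonsynonymous, stopgain,
  stoploss.
- **Coordinates**: VCF and GFF3 are 1-based inclusive (also the
  in-memory convention); BED12 is 0-based half-open. All conversions
  live in the I/O layer.
- **Density uniformity** is a chi-square statistic of per-chromosome
  SNP counts against a length-proportional expectation, with
  df = #chromosomes − 1 (undefined at df 0).

## The synthetic-data generator

Every analysis input can be simulated with known truth; the generators
are deterministic under their seeds, and each emitted record is
traceable to exactly one truth label.

- **Function catalog**: random 4-level tree with given level sizes;
  each node attaches to a uniform random parent, so every function has
  exactly one path to a top-level category.
- **Community**: genome abundances from a lognormal (default
  σ = 1.2), Dirichlet, or manual law, normalised to sum to 1; genomes
  are labelled in decreasing abundance. Each genome's functional
  repertoire is a without-replacement draw of distinct functions whose
  size is a monotone function of abundance rank (default
  `0.5 · n_functions · rank^(−0.7)`) plus optional Gaussian noise; each
  repertoire member becomes a gene record with a `1 + Poisson` hit
  count. A configurable fraction of genes carries no functional
  assignment, emulating the unknown-function component of real
  annotation. The lognormal default is a modelling choice — no
  distributional form for real saliva genome abundances is claimed.
- **Read pairs**: origins are multinomial over (host, genomes) with
  probabilities (host_fraction, (1 − host_fraction) × abundances); the
  host fraction defaults to 0.7 for healthy-host (H) samples and 0.45
  for caries-active (C) samples, i.e. microbial fractions of ~30% and
  ~55%. MAPQ emission is a two-point mixture: a host pair emits the
  high MAPQ (150) on both mates with probability 1 − crossmap_rate and
  two uniform values in [0, 100] otherwise; microbial pairs do the
  reverse. Under this model the strict ">100 on both mates" rule errs
  exactly when the crossmap coin fires, so its expected error rate
  equals crossmap_rate analytically — which is what the recovery tests
  check. Multinomial (rather than exact-proportion) sampling is
  deliberate: recovery tests must tolerate sampling variability.
- **Gene model**: rejection-placed non-overlapping transcripts with 1–4
  exons (introns ≥ 60 bp), a CDS whose length is a multiple of 3, and
  random strand; reference chromosomes are uniform random nucleotide
  sequences.
- **Variant call sets**: a truth set of SNVs at distinct positions with
  Poisson depths, plus two caller outputs; each caller independently
  misses truth variants at its false-negative rate and reports false
  positives over a universe of candidate error sites at its
  false-positive rate. Each candidate site carries a
  position-determined alternate allele — a systematic miscall shared by
  both callers — so the expected number of false positives surviving
  the intersection is exactly `fp_a × fp_b × n_candidates`. Had each
  caller drawn its FP allele independently, agreement would carry an
  extra 1/3 factor; the systematic-error model is both the simpler
  analytical target and the more realistic failure mode (shared
  alignment artefacts).
- **Group shifts**: `resample_catalog` creates per-sample noisy copies
  of a community catalog and can multiply expected counts of selected
  categories. Because multiplying counts by r does not multiply
  relative abundances by r (the total grows too),
  `fold_for_relative_abundance_shift` computes the exact count fold
  `F = r(T − S)/(T − rS)` that realises a target relative-abundance
  ratio r after renormalisation.

### What the simulation does and does not capture

The generators emulate the *statistical* structure the analysis relies
on — skewed abundances, abundance-linked repertoires, a tunable
host-DNA fraction, MAPQ separation with crossmapping, and noisy
paired callers — not sequences. There is no nucleotide-level read
simulation, no assembly, no annotation error model beyond the
unknown-function fraction, and no linkage between a genome's taxonomy
and its repertoire content. Passing recovery tests therefore
demonstrates that the analysis correctly inverts its own generative
assumptions at realistic sizes; it does not validate aligner behaviour,
annotation quality, or caller error structure on real data.

## Problem sizes and defaults

The bundled demo study uses 4 samples (2 H + 2 C), a 20-genome
community over an (8, 20, 60, 240) hierarchy with 30% unknown-function
genes, 20,000 read pairs per sample with a 2% crossmap rate, a 40-gene
model over three chromosomes (1.25 Mb total), and per sample 1,200
truth SNVs (Poisson(45) depth) with caller rates fp = 0.03, fn = 0.05
over 30,000 candidate error sites. These sizes keep a full run in
seconds while leaving every statistic comfortably away from its
small-sample regime. The recovery experiments in the acceptance suite
use 50,000 read pairs, 10^6 candidate error sites, and 1,000 random
exonic SNVs.

## Numerical and degenerate-input choices

- Relative abundances are checked to sum to 1 within 1e-9; abundance
  vectors within 1e-12.
- Empty inputs are flagged, not silently zero: empty partition input
  yields undefined fractions, an empty record list an undefined
  unknown_fraction, an empty call list an undefined region
  distribution, a single chromosome an undefined uniformity statistic.
- Reference-allele disagreements between callers at the same position
  are excluded from the consensus with a warning and a reported count.
- Zero-total categories are omitted (with a note) from contribution
  fractions.

## Known limitations

- The per-category contribution summary is reported at whichever level
  is requested; the min–max ranges across categories are
  level-dependent.
- `genes_with_snps` counts transcripts, not collapsed gene loci; with
  the non-overlapping synthetic models the two coincide.
- The splicing window is fixed at 2 bp, the conventional donor/acceptor
  dinucleotide; real splice-region definitions vary by annotator.
- The pipeline consumes alignment tables and caller outputs; it does
  not run aligners, assemblers, annotators, or variant callers.
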