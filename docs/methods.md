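# Methods

This note records the models, conventions, and numerical choices behind
`spongefunc`, and what the synthetic benchmarks do and do not demonstrate.

## Compositional arm

**Rarefaction** is a single multivariate-hypergeometric draw (subsampling
without replacement) to the target depth, with the generator state recorded;
no averaging over replicate draws.  Samples under the depth are dropped with a
warning.  A single draw matches common amplicon practice and keeps outputs
bit-reproducible under a fixed seed.

**Log2 transform before Bray–Curtis.**  Relative abundances are scaled to
counts-per-million and shifted by one: `log2(ra * 1e6 + 1)`.  A pseudocount on
raw proportions would be dominated by the pseudocount itself; scaling first
keeps the transform monotone and zero-preserving.  The scale constant is an
argument of `log2_transform`.

**Shannon diversity** uses natural logarithm (nats), the vegan default.

**PCoA** double-centers −d²/2 (Gower) and eigendecomposes.  Axes with negative
eigenvalues are reported in `eigenvalues` but excluded from coordinates; no
Lingoes/Cailliez correction is applied.  Proportion explained is relative to
the positive eigenvalue mass.

**PERMANOVA** uses the pseudo-F
`F = (SS_between/(a−1)) / (SS_within/(N−a))` with
`SS_total = Σ_{i<j} d²_ij / N` and within-group sums divided by group size.
Two p-value modes:

* *exact* — every distinct assignment of the group-label multiset is
  enumerated; p is the fraction (including the observed assignment) with
  F ≥ F_observed.
* *sampled* — `n` random relabelings with the +1 correction, so
  p ≥ 1/(n+1) and p can never be zero.

A caution that shaped the test designs: permutation p-values are *discrete*.
Two groups of three admit only 10 distinct partitions, so the smallest
achievable p is 0.1 and a 3-vs-3 design can never reject at α = 0.05.
Calibration checks therefore use designs where α = 0.05 is reachable
(5 vs 5 sampled, or three groups of three), while exhaustive-enumeration
correctness is still checked at 3 vs 3 against a brute-force oracle.

**Dispersion homogeneity** embeds samples by PCoA (positive axes only — the
imaginary-axis bookkeeping of vegan's betadisper is deliberately omitted),
computes each sample's distance to its group centroid, and applies one-way
ANOVA.  Groups of one sample are excluded with a warning.  **Group
variability** is the mean off-diagonal within-group dissimilarity; the
deep/shallow contrast pools within-group distances per habitat class and
compares them by ANOVA.

## Functional arm

**Apportionment.**  `count(p,s) = count(t,s) · len(p) / Σ_{p'∈t} len(p')`.
Peptide lengths are amino acids everywhere; because TPM normalizes per sample,
the ×3 nucleotide factor cancels.  Transcripts with no annotation record, and
records with no matching transcript, are dropped with logged tallies.

**TPM.**  `rate = count/length`, scaled to 10⁶ per sample.  The denominator
includes *all* apportioned peptides (annotated or not); KO totals plus the
reported unannotated mass reconstruct 10⁶ exactly, which is the invariant the
tests assert.

**KO aggregation** sums member-peptide TPM; aTPM is the unweighted arithmetic
mean across samples.

**TMM** follows the edgeR algorithm: upper-quartile-closest-to-mean reference,
M/A computed on count fractions over features expressed in both samples,
double trim (30% on M, 5% on A, rank-based with average ties), inverse
delta-method-variance weights, factors re-centered to geometric mean 1.  The
unit test cross-checks against edgeR's `calcNormFactors` via Rscript to 1e-6.

**Module grammar.**  Precedence, tightest first: `+`/`-`, then `,`, then the
step separator; parentheses group.  Completeness: a leaf is satisfied when its
KO is present; a complex requires all non-optional parts; an alternative any
option; the module is complete when every top-level non-optional step is
satisfiable, and `fraction_satisfied` is satisfied steps over counted steps.
"Present" defaults to TPM > 0 in at least one sample (threshold configurable).
This step-satisfaction rule is this package's documented stand-in for KEGG
Mapper's internal completeness rule, which is not published.

**Multiplicity.**  A KO contributes its full TPM to every module containing
it (once per module even if the definition repeats it), so module and
hierarchy sums may exceed total TPM — deliberate, and surfaced by
`ko_multiplicity`.

**Taxon split** decomposes KO TPM by the rank-level taxon of each contributing
peptide before rollup; splits are an exact partition of each module's total.
It therefore requires peptide-level expression, not the already-aggregated KO
matrix.

## Comparison

**Shared features** use strict thresholds (RA > 0.01% for ASVs; TMM-normalized
CPM-scale abundance > 1 for transcripts) in at least one sample of a group.
All inclusive intersections and the exclusive partition are computed; pairwise
summaries report the shared percentage of the pair's union and the share of
each group's abundance mass.

**Differential caller.**  Features are filtered (RA > 0.001% for ASVs,
CPM > 10 for transcripts, in ≥ 2 samples), TMM-normalized, and scored by the
difference of group means of `log2(CPM+1)` — which is also the reported log2
fold change.  The null pools the statistic across *all* features and all
distinct non-observed label partitions (sampled when more than the requested
permutation count).  Pooling is what gives the test resolution at small n:
with 3 vs 3 samples only 9 non-observed partitions exist, so a per-feature
permutation p is bounded below by 0.1 and the BH < 0.01 threshold would be
unattainable; pooled over F features the floor is ≈ 1/(9F+1).  The cost is
the usual pooled-null assumption of comparable per-feature null scales (here
reasonable after log2-CPM).  Passing requires BH-adjusted p < 0.01 *and*
|log2FC| ≥ 1 — the fold-change gate blocks significant-but-small effects.
This permutation test deliberately replaces a negative-binomial exact test:
the thresholds and filters are the analysis contract, and a permutation null
is exactly calibratable against synthetic truth.

## Synthetic generator

The generator emulates the data *structure* of a deep-sea HMA sponge study,
not any real dataset:

* **ASV arm** — a shared skewed base composition (Dirichlet(0.8) draw);
  per-sample compositions `Dirichlet(c · base)` with concentration
  `c = dirichlet_concentration` (default 150), divided by
  `habitat_dispersion_factor` for shallow samples (shallow communities are
  noisier); counts Multinomial at Poisson depth around `seq_depth_mean`
  (default 20 000, the common rarefaction depth).  Each species/location group
  multiplies a designated round-robin ASV block by `exp(group_effect_size)`.
  Dirichlet-multinomial is an assumption of convenience; real ASV tables are
  more zero-inflated and correlated than this.
* **Transcriptome arm** — transcripts carry one ORF with probability
  `single_orf_fraction` (default 0.366) else uniform 2..12; peptide lengths
  log-normal(μ=5.2, σ=0.6) truncated at 50 aa (plausible protein lengths);
  baseline expression log-normal(0, 1.2); per-sample log-normal noise
  (σ = 0.25) for biological replication; counts Multinomial at Poisson depth
  around `transcript_depth_mean` (default 10⁶, a scaled-down stand-in for
  20 M rarefied reads).  Planted differential transcripts are drawn from the
  above-median-baseline pool — an a-priori observability choice so the planted
  truth is not erased by the CPM > 10 filter — and assigned to species groups
  round-robin.  Required KOs of planted complete modules are attached to
  peptides of expressed transcripts; planted-absent KOs are never assigned, so
  modules requiring them are incomplete by construction.
* One seed expands into per-stage substreams; fixed seed ⇒ bit-identical
  outputs.

Because group effects, dispersions, and fold changes are planted directly on
the generating parameters, passing the recovery benchmarks shows the chain is
*correct and calibrated under its own model* — it does not certify performance
on real sequencing data, where compositionality, annotation error, and
unmodeled correlation all intrude.

## Problem sizes

The benchmarks run at desk scale, chosen once: 1000 transcripts for
conservation checks; 200 random module definitions (≤ 10 leaves, every KO
subset enumerated); 20 exhaustive-PERMANOVA instances plus 500 null
simulations; 50 differential-recovery simulations (400 transcripts, 3 vs 3,
depth 10⁶); 50 completeness datasets; 100 habitat-contrast simulations
(80 ASVs, 6 + 6 samples).  The full suite and the acceptance script each
complete in about a minute on a single CPU.

## Known limitations

* Pathway rollups use flat KO lists; only modules get the grammar.
* One-factor PERMANOVA only; no multi-factor (sequential/marginal SS) designs.
* Dispersion test ignores imaginary PCoA axes (see above).
* The module catalog format is this package's own flat TSV; a converter from
  KEGG flat files is future work.
* The generator does not emulate sequencing error, chimeras, or annotation
  noise; `truth.json` is exact.
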