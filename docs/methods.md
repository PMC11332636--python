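# Methods

## Data model and coordinates

All internal coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted on parse, BED output is 0-based half-open.  A CpG
locus is identified by the + strand cytosine of the dinucleotide: a − strand
call at position p+1 is summed into the locus at p (CpG methylation is
symmetric across strands), and an orphan − strand call is re-anchored to p.
Destranding conserves total read counts.  The methylation level at a locus
is β = methylated / total, defined only where total > 0; all aggregate
levels (global summaries, tile levels, region means, metaprofile bins) are
count-weighted (Σmeth/Σtotal), never means of per-CpG ratios — this is the
convention sequencing summaries use, and it keeps low-coverage CpGs from
dominating.

The TSS is gene-level: the strand-aware 5′ terminus of the gene record
(start on +, end−1 on −).  Transcript isoforms are out of scope.

## Genomic features

Each gene contributes five windows (defaults in parentheses): proximal
promoter P1 (1 kb immediately upstream of the TSS), distal promoter P6
(upstream of P1 out to 6 kb, i.e. a 5-kb window), gene start GS (first
1.5 kb of the gene, or the whole gene when shorter), gene body GB (the
remainder to the TTS; absent for short genes) and TTR (1 kb downstream of
the TTS).  Windows are clipped at contig bounds and are strand-aware.

`FeatureGeometry.p6_excludes_p1` (default true) makes P1 and P6 disjoint.
This matters for densities: per-class DMR density divides the assigned DMR
count by the *canonical* feature length — p1_span, gs_span, ttr_span, the
5-kb exclusive P6 window, and for GB the mean body length over genes longer
than gs_span.  With the inclusive alternative the P6 denominator would be
6 kb; both constructions are available.

Features of different genes may overlap and are never deduplicated: the
annotation bookkeeping (below) is defined per gene.

## Annotation bookkeeping

Candidate DMRs are intersected with feature intervals by an event sweep
(starts/ends sorted per contig, ends processed first so touching half-open
intervals never pair); a 1-bp overlap suffices.  Two parallel counts are
kept, because one DMR can span several features and several genes:

* **N_A** — the number of (DMR, gene, feature-class) interactions;
* **N_DMRs** — each DMR assigned to exactly one class by the hierarchy
  P1 > GS > P6 > GB > TTR > Intergenic, applied across genes (a DMR in gene
  A's GB and gene B's P1 is a P1 DMR: the hierarchy expresses feature-class
  precedence, not gene membership).

The assignment is a partition: ΣN_A ≥ ΣN_DMRs with equality iff no DMR has
multiple annotations.  Annotations on genes no longer than gs_span are
reported in a separate column, since those genes have no GB and their GS is
the entire gene.

## DMR caller

The caller tests a two-group contrast (reference = large size class) while
adjusting for a categorical covariate (feed pen) by stratification:

1. Per CpG, per stratum, d_s = mean β over reference samples − mean over the
   others; the combined d is the stratum-size-weighted mean of d_s.  Strata
   containing a single group are excluded with a warning.
2. d is smoothed to d̃ by a plain mean over CpGs within ±`smooth_bw` bp on
   the same contig (default 250 bp).  The bandwidth should be comparable to
   the scale of the regions sought: at a typical ~20 CpGs/kb, ±250 bp
   averages ~10 CpGs, matching the minimum region size of 5 CpGs; a window
   much wider than a region dilutes its boundary contrast and extends it
   over flanking CpGs with attenuated differences, costing power for short
   regions.
3. Candidate regions are maximal runs of adjacent CpGs with |d̃| ≥ cutoff
   (default 0.05), constant sign of d̃, and inter-CpG gaps ≤ max_gap
   (default 1 kb); runs of fewer than min_cpgs (default 5) CpGs are
   dropped.  Region bounds are [first CpG, last CpG + 2) to cover the
   dinucleotide.
4. Each region scores stat = n^(−1/2) Σ_i d_i/√(s_i² + ε), with d_i the raw
   (unsmoothed) combined difference, s_i² the pooled within-group variance
   of levels at CpG i, and ε = 0.01 stabilising near-constant sites.  The
   n^(−1/2) factor makes statistics comparable across region lengths, which
   the pooled null (next step) requires: a sum-type statistic grows with
   region length, so long weakly-differential regions arising under
   near-identity relabelings would dominate the null tail and mask short
   genuine regions.
5. p-values come from label permutation: group labels are shuffled within
   strata, the entire pipeline (differences, smoothing, region construction,
   statistics) is re-run, and all permuted region statistics pool into one
   null set.  For an observed region,
   p = (1 + #{null |stat| ≥ |stat_obs|}) / (1 + N_null).  When the distinct
   within-stratum relabelings number at most n_perm (default 1000) they are
   enumerated exhaustively, excluding only the identity labeling; with two
   groups the group-swap complement produces the identical |stat|, so the
   smallest attainable exhaustive p is 2/(1+N_null) — at very small n (3v3)
   this floors p at ~0.1, which is the honest resolution of the design.
6. Raw p < candidate_alpha (default 0.01) flags candidates.  No
   multiple-testing correction is applied — the caller feeds a pattern-level
   integration analysis, not per-region discovery claims, and the region
   filters (≥5 CpGs, complete coverage) already bound the false-positive
   contribution; measured type-I behaviour is ~0.4% of null regions at
   p < 0.01.

delta_beta is the mean of d over the region's CpGs (reference minus other);
direction is hyper iff delta_beta > 0.  Swapping the group labels negates
every statistic and delta_beta and leaves p unchanged; fixed seed and input
give byte-identical output.

## Global patterns

Tiles are non-overlapping windows (default 10 kb) retained when they hold
≥min_cpgs CpG loci (default 100) and their mean per-CpG coverage, averaged
over CpGs and samples, lies in [min_cov, max_cov] (default [1X, 30X]; the
bounds are interpreted as per-tile means — per-CpG variants would be
stricter and the choice is exposed in config).  PCA runs on centered,
unscaled per-sample tile levels via SVD; tiles with any undefined level are
dropped.  PERMANOVA uses Euclidean distances between sample tile profiles
(the metric is configurable), pseudo-F from the Gower-centered squared
distance matrix, and the permutation scheme above (exhaustive enumeration
over distinct relabelings when feasible, else Monte Carlo with the
(1+k)/(1+n) rule).

The TSS metaprofile pools every CpG within [−6 kb, +5 kb) of any gene's TSS
into 50-bp bins of strand-aware offset; a CpG near two TSSs contributes once
per gene.  On the − strand the destranded anchor at genomic position p is
the − strand cytosine at p+1, so its offset is tss − p − 1.  Bins are
count-weighted over pooled CpGs and all samples; genes are deliberately not
equally weighted.

## Expression

Genes are filtered by total count (≥10 across samples) and prevalence
(count ≥10 in ≥50% of samples); both switchable, since the prevalence rule
derives from a larger cohort and is approximated within-dataset.  Size
factors are median-of-ratios: per-gene geometric means over samples form the
pseudo-reference, restricted to genes positive in every sample; a
positive-count fallback exists for sparse matrices.  The DE test is an
ordinary linear model of log2(normalized + 1) on the group indicator plus
stratum dummies with a two-sided t-test on the group coefficient and BH
adjustment; positive LFC means higher in the non-reference group.  This is
deliberately not a negative-binomial shrinkage analysis: in this pipeline
DE is supporting infrastructure (the integration uses normalized counts,
not DE calls), and a fully specified linear model is oracle-testable.
Constant genes report p = 1.

## Integration

For every annotated (DMR, gene) pair where the gene has expression data, the
DMR's per-sample count-weighted mean methylation is Pearson-correlated with
the gene's normalized counts over the samples carrying both data types
(pairs with undefined values dropped; n ≥ 3 required; zero-variance pairs
skipped).  p is the two-sided t-test with n−2 df; significance at p < 0.05.
The pair's feature class is the highest-ranked among that gene's annotated
classes for the DMR; per-feature summaries count significant and negative
correlations per unique DMR under the cross-gene assignment, with
proportions at 1 decimal and densities at 3, matching conventional table
rounding.

## Synthetic data generator

The generator emulates the structure of a WGBS + RNA-seq study of a
hypermethylated vertebrate genome; its defaults are the study conditions
used throughout the tests:

* genome: 2 contigs × 400 kb, 60 non-overlapping genes (15% shorter than
  1.5 kb to exercise the GS-only path), CpGs as a uniform point process at
  0.02/bp with doubled density within ±500 bp of each TSS and ≥2 bp spacing;
* methylation: background β = 0.78, lowered to 0.2 within ±500 bp of each
  TSS; 20 planted DMRs (8–25 CpGs, alternating direction, ≥2 kb apart)
  shift the two groups by ±Δ/2 with Δ = 0.3; per-(CpG, sample) latent levels
  are Beta(βκ, (1−β)κ) with κ = 30 (biological variability), coverage is
  Poisson(5), methylated counts binomial — i.e. beta-binomial sequencing
  noise at 5X;
* samples: 10 large + 10 small split over two feed pens; 3 of 20 lack RNA
  (17 with both data types);
* expression: negative-binomial counts (dispersion 0.1, per-sample depth
  factors 0.7–1.4, baselines log-uniform over ~20–2000).  Genes whose
  features hold a planted DMR are coupled with class-dependent probability:
  log-mean += strength × sign × z(latent feature methylation), with
  repressive sign at P1/GS (promoter methylation silences) and mixed sign
  elsewhere.  Coupling acts through the latent (read-sampling-free)
  methylation, so the attenuation of observed correlations by sequencing
  noise is realistic and measurable.

What the generator does *not* emulate: genome-scale sparsity of genes (the
toy genome is gene-dense, so TSS dips depress the global mean methylation to
~70% even though the background is 78% — in a real genome the two nearly
coincide), read-level artefacts (M-bias, conversion errors), non-CpG
methylation, RNA degradation, isoform structure, and correlated
between-sample structure beyond the planted groups.  Passing tests therefore
demonstrate the correctness and power of the machinery under controlled
conditions, not performance on real genomes.

`true_link_r` exposes the noise-free correlation between any region's latent
methylation and a gene's expression driver, which defines the planted sign
for sign-recovery checks: a link's truth is per (region, gene) — a DMR in a
gene's GS can legitimately anticorrelate with expression driven positively
by that gene's P6.

## Numerical and degenerate-input choices

* Permutation p-values are never 0: the +1 rules above.
* PCA of a constant matrix returns zero scores and undefined (NaN) variance
  fractions.
* A zero-coverage sample's global methylation is NaN, never 0.
* Duplicate positions within one sample's call file are summed with a
  warning; duplicate gene IDs are an error.
* Exhaustive vs sampled permutation is decided by comparing the count of
  distinct relabelings (product of within-stratum binomial coefficients)
  with n_perm.
* Ties in the permutation null are counted as exceedances (≥ with a 1e-12
  guard), the conservative direction.
* All stochastic stages take explicit seeds; the pipeline propagates one
  seed and two runs with identical config and inputs are byte-identical.

## Problem sizes in the test suite

The shipped tests run the full generator at its defaults (≈16.5k CpG loci,
20 samples) for end-to-end checks, 5v5 subsets for the recovery and error
control studies (10 replicate null genomes of ≈4k loci for type-I), and
exhaustive-enumeration toys (n = 4–6) for the oracle equivalences.  These
sizes give the permutation machinery ≥10⁴ null draws per check while the
whole suite completes in well under a minute of compute for the statistical
core.
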