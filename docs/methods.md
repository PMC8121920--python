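# Methods

## Statistical model

Allele counts at a heterozygous SNV are modeled beta-binomially with
mean fixed at 0.5 under the null and a per-condition dispersion
`rho = 1/(alpha + beta + 1)`; `rho -> 0` recovers the binomial. The same
parameterization is used by the generator and the test, so dispersion
round-trips exactly. The dispersion is estimated by bounded
maximum-likelihood search on `rho in [0, 0.5]` (Brent, xatol 1e-7) over
sites with more than 100 reads — deep sites dominate the likelihood and
are least affected by discreteness — and the fitted value is applied to
all tested sites (>= 30 reads). `mu` is never fitted: freeing it would
absorb genuine imbalance into the null. Because the fit pools causal
and null sites, the estimated `rho` is slightly inflated, which makes
the test conservative; this is intentional and mirrors how such a null
must be fitted when truth is unknown.

Two-sided p-values are computed by tail doubling,
`p = min(1, 2 min(P(X<=k), P(X>=k)))`. Under the symmetric null the
smaller tail always lies toward `min(k, n-k)`, so only that lower tail
is accumulated, from the extreme end inward, from a log-space pmf
(log-gamma). Work is grouped by unique read depth so each pmf vector is
evaluated once per depth; the unit tests pin the result to a direct
pmf-summation oracle at 1e-10 for all n <= 200.

q-values follow Storey: `pi0(lambda)` on the grid 0.05..0.95 is
smoothed by a cubic polynomial fit and read off at the largest lambda,
clipped to [1/m, 1]. Collections smaller than 100 p-values fall back to
`pi0 = 1`, i.e. Benjamini–Hochberg, which the tests verify against the
statsmodels implementation. The multiple-testing universe is the whole
pooling analysis (all SNVs tested at that level jointly); a
`per_group_fdr` flag switches to within-condition universes.

### Calling thresholds (defaults)

| parameter | default | meaning |
|---|---|---|
| fdr | 0.10 | q-value cutoff |
| ratio | 0.70 | major-allele fraction, strict `>` |
| min_reads | 30 | minimum pooled depth to test a site |
| min_fit_depth | 101 | minimum depth for a site to inform the dispersion fit |
| RNA ratio / min_reads | 0.60 / 50 | transcript-level analogues |

All boundary inequalities are strict exactly as stated (base quality
>20; template length <500 bp; MAPQ >=20; pass-fraction >0.60; mappable
fraction >0.95; indel distance >72 bp; 3 bp excluded at the 5' end in
read orientation — for minus-strand reads the 5' end is the rightmost
aligned base, because the sequence-specific cleavage bias the exclusion
guards against acts at the cleavage end).

Counting conventions where the upstream description is silent:
a mate pair agreeing on the allele is counted once, with the higher
variant base quality governing the quality filter; mates disagreeing on
the allele discard the whole fragment (conservative reading of "counted
once"); among passing fragments sharing a 5' position the one with the
highest variant base quality survives, ties broken by a deterministic
(chrom, start, mate id) sort; a missing mappability entry fails closed.

## Synthetic cohorts

The generator emulates the study design rather than any particular
dataset: 4 cell types x 2 F1-hybrid strains by default (each SNV is
heterozygous in exactly one hybrid and therefore observed only in that
strain's conditions), ~70% of SNVs inside DHS hotspots (150–400 bp,
exponential gaps, mean 2 kb), read depths negative-binomial with mean
60 and shape 2 truncated to [10, 2000] — heavy-tailed like DNase data
and straddling both the 30-read test and 100-read fit thresholds — and
dispersion 0.03 per condition, a mid-range value for allelic DNase
counts. 5% of SNVs are causal with `|theta - 0.5| ~ Uniform(0.15,
0.45)` and random sign, spanning the >70% call threshold in both
directions; 60% of causal effects act in all cell types, the rest in
one. 60% of causal SNVs are planted at a core position (middle third)
of a TF motif instance; motif matches carry FIMO-like scores, p-values
(stringent for planted instances) and an allele log-odds difference
that tracks the planted effect. Footprints wrap half the matches.
Genomic annotations (activity spectrum from 45 synthetic catalogs,
TSS distance, DHS strength/width, footprint presence, conservation,
nearby sites) are drawn conditionally on causality so that
context-based scoring has signal to find. Transcript-level counts are
coupled to nearby DHS effects by a user-supplied distance kernel
(exponential, 10 kb scale in the examples) plus independent Gaussian
noise.

What the generator does **not** emulate: sequence-level genomes and
alignment, reference-mapping bias, DNase cut-bias profiles,
fragment-length structure, linkage between nearby SNVs beyond shared
DHS effects, and realistic motif inter-dependencies. Passing tests
therefore demonstrate the correctness and calibration of the
statistical machinery under the model's assumptions, not robustness to
real-data artifacts that the out-of-scope upstream steps (alignment,
peak calling) are responsible for removing.

Read-level fixtures are generated separately with one ground-truth
filter label per read, enabling an exhaustive confusion-matrix test of
the counting filters (all off-diagonals zero).

## Variant scoring

The squared terms of the context formula are realized as additional
columns (degree-2 polynomial expansion); distance-to-TSS and DHS-width
logs use `log(x+1)` to admit zeros. Quantitative annotations can first
be rescaled by the ratio of means against a reference cohort (for
cross-cohort training) and are then z-scored with training-set
parameters that are persisted in the model bundle — scoring always
reuses training-time parameters. Per-TF models add the global fitted
probability, `log(score)` and its square, the allele log-odds
difference, and per-position indicator columns for positions with >= 7
training rows (the same sufficiency rule as the profile QC); constant
columns are dropped. Cell-type gating uses log2 core-vs-flank
enrichment > 1 (i.e. more than twofold), with flanks defined as +-10 bp
outside the match excluding other matches of the same motif and a
Haldane–Anscombe pseudocount of 0.5. The combiner is an L1-penalized
logistic regression over the best per-TF-cluster score per SNV plus the
global probability, with the penalty chosen by cross-validated AUC
(stratified folds, seeded; folds are reduced with a warning when they
exceed n/2). An SNV with no motif overlap is scored through the
combiner with all cluster features at zero, i.e. by the global model
through the combiner's intercept pathway. Precision–recall curves are
computed by an explicit threshold sweep with trapezoidal area over the
recall grid; the tests pin them to scikit-learn's implementation.

## Expression link

Transcript allele counts aggregate non-exonic SNVs per transcript (an
SNV in two transcripts counts for both); exonic SNVs are excluded
because exonic allelic skew reflects the transcript itself. Pairing
uses every (DHS, TSS) combination within 500 kb in the same condition —
not nearest-gene assignment — with the DHS anchored at its hotspot
midpoint and signed distance in transcript orientation (positive =
downstream). The null band is the 2.5–97.5 percentile envelope of the
binned correlation after permuting DHS ratios among pairs within each
condition (1000 permutations by default).

## Design choices made where the design was open

- Adjacent-SNV correlation pairs each tested SNV with its immediate
  downstream tested neighbor per chromosome (minimal reading of
  "adjacent"); its permutation band is an extension, produced the same
  way as the expression band.
- Sharing matrices are computed on the intersection of the two tested
  universes (only jointly tested SNVs have p-values in both); entries
  resting on fewer than 50 SNVs are masked.
- Chromosome names are opaque labels; `restrict_to_hotspots` takes an
  `exclude_chroms` flag that routes whole chromosomes (e.g. chrX) to
  the untested background set for designs that test autosomes only.
- The q-value pi0 estimator is the smoother (cubic fit), not the
  bootstrap; the lambda grid is the standard 0.05..0.95.
- The lasso penalty uses the CV-maximum rule rather than the 1-SE rule.
- Effect sizes of causal variants are a modeling choice (no empirical
  distribution is available at desk scale) and are config-exposed.

## Problem sizes

Unit and property tests run on cohorts of 1,000–20,000 SNVs; the
false-discovery benchmark uses 20 cohorts of 50,000 SNVs, chosen so the
flagged set per cohort (~1,500 calls) makes the realized FDP estimate
stable while the whole benchmark stays under a minute. The
cell-type-vs-aggregate scoring comparison uses 12,000-SNV cohorts with
fully cell-type-specific causal motifs, deeper coverage (mean 150) and
a 0.9 motif-planting rate so that per-cell-type labels are plentiful
enough to train gated TF models on half the SNVs and evaluate on the
held-out half.

## Known limitations

- The beta-binomial dispersion is global per condition; depth-dependent
  dispersion is not modeled.
- Storey's smoother uses a cubic polynomial rather than a smoothing
  spline; on the sizes tested the difference is within the estimator's
  own noise, and the BH fallback bounds small-sample behavior.
- The SAM-text ingestion path is minimal (the filters operate on record
  fields); BAM/CRAM and tabix indexing are out of scope.
- `pairwise_sharing` with very small flagged sets returns 0 via the
  BH fallback (pi0 = 1); entries are masked below 50 SNVs for this
  reason.
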