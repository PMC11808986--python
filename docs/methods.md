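# Methods

This note records the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Coordinates and formats

All coordinates are 0-based half-open internally; VCF positions are shifted
by one on load, BED/BEDPE are taken as-is. Only cis (same-chromosome) loops
are representable: the loop analyses are cis-only, and trans BEDPE rows are
skipped with a warning. Contact matrices are stored as sparse
upper-triangle triplets (plain text `bin_i  bin_j  count`); symmetric
queries fold the lower triangle. Missing genotype dosages are excluded
pairwise in every regression rather than imputed, matching standard QTL
practice and keeping each fit's sample size explicit.

## Matrix balancing

Coverage bias is removed by iterative correction: per-bin weights w are
iterated with a square-root damped update until every unmasked bin's
weighted marginal equals the mean marginal to relative tolerance 1e-5
(at most 200 sweeps). Bins with zero raw coverage are masked (NaN weight)
and excluded from decay curves, loop windows and insulation diamonds.
Weights are scaled so the mean unmasked weight is 1, which keeps balanced
counts on roughly the raw-count scale; the scale is arbitrary and cancels
in the decay-ratio normalization. Iterative correction replaces the
closed-source balancing of the Juicer ecosystem; both schemes equalize
marginals, and for a multiplicative (rank-one) bias the fixed point
inverts the bias exactly.

## Loop strength and distance decay

Loop strength is the **sum** of balanced counts over the 3×3 pixel block
(15×15 kb at 5 kb resolution) centred on the pixel containing the anchors'
midpoints, clipped at matrix bounds; masked pixels contribute 0. A mean
over the block is available as an option (it differs only by the constant
9 on unclipped windows). The expected-decay curve E(d) is the mean balanced
count over all unmasked pixel pairs per 10 kb distance lag, per chromosome;
lags with no unmasked pixels are undefined (NaN), never 0. Cross-library
normalization multiplies each loop's strength by E_ref(d)/E_sample(d) at
the loop's midpoint distance rounded to the nearest lag — a
distance-dependent correction, not a single scalar, because decay curves
differ in shape as well as depth. The reference library defaults to the
lexicographically first sample and is recorded on the result. Strengths
where E_sample(d) = 0 are set missing. log2 (pseudocount 1) is applied only
after decay normalization.

## Insulation

Diamond insulation at 25 kb bins, 100 kb window (w = 4): score(i) = log2 of
the mean balanced count over unmasked pixels of rows [i−w, i−1] × cols
[i+1, i+w], divided by the chromosome-wide mean of those diamond means.
The diagonal pixel (i, i) is excluded by construction of the block (this
matches the convention of the standard cooler-ecosystem implementation).
Bins within one window of either chromosome end are undefined; a
chromosome shorter than two windows yields an all-undefined track with a
warning. Scores are quantile-normalized across libraries by default: each
sample's sorted values are mapped onto the cross-sample mean quantile
vector, ties receiving the mean of their tied reference values; samples
with fewer than two finite values are excluded.

## Differential analysis and outliers

Per-feature OLS of (log2) value on a binary group indicator plus covariates
(sex by default). The group coefficient's two-sided t-test p (n−k d.o.f.)
is BH-corrected across features. Features constant across samples report
beta 0, p 1 rather than dividing rounding noise by rounding noise. With no
covariates the fit reduces exactly to the pooled-variance two-sample
t-test (asserted to 1e-12 in the tests). The label-shuffle check permutes
group labels (covariates stay attached to samples) and re-runs the whole
pipeline, reporting significant counts per shuffle — the pipeline-level
null check.

Expression counts are normalized by median-of-ratios size factors (genes
with mean raw count below 5 removed first; genes with any zero count are
excluded from factor estimation). This is the same estimator the standard
RNA-seq packages implement, written out directly so the stage is
self-contained.

Single samples without replicates (cell lines) are screened per feature by
z = (query − cohort mean)/cohort sd with a two-sided normal tail p,
flagged at unadjusted p < 0.05 (strict). The plug-in mean/sd ignores
estimation error, so the realized null flag rate is slightly above 5% at
cohort sizes in the tens; the screen ranks candidates, it does not control
an error rate. Altered-fraction summaries divide flagged by *defined*
features, excluding undefined edge bins.

## Pair classes and correlation

A feature point (gene TSS; peak midpoint) is classified against a loop as
`anchor_overlap` (inside an anchor), `spanned` (strictly between anchors),
`nearby` (outside the span, ≤ 250 kb from the nearest loop end) or
`distal` (> 250 kb and ≤ 4 Mb, the background set); farther pairs are not
classified. The inner "nearby" bound is a design choice pinned to the
250 kb contrast threshold, with 4 Mb as the outer background bound; both
are configurable. Pearson correlation across samples is computed for pairs
passing the signal filters (gene mean count > 5, loop mean strength ≥ 10,
peak mean ≥ 10 reads, ≥ 3 paired samples), optionally restricted to loops
differential between cell types at FDR < 0.01. Zero-variance vectors are
excluded with a reason rather than returning r = NaN. Insulation–expression
correlation uses the 25 kb insulation bin containing the gene's TSS;
genes whose promoter bin is undefined are excluded with a reason.

## cis-QTL mapping

Phenotypes enter after their modality transform (expression: size-factor
normalized log2; accessibility: quantile-normalized log2; insulation:
quantile-normalized; loops: decay-normalized log2) and then a rank-normal
transform Φ⁻¹((rank − 0.5)/n) with average ranks for ties — applied *after*
the modality transform, the reading we adopt of the permutation software's
normal-transform option. The cis anchor is the gene TSS point, the peak or
insulation-bin interval, or the full loop span (so variants near either
anchor are testable); the window is ±1 Mb. Variants pass MAF > 0.05
(strict). Nominal association is OLS on dosage with covariates; pairs with
fewer than 10 usable samples or monomorphic after missing-data removal are
skipped.

The permutation pass shuffles the phenotype across samples with genotypes
and covariates fixed, records the minimum nominal p over cis variants per
permutation (1,000 by default), fits Beta(a, b) to the minima by maximum
likelihood, and sets p_adj = BetaCDF(p_lead). The degrees-of-freedom
refinement some QTL software layers on the beta fit is omitted; if the fit
fails, the empirical permutation p (1 + #{minima ≤ observed})/(n_perm + 1)
is used and flagged. Permutations are computed in a vectorized path: the
permuted phenotype matrix is residualized against covariates once and
correlated with residualized dosages, which is algebraically identical to
refitting each permutation. BH FDR across phenotypes at 0.1 defines
significance. PCA sample QC removes samples beyond 3 SD on either of the
first two PCs (threshold configurable) and returns the first n_pcs
(default 3) PCs of the retained samples as covariates; a grid search over
n_pcs on one chromosome is how covariate counts are chosen when it
matters. Cross-condition replication reports the fraction of significant
lead pairs found at nominal p < 1e-2 in the other condition and the
fraction of those with concordant slope sign.

## Allelic imbalance

Records enter the accessibility analysis iff depth ≥ 10 and the
minor-allele count ≥ max(2, ⌈5% of depth⌉). Loop allele counts aggregate
allele-assigned contacts whose ends overlap the two anchors expanded by
10 kb (half-open arithmetic, [start − slop, end + slop), either end
orientation); a variant/loop pair is testable with ≥ 3 heterozygous
samples each having ≥ 10 reads and ≥ 1 read per allele. Each SNP is tested
separately against a loop; a pooled mode across anchor SNPs is not the
default because summing reads across SNPs mixes haplotype phases.

The model is BetaBinomial(n_i, p, φ) with logit(p) = θ shared across het
samples; φ is profiled by MLE in [1e-6, 0.5), with the cohort median φ
substituted when a feature has fewer than 5 het samples. The curvature
standard error of θ̂ is inflated by n/(n−1) to account for the profiled
nuisance parameter (the plug-in φ̂ is biased low at small n, which would
otherwise deflate the se and leak false signs cohort-wide).

θ receives a Cauchy(0, S) prior. S defaults to an adaptive estimate: the
method-of-moments signal variance mean(θ̂² − se²), taken at its one-sided
lower 2-standard-error bound and floored at 1e-3. Under a global null the
bound collapses to the floor and every effect shrinks to ~0; genuine
signal keeps the prior wide. A fixed scale (or a flat prior) can be
passed instead. Posterior summaries (mode, sd, sign probabilities) are
computed by trapezoidal quadrature on a θ grid densified at the prior
scale — with a tight prior the posterior is a spike-and-slab-like bimodal
density, so a single-mode Laplace step mis-assigns mass and a uniform grid
coarser than the prior scale drops the spike entirely. The local
false-sign probability is lfsp = min(P(θ ≤ 0), P(θ ≥ 0)); the s-value of a
feature is the mean lfsp over all features at least as confidently signed,
computed in a cohort-wide final pass.

Reference-mapping bias is assumed removed upstream (reads mapped to an
N-masked genome); the model carries no bias term and the generator draws
unbiased counts.

## The synthetic cohort generator

`simulate_contact_map` draws Poisson pixel counts around a mean field
depth · (d + d₀)^−α (d₀ = one bin, avoiding the d = 0 singularity;
α defaults to 1, the canonical contact-decay exponent), multiplied by TAD
block factors and by loop fold-enrichments on the loop's 3×3 pixel
neighbourhood, rescaled to a target total depth. `simulate_cohort` draws
genotypes Binomial(2, MAF), a balanced binary sex covariate, and latent
log2 phenotype values baseline + group effect + sex effect + slope·dosage
+ N(0, σ); expression and accessibility are negative-binomial counts
around 2^latent (Poisson for contact pixels — the minimal standard models
for these assays), loop strengths stay on the latent continuous scale.
Allele-specific alt counts are BetaBinomial(n, logistic(θ), φ) for het
carriers with Poisson depths. Defaults mirror the study design the package
targets: 40 samples split evenly into two T-cell types, 2,000 loop
phenotypes, unit latent noise, overdispersion φ = 0.02, allele depth 100,
MAF 0.3. Everything is a pure function of (config, seed), and the injected
effects are returned as ground-truth tables.

Per-sample contact matrices are generated only on request
(`make_contact_maps=True`): the downstream statistical stages consume the
latent phenotype tables directly, and the map generator is exercised by
its own tests; this keeps cohort simulation cheap at any sample size.

What the generator does *not* emulate: read-level noise and mapping bias,
restriction-fragment structure, trans contacts, LD between variants
(variants are drawn independently), population structure, and
batch/library-preparation artifacts beyond a global depth factor. Passing
tests therefore demonstrate estimator correctness and calibration under
the assumed generative models, not robustness to every artifact of real
sequencing data.

## Numerical choices and degenerate inputs

- Balancing: square-root damped updates; all-zero matrices raise
  "nothing to balance".
- Constant features: beta 0, p 1 (explicit guard, not floating noise).
- BH FDR validates p ∈ [0, 1] and is delegated to statsmodels'
  step-up implementation.
- Beta MLE for permutation minima clips to (1e-12, 1 − 1e-12) and falls
  back to the empirical permutation p on non-convergence.
- Rank-normal transform of an all-tied vector returns zeros with a warning.
- Quantile normalization with unequal missingness interpolates each
  sample's quantiles onto the common grid.
- Decay normalization at an undefined or zero expected value yields
  missing, never 0.
- The problem sizes used in the test suite and acceptance script (e.g.
  2,000-feature nulls, 200 phenotypes × 1,000 permutations, 500-replicate
  power runs, ≤ 200-bin matrices) were chosen as the smallest scales at
  which the calibration properties under test are statistically decisive.

## Known limitations

- The insulation aggregation from finer matrix resolutions uses the mean
  of balanced pixels per coarse bin; genuinely multi-resolution pipelines
  re-bin raw counts instead.
- The outlier screen's plug-in normal approximation is anti-conservative
  at small cohort sizes (documented above).
- The s-value machinery assumes the unimodal Cauchy prior describes the
  cohort's effect distribution. When effects are strongly bimodal (a
  spike of nulls plus large effects), true-null features are shrunk less
  than ideal and the called set's realized false-sign rate can exceed the
  nominal s threshold, although their shrunken effects stay near zero;
  this is inherent to single-scale adaptive shrinkage.
- Beta-approximated adjusted p-values assume exchangeable samples; the
  permutation scheme does not preserve relatedness or repeated-measures
  structure.
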