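# Methods

## The phenotype and the distance

For each gene with at least two expressed transcript isoforms, the splicing
phenotype of a sample is the vector of transcript relative abundances
(splicing ratios): transcript TPMs divided by their sum, a composition on
the simplex. Dissimilarity between two samples' compositions *x*, *y* is the
Hellinger distance

    H(x, y) = sqrt(1/2 * sum_i (sqrt(x_i) - sqrt(y_i))^2)  in [0, 1],

which equals the Euclidean distance between the square-rooted vectors up to
a factor 1/sqrt(2). This identity is what makes covariate correction
compatible with the distance: after the square-root transform, removing
covariates by per-transcript ordinary least squares is a linear operation in
the very space where the distance is Euclidean, so distances between
residualised samples remain meaningful Hellinger-type distances. The
package therefore residualises on the sqrt scale (intercept always
included, categorical covariates one-hot encoded with the reference level
dropped, collinear columns removed with a warning). Whether correction on
the raw-ratio scale would be preferable is genuinely open; the sqrt-scale
choice was made for this self-consistency and is used throughout.

## Filters

Applied per tissue dataset, independently, before testing:

* genes need >= 1 TPM in at least 80% of samples (rounding up); samples
  below 1 TPM are dropped from that gene only;
* transcripts below 0.1 TPM in every sample are removed; ratios are
  renormalised over the surviving transcripts so rows sum to 1 exactly;
* variants are tested in a cis window of the gene body plus 5 kb each side
  (symmetric, strand ignored), must be biallelic, have MAF >= 0.01 and at
  least 10 samples in every observed dosage group, evaluated on the gene's
  retained samples; monomorphic variants are excluded. Samples with a
  missing dosage are dropped from that variant's test only, and the rules
  are re-checked after removal.

All coordinates are 0-based half-open internally; VCF positions are
converted on read, BED is consumed natively, and regions on the command
line use the 1-based `chrom:start-end` convention.

## The association test

Genotype dosage (0/1/2) defines groups; association is the distance-based
pseudo-F (the non-parametric analogue of one-way MANOVA). With the squared
distance matrix Gower-centred as G = -1/2 J (D∘D) J and H the hat matrix of
the group indicators,

    F = [tr(HGH) / (k-1)] / [tr((I-H)G(I-H)) / (n-k)].

The permutation engine uses the algebraically identical within-group
sum-of-squares form (SSW = sum_g (1/n_g) sum_{i<j in g} d_ij^2), which
vectorises over batches of label permutations via one matrix product per
group. The distance matrix is computed once per gene and reused across
variants; only labels change.

p-values come in three modes:

* **exact_perm** — all distinct arrangements of the label multiset are
  enumerated (allowed up to 1e5 arrangements); p is the fraction of
  arrangements, observed one included, with F at least the observed F, so
  it is never 0 and ties count against significance.
* **mc_perm** — B random permutations with the (1+hits)/(1+B) estimator.
* **approx** (default) — a Pearson-III (shifted gamma) right tail is
  moment-matched to an initial batch of 100 permutation F values
  (bias-corrected skewness). Because the third moment is noisy in small
  batches, the batch doubles — up to 12,800 — whenever the fitted p lies in
  the tail of the current batch. The family itself reproduces brute-force
  permutation p-values to within a few percent when its moments are well
  estimated; the adaptive batch keeps the worst log10 deviation from a
  1e5-permutation reference under 0.3 for p >= 1e-4. The permutation modes
  remain the ground-truth path and arbitrate the approximation in the test
  suite.

Because the pseudo-F is sensitive to unequal dispersion between genotype
groups, every pair also gets a homogeneity-of-dispersions screen: each
sample's Euclidean distance to its group centroid in the adjusted space,
one-way ANOVA F on those distances, significance by 999 label permutations.
Pairs failing the screen at BH FDR < 0.05 (computed across all nominal
tests of a run) are flagged and excluded from the reported significant
pairs, but stay in the multiple-testing accounting.

## Effect size (MD)

MD is the largest absolute difference in mean adjusted transcript relative
expression between any two dosage groups, in [0, 1]. Adjusted relative
expression is obtained by re-centring the sqrt-scale residuals with the
per-transcript grand-mean sqrt-ratio, clipping at zero and squaring; with
no covariates this reproduces the raw ratios exactly, so the estimator is
unbiased for the simulated ratio-scale shift. Reported sQTLs require
MD >= 0.05.

## Gene-level significance and pair retrieval

Per gene, phenotype rows are permuted jointly across all cis variants (one
shuffle per permutation, preserving LD structure), the minimum nominal p is
recorded per permutation, and the empirical gene-level p is
(1 + hits)/(1 + B). The scheme is adaptive: permutations run in batches of
100 and stop once 10 permutation minima lie at or below the observed
minimum, or at 1,000 permutations (B_min = 100, hit_target = 10,
B_max = 1000; configurable — the calibration checks are agnostic to these
constants). A Beta distribution fitted by maximum likelihood to the
permutation minima refines quantile look-ups. Within the scheme, each
variant's permuted F values are converted to nominal p through the
variant's pre-fitted Pearson-III tail, so a permutation costs one pseudo-F
per variant.

sGenes are called by Benjamini-Hochberg at FDR 0.05 on the empirical
p-values. To retrieve all significant pairs, the genome-wide threshold p_t
is the midpoint between the largest empirical p passing BH and the smallest
failing; each sGene maps p_t back to a nominal threshold through its
permutation-minimum distribution (Beta quantile when available, else the
empirical quantile). Reported pairs satisfy nominal p <= threshold,
MD >= 0.05 and the homoscedasticity screen.

## Replication (pi1)

pi1 = 1 - pi0 with pi0 estimated on the grid lambda = 0.05..0.95:
pi0(lambda) = #{p > lambda} / ((1 - lambda) n), smoothed by a cubic
smoothing spline (weights 1 - lambda) and evaluated at lambda = 0.95, then
clamped to [0, 1]. Below 100 p-values a bootstrap selection (the lambda
minimising bootstrap MSE against the minimum raw estimate) replaces the
spline.

## Cross-tissue analytics

* **MD correlation** — Pearson r of effect sizes over variant-gene pairs
  tested in both tissues and significant in at least one (NaN below 3
  eligible pairs).
* **Jaccard** — on the significant-pair sets; 0 when the union is empty.
* **Centroid distance** — for pairs tested in all tissues and significant
  in at least one, d(t1,t2) = (1/p) sum_j sum_k ||c_{t1jk} - c_{t2jk}||,
  the per-pair sum over dosage groups of Euclidean distances between
  centroids of the adjusted phenotype. Pairs whose transcript sets differ
  between tissues are dropped (logged); a dosage group present in exactly
  one tissue drops the pair (conservative), while groups absent in both
  contribute zero.
* **Tissue specificity** — s_t = 1 minus the mean off-diagonal similarity
  of tissue t.
* **Dendrogram comparison** — hierarchical clustering (average linkage by
  default; the linkage is configurable since nothing pins it down) and
  Baker's Gamma: the Spearman correlation of the merge stages at which
  leaf pairs first combine, with significance from shuffling one tree's
  leaf labels 10,000 times at constant topology.
* **tau** — sum(1 - x_t/max x)/(n-1): 0 for uniform profiles, 1 for
  one-tissue profiles. The splicing variant tau_s feeds -log10(FDR),
  capped at 300 so underflowed FDRs stay finite. A percentile filter
  utility selects the top/bottom quantiles of either index.

## Event classification

For an sQTL, the isoform pair examined is the two transcripts changing the
most in opposite directions over the dosage-group pair that realises the
gene's MD. The classifier works in transcript orientation (minus-strand
coordinates are mirrored, so exon starts are always acceptors), anchors the
two splice-site chains on shared sites and shared termini, and labels each
maximal variable region: cassette exon, alternative donor/acceptor, intron
retention, mutually exclusive exons; differing termini yield alternative
or tandem first/last exons and UTR labels. Variable regions not matching a
single simple pattern — including multiple exons skipped at once — are
labelled complex (internal, 5' or 3'); the boundary between "complex" and
stacked simple events is a design choice of this implementation and is
versioned with it. Coordinates are compared exactly, with no fuzz. One
isoform pair may carry several labels.

## Matched-null enrichment and location

Enrichment inputs are the top ten most significant sQTLs per gene. Null
sets (1,000 by default) are matched per sQTL on the relative location bin
within the gene (20 bins, the same scheme as the location profiles — the
bin count for matching is unified with the profile bins) and on MAF within
±0.02, drawn without replacement within a set and with replacement across
sets; an exhausted MAF stratum falls back to the nearest-MAF candidate in
the bin, an empty bin is an error. The OR compares the annotated fraction
of sQTLs to the rounded (half-up) mean annotated count across null sets;
two-sided Fisher exact p-values, BH-corrected; annotations with mean null
count below five are dropped. Location profiles assign each variant to one
of 20 equal bins (bin 1 at the 5' end, strand-aware), normalise per region
and average across regions after removing the shortest 20%.

Heteropleiotropy is a deterministic 8-boolean rule on a variant's
sQTL/eQTL status for two genes in two tissues: sQTL-only for g1 in t1,
eQTL-only for g2 in t2, and silent for the crossed combinations; any
missing call makes the variant not evaluable rather than negative.

Splice-site strength changes are scored with a user-supplied PWM:
score = sum log2(p(base)/0.25) over the site, delta = |alt - ref|;
indels are flagged unsupported.

## The synthetic-data generator

The generator defines the study conditions for every test. Genotypes are
Binomial(2, MAF) under Hardy-Weinberg; the default MAF of 0.35 models a
common variant whose three genotype groups are all observable at the
simulated sample sizes (under HWE the minor-homozygote group crosses the
10-sample rule in expectation only above MAF ~0.26 at n = 150). Splicing
ratios are Dirichlet draws whose mean is shifted between genotype groups
along a two-transcript contrast; because the Dirichlet mean is linear in
the shift, setting the shift to the target MD calibrates the population MD
of group means exactly (closed form; no numerical root finding needed).
The concentration parameter (default 50) sets biological noise — component
standard deviations around 0.07, of the order seen in transcript-ratio
data. Gene expression is lognormal (median 50 TPM, sigma 0.5), comfortably
above the 1-TPM filter; covariates act additively on the sqrt-ratio scale
and are renormalised back to compositions. Multi-tissue effect-size tables
use a one-factor Gaussian model mapped linearly into [0.05, 1], so the
pairwise MD correlation equals the requested sharing; significance flags
are drawn independently of effect size so that conditioning on
"significant in >= 1 tissue" does not attenuate the correlation.

What the generator does not emulate: linkage disequilibrium between
variants (one causal variant per gene), read-level sampling noise in the
TPM estimates, correlated expression across genes, population structure,
or the heavy-tailed MAF spectrum of real cohorts. Passing tests therefore
demonstrate the statistical machinery under its own assumptions — correct
calibration, effect recovery and FDR control on compositional phenotypes —
not performance on any specific real dataset.

## Problem sizes and numerical choices

The test and acceptance runs use cohorts of 150–200 samples and up to
1,000 genes with 3 transcripts each, sizes at which every stage of the
pipeline (including 1e5-permutation reference runs) completes in minutes
on a single core; the statistical conclusions (calibration, power at
MD 0.3, FDR control) are stable at these sizes. Tie handling in all
permutation comparisons is >=, counting against significance. Degenerate
inputs (zero total dispersion, zero within-group dispersion) yield NaN/1.0
with explicit flags rather than errors. p-value floors are the smallest
positive float; empirical estimators carry the +1 correction and cannot
return 0.

## Known limitations

* The approx mode's parametric family is a design choice validated against
  permutations, not a closed-form null; extremely small p-values (beyond
  the adaptive batch) are extrapolations.
* The homoscedasticity screen uses distances to the group spatial
  centroid, not the spatial median; with tiny groups its permutation p is
  coarse (999 permutations).
* Event classification is exact-coordinate; annotation jitter in real GTFs
  (e.g. 1-bp boundary disagreements) will surface as tandem/complex labels.
* pi1's spline smoother inherits the usual conservative bias of
  pi0(lambda) extrapolation for signal concentrated near p = 0 mixed with
  weak signal.
* The pipeline tests one variant at a time; no interaction, haplotype or
  trans analyses, and no co-localisation.
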