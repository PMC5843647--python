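# Methods

`plastigene` quantifies two things from a family × environment × food
factorial expression experiment: how much of the transcriptome responds to
the seasonal environment (plasticity), and how much intra-population
genetic variation exists *for* that response (genotype-by-environment
interaction, GxE). A companion module computes per-gene coding-sequence
diversity statistics (π, Watterson's θ, Tajima's D) and repertoire
comparisons, so that selection on plasticity genes can be examined. All
stages run on synthetic data with known ground truth, generated by the
package itself.

## The experimental design being modelled

The reference design is a split-brood factorial: seven full-sib families,
each split across two rearing temperatures standing for the dry and wet
seasons, crossed with two developmental food treatments (ad-libitum
control vs larval food stress). Four families contribute three replicate
females per family × season × food cell and three families contribute two,
giving 72 samples per tissue; abdomen and thorax are analysed
independently end to end. In this design, family main effects measure
genetic variation in *average* expression, and the family × season
interaction measures genetic variation in *plasticity*.

## Synthetic data generator

`simulate_counts` draws counts from a negative binomial whose log2 mean is

    log2 μ_gs = log2(L_s · q_g) + s_g x_season + d_g x_food
                + f_{g,fam(s)} + i_{g,fam(s)} x_season

with x_season, x_food = ±1/2, so the wet−dry log2 fold change of gene g in
family f is exactly s_g + i_{g,f} and its across-family mean is s_g.

Key parameters (defaults in parentheses):

- fractions of affected genes — season 0.46, family 0.50, food 0.05, GxE
  0.01. These follow the detected fractions of the reference experiment;
  for GxE the detected 1% is used as the generating fraction for lack of a
  better estimate. Exactly round(frac·n_genes) genes get each flag.
- effect scales (log2 units) — season 1.0, family 1.0, food 0.5, GxE 0.5.
  Season and food effects are fixed-magnitude spike-ins with random sign,
  the standard construction in differential-expression power studies: it
  makes detection power and sign-recovery well defined at a stated effect
  size, whereas a N(0, σ) draw places a share of "true" effects
  arbitrarily close to zero where the sign is unrecoverable in principle.
  Family effects and GxE slope deviations are drawn N(0, σ) per family and
  centred to sum to zero per gene, which keeps "average expression" and
  "plasticity" components orthogonal and parameter recovery well defined.
- noise — NB dispersion 0.05 (variance = μ + 0.05 μ²), a typical
  biological-replicate value for bulk RNA-seq; dispersion ≤ 0 falls back
  to Poisson. Library sizes are lognormal, mean 5 × 10⁵ expected counts
  per sample with CV 0.2 — deliberately desk-scale rather than the tens of
  millions of reads of a real experiment, so the full test battery runs in
  seconds. Baseline relative abundances q_g are lognormal (σ_ln = 1.2),
  normalised to sum to one.

What the generator deliberately does not emulate: read-level artefacts
(mapping bias, positional or GC bias), isoform structure, correlated genes
(all genes are conditionally independent given the design), and
outlier samples. Passing tests therefore demonstrate that the inference
machinery is correct and calibrated under the assumed model, not that the
model captures every pathology of real libraries.

`simulate_haplotypes` controls the site-frequency spectrum directly: the
minor-allele count i at each segregating site is drawn from {1..n−1} with
weight 1/i (the neutral coalescent expectation), 1/i² (excess of rare
alleles → negative Tajima's D, the footprint of purifying selection), or
uniform (excess of intermediate-frequency alleles → positive D). The 0/1
polarity is bookkeeping only; every statistic used is frequency-based and
polarity-agnostic.

## Normalization

Genes expressed (count > 0) in fewer than 3 samples, or with mean CPM
below 0.25, are removed; CPM for the filter uses pre-filter library sizes
so the rule is independent of iteration order and idempotent. TMM factors
follow the published trimmed-mean-of-M-values definition exactly
(reference sample by upper-quartile proximity to the mean; M and A
computed over co-expressed genes; 30% two-sided trim on M and 5% on A;
inverse-variance weights; factors rescaled to geometric mean 1) and are
verified against edgeR's `calcNormFactors` in the test suite. Note two
consequences of the definition: a library in which a minority of genes is
strongly up-regulated receives a factor *below* 1 (its effective depth is
inflated), and the precision weights make factors only approximately
invariant to rescaling one library's counts (drift at the ~10⁻³ level).

Downstream transforms: log10(CPM+1) for PCA and clustering, log2(CPM+1)
for model fitting, per-gene Z across all samples of a tissue for reaction
norms and cross-environment correlations. The +1 offset (configurable)
maps zero counts to zero; it shrinks fold changes of very low-expressed
genes toward zero, which is visible as a small conservative bias in
fold-change recovery.

## Factorial inference

Each gene's log2(CPM+1) is fit by OLS with sum-to-zero coding under

    y ~ season + food + family + season:family + food:family
        + season:food + season:food:family

Terms are tested by drop-one-term F tests respecting marginality: the
three-way interaction in the full model, each two-way interaction in the
model without the three-way, each main effect in the purely additive
model. This is a deliberate substitution of engines: the original
analysis used negative-binomial GLMs with dispersion shrinkage (edgeR) on
raw counts. A Gaussian linear model on normalized log counts is fully
specified, deterministic, preserves the design structure and fold-change
semantics, and — as the calibration tests show — controls the FDR on this
data regime; the acceptance surface is parameter recovery and
calibration on synthetic data, not replication of published per-gene
counts. P-values are BH-adjusted per term across genes.

Fold changes are least-squares-mean differences on the log2 scale, signed
so positive = higher in the wet season (stress for food). Terms involving
family are summarized as the mean |contrast| over the F−1 orthogonal
Helmert contrasts (each scaled as "family k vs mean of families 1..k−1",
so contrast values are directly interpretable log2 fold changes); a max
mode is available. Degenerate genes (zero variance) are reported with
p = 1 and logFC 0 rather than NaN.

The paired fold-change-magnitude comparison (e.g. GxE vs family) uses the
two-sided Wilcoxon signed-rank over genes: exact distribution for n ≤ 25
without zeros or ties, otherwise the normal approximation with Pratt
zero handling.

## Plasticity metrics

Reaction norms are per family × gene OLS fits of Z-scored expression on
season coded dry = 0, wet = 1; the intercept is therefore exactly the
family's dry-season mean and the slope its wet−dry difference.
Across-family variability of slope vs intercept is compared by paired
signed-rank. The variability measure defaults to the across-family SD;
the coefficient of variation (SD/|mean|) is emitted alongside but flagged
undefined when |mean| < 10⁻⁸, which is common on Z-scaled data where the
per-gene mean is near zero by construction — the SD is the stable
quantity there.

Cross-environment genetic correlations correlate family mean expression
in wet vs dry across families, per gene; Pearson is the default and
Spearman is always computed as well (published analyses describe Pearson
in their methods but report Spearman medians, so both are first-class).
Genes with constant family means in either season are flagged undefined
and excluded from the median.

PCA is SVD on samples with genes centred (not scaled); component signs
are fixed deterministically (largest-|loading| gene positive). Each
leading PC's scores get a two-way fixed-effects ANOVA (season, family,
interaction) with BH adjustment across tested PCs per term; the number of
PCs tested defaults to the smallest set reaching 60% cumulative variance,
mirroring the reference analysis's "first 13 PCs, 62% of variance".
Sample clustering is neighbour joining on the Euclidean distance matrix
of log10(CPM+1); the NJ implementation joins the Q-criterion-minimal pair
with ties broken toward the lowest index pair, uses the standard
three-point branch-length formulas, clamps negative branch lengths to
zero, and recovers additive trees exactly (verified to 10⁻⁹ in tests,
plus topology cross-checks against scikit-bio's implementation).

## Diversity statistics

π is the mean pairwise difference count over all n(n−1)/2 haplotype pairs
(computed per site from allele counts; verified against a brute-force
double loop), θ_W = S/a₁, and Tajima's D uses the standard constants
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ as spelled out in `popgen.py`), verified
against an exact-rational-arithmetic recomputation and against dendropy.
D is flagged undefined when S = 0 or n < 4. Totals and per-site values
(divided by coding-sequence length) are both emitted, since published
per-transcript values are ambiguous between the two scalings.

Repertoire comparisons run a two-sided Mann-Whitney U (exact enumeration
when min(n₁, n₂) ≤ 8 and no ties, tie-corrected normal approximation
otherwise) plus a size-matched permutation null: 1000 without-replacement
draws of |test| genes from the background, two-sided p by doubling the
smaller tail with +1 smoothing, capped at 1 — so p can never be 0 and is
calibrated under the null (verified: rejection rate at 0.05 within
[0.01, 0.10] over 200 null replicates). The 2 × 2 repertoire contingency
test is the Yates-corrected chi-square, which reproduces the published
worked example (χ² = 2.8, p = 0.09) from its printed counts.

## Numerical and degenerate-input conventions

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical
  outputs everywhere, including the pipeline report.
- Permutation draws sort gene ids internally, so results are invariant to
  input ordering.
- TMM returns factor 1 with a warning for a sample sharing no expressed
  genes with the reference; single-sample matrices get factor 1.
- Families missing one season are dropped from reaction-norm and
  correlation computations with a warning.
- Aliased (confounded) designs raise an error rather than silently
  dropping columns.

## Problem sizes

The bundled analysis scripts and the acceptance computations use 2,000
genes at 72 samples per tissue (null calibration: 20 replicate
simulations; permutation uniformity: 200 replicate null sets of 1,000
draws each; diversity calibration: 1,000 genes at n = 20, S = 20). These
sizes give standard errors comfortably below the tolerances being checked
while keeping a full run in the tens of seconds on one core; every
computation scales linearly in genes if rerun at transcriptome scale.

## Known limitations

- The Gaussian-on-log-counts engine has less power than a dispersion-
  shrinking NB GLM at very low counts; it is calibrated but conservative
  there (the low-expression filter removes the worst cases).
- CV of reaction-norm parameters on Z-scaled data is frequently undefined
  (near-zero means); use the SD measure, which is the default.
- The +1 CPM offset biases |logFC| of very low-expressed genes downward.
- The synthetic GxE fraction (1%) is a detected, FDR-thresholded fraction
  in the reference experiment, not an estimate of the true fraction; it
  is a convenience default, and power statements are always made relative
  to the generator's own truth table.
- Haplotype simulation draws sites independently (free recombination); no
  linkage structure is modelled.
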