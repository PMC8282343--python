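# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `sigqtl`.

## Expression preprocessing

Counts are filtered with a drop rule: a gene is removed when its expression
is below 6 reads **or** 0.1 counts per million in at least 20% of samples
(equivalently, kept only if it clears both thresholds in strictly more than
80% of samples; a gene at exactly 80% is dropped). Sex-chromosome genes
(chrom X/Y in any "chr" dialect) are removed first; because the autosomal
keep-set does not depend on that order, the ordering is a convention, not a
result. Normalization is log2-CPM with a prior count of 0.5 and library
size + 1 — the log-CPM transform used by voom-style pipelines. Precision
weights are deliberately not computed: every downstream fit (elastic net,
OLS) is unweighted, so weights would never be consumed.

Technical/biological covariates are compressed to their top principal
components: categorical covariates are one-hot encoded (first level
dropped), missing numeric values are median-imputed, columns are z-scored,
and the top k = 3 PCs (with variance-explained fractions) are regressed out
of the normalized expression gene by gene. Residualization is ordinary
least squares with intercept; residuals are exactly orthogonal to the
covariate columns and have zero mean.

## Transcriptional signatures

Model: for a measured variable *y* over the expressed genes' residual
expression E, a Gaussian elastic net in the glmnet parameterisation

  (1/2n)·Σᵢ (yᵢ − β₀ − Σₙ βₙ Eᵢₙ)² + λ·(α‖β‖₁ + (1−α)/2·‖β‖₂²),

with mixing α = 0.1. The relaxed α lets groups of co-regulated genes share
the signal instead of forcing an arbitrary representative, which matters
because blood expression modules are strongly co-expressed.

Solver: hand-written cyclic coordinate descent on the Gram matrix X'X with
sequential strong-rule screening, covariance updates over the ever-active
set, and warm starts along a descending 100-value lambda grid from the
data-derived λ_max = maxⱼ|xⱼ'y|/(nα) down to λ_max·r, r = 10⁻² when n < p
(10⁻⁴ otherwise, the glmnet conventions). Screening is safe: a full KKT
pass after convergence on the screened set admits any violator and
iterates. Convergence uses the glmnet criterion (largest single-coordinate
objective change below tol·y'y, default tol = 10⁻⁶). Predictors are
standardized internally; coefficients are reported on the original scale.
The solver is checked against scikit-learn's `enet_path` (agreement to
~10⁻⁶ at matched grids) and cross-validation predictions against
brute-force per-fold refits.

Cross-validation: true leave-one-out by default (n per-fold path solves;
the Gram of a training fold is a rank-k update of the full Gram, which is
what makes LOO at n ≈ 250, p ≈ 2000 affordable — roughly 40 s per
variable), with a contiguous k-fold option (default 10 folds, path early
stopping with a 15-lambda patience) for bulk fits such as permutation
nulls. Each training fold re-centers the predictors and the response
(rank-one Gram corrections); without this, the held-out samples' influence
on the global means optimistically biases the CV error by order 1/n —
visible in null-phenotype r² distributions. Per-fold re-*scaling* is not
applied: the column scale estimates are far more stable than means, and the
residual effect is second order.

λ is chosen by minimum CV MSE (the one-standard-error rule is available via
`selection="1se"`). The variance explained is defined from the CV error,
r² = 1 − cv_mse/var(y) with the sample (n−1) variance; it is reported
signed, never clamped, and a signature is "selected" when r² ≥ 0.01 (the
1%-of-variance rule). Imputation applies the chosen model to **all**
samples: for training samples this replaces the noisy measurement with the
model prediction (denoising); for unmeasured samples it is imputation
proper.

### Null behaviour of the CV r²

For a phenotype with no true expression association (e.g. a permuted
variable), the selected r² is usually near zero but has an intrinsic upper
tail: with p = 2000 genes at n = 250, the largest spurious sample
correlation between any gene and the phenotype is about
√(2·log p/n) ≈ 0.25 in expectation, and because that fluke is a property of
the realized sample, cross-validation within the same sample cannot screen
it out; minimum-MSE selection over the lambda grid adds a winner's-curse
component. Empirically ~5–8% of permuted phenotypes reach r² between 0.02
and 0.09 at these dimensions — under this implementation, under true
leave-one-out, and under the independent R glmnet/cv.glmnet oracle run on
identical data. The 1%-variance selection threshold should therefore be
read as a screening rule, not a per-variable error guarantee; the
permutation-based corrections downstream (not the signature r²) carry the
formal error control.

The restricted-panel comparison (`compare_restricted`) refits the identical
procedure on a fixed gene panel (e.g. a published 53-gene adversity panel)
and reports both r² values along with how many panel genes are measurable
in the data. Longitudinal validation imputes wave-2 signatures from
expression never seen in training and Spearman-correlates imputed changes
with observed changes.

## cis-eQTL mapping

Candidates: variants on the gene's chromosome with |pos − TSS| ≤ 1 Mb
(inclusive; TSS strand-aware — for minus-strand genes the annotated end)
and dosage-based cohort MAF strictly greater than 0.1, MAF = min(m, 1−m),
m = mean(dosage)/2. Nominal pass: per-variant simple OLS with intercept,
two-sided t test with df = n − 2 (no residual-df correction for the
upstream residualization; at n = 250 with 3 covariate PCs the df error is
~1%). Zero-variance variants are flagged and skipped, not fatal.

Permutation pass: the expression vector is permuted (dosages and their LD
structure fixed), the minimum nominal p over candidates recorded per
permutation; adaptive stopping ends permutation once 100 permutation minima
beat the observed minimum, never before 1,000 nor after 10,000
permutations. The direct permutation p is (1 + hits)/(1 + P). A Beta(a, b)
is fit to the permutation minima by maximum likelihood
(`scipy.stats.beta.fit`, location 0/scale 1, method-of-moments start and
fallback, shapes clipped to [10⁻³, 10⁶]); the beta-approximated p-value is
the Beta CDF at the observed minimum. Sanity anchors: one candidate variant
gives Beta(1,1) (the minimum of one uniform); m independent candidates give
approximately Beta(1, m). Gene-level FDR applies Storey q-values to the
beta-approximated p-values; eGenes are genes with q ≤ 0.10.

Lead-variant ties break by smallest nominal p, then smallest |TSS
distance|, then lexicographic variant id. Per-gene RNG streams are derived
from the scan seed and a CRC32 of the gene id, so results are invariant to
gene and variant input order. The expression-PC optimization loop appends
top-k expression PCs to the residualization for each k in a grid, reruns
the scan, and keeps the k maximizing the eGene count (ties to smallest k).

## Interaction (GxE) eQTL mapping

Each signature is quantile-normalized by the rank-based inverse normal
transform with the Blom offset, Φ⁻¹((rank − 3/8)/(n + 1/4)), average ranks
on ties — this bounds the influence of outlying signature values on the
interaction term. The model per (eGene lead variant, signature) pair is

  expression ~ 1 + dosage + signature + dosage·signature [+ covariates],

fit by OLS on residualized expression with two-sided t tests for all four
named terms (covariates — e.g. the four blood-cell-composition signatures —
enter as main effects only, matching the adjusted model's formula). Lead
pairs come from the cis scan run *without* expression PCs, because
expression PCs absorb cell-composition and environmental variance and would
make the interaction uninterpretable.

Empirical null: dosages are permuted per pair (expression-signature pairing
intact), the model refit, and interaction p-values pooled across all lead
pairs within a signature until n_null values are collected
(rounds = n_null/n_pairs; each pair has its own seeded RNG stream, so the
store is deterministic and insensitive to pair order). Pooling across pairs
is what makes nulls of 10⁶–10⁸ values reachable; a per-pair null at that
depth would be computationally absurd and statistically unnecessary since
the correction is applied per signature. The permutation-corrected p-value
is (1 + #{null ≤ p})/(1 + n_null) — the +1/+1 pseudocount keeps p > 0 —
and Storey q-values are computed over the corrected p-values within each
signature separately; interactions with q ≤ 0.10 are reported significant.

### Why the empirical null, not the parametric p

On negative-binomial counts the interaction t-test is only asymptotically
calibrated: per-sample variances depend on the (confounder-driven) means,
log-CPM residuals of genes with strong unmodeled structure are non-Gaussian,
and low-MAF dosages concentrate the interaction term's leverage in a
handful of samples. Across simulated cohorts the realized type-I rate at
nominal 0.05 therefore varies around 0.05 (roughly 0.045–0.07 depending on
the realized environment and confounder draws), and with 10⁵ pooled values
a KS test can detect the same deviation in the permutation null itself.
That is the point of the design: because dosage permutation preserves the
expression-environment pairing and hence the heteroskedasticity pattern,
the pooled null reproduces whatever miscalibration the parametric test has,
and the corrected p-values — not the nominal ones — carry the inference.
The FDR experiments confirm that the corrected pipeline controls FDR even
in cohorts whose nominal type-I rate is inflated. Calibration experiments
test lead pairs only at cohort MAF > 0.1, the same rule the cis scan
applies — rare-dosage variants are never tested in the pipeline and their
interaction t-statistics are the worst-behaved.

The batched OLS used for scans and nulls reduces each permutation to a
handful of matrix-vector products by exploiting that all design moments not
involving the dosage are permutation-invariant; it is verified against
statsmodels OLS term by term.

Storey q-values: pi0 is estimated on the lambda grid 0.05–0.95 (step 0.05)
with a cubic smoothing-spline extrapolation at the right end, clipped to
(0, 1], falling back to pi0 = 1 (exact Benjamini-Hochberg) if the smoother
fails. Measured-variable reruns drop samples missing that variable rather
than imputing, and report the per-record sample size implicitly through the
restricted cohort. Replication between measured-variable and signature
results uses Fisher's exact test on the 2×2 gene classification (p < 0.01
in each analysis; sample odds ratio ad/bc with a 0.5 continuity correction
on zero cells) and the Pearson correlation of interaction z-scores
(b/se) over joined records. TWAS integration is bookkeeping only: the
externally produced gene-trait table is intersected with the marginal-
signature (q_signature ≤ 0.10) and GxE (corrected q ≤ 0.10) gene sets per
signature and trait.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the scale of a ~250-participant pediatric cohort with ~50 psychosocial and
clinical variables measured on roughly half the participants:

- **Phenotypes.** Variables live in category blocks (SES, social
  relationships, emotionality, asthma, blood composition, biomarkers); each
  non-blood block shares a latent factor (loading 0.75, so within-block
  correlations ~0.56 exceed between-block ones). Observed values are latent
  + Gaussian noise; the default noise SD of 1 on unit-variance latents
  gives a true signal fraction of 0.5, a deliberately pessimistic
  measurement quality. A configurable fraction (default 0.5) of samples is
  missing per variable.
- **Blood composition.** Four cell proportions (neutrophils, lymphocytes,
  monocytes, eosinophils) drawn from a Dirichlet with mean ~55/35/7.5/3%
  and realistic spread; their centered log-ratios drive dedicated gene
  blocks (40 genes each, loading 0.5) and appear as the four
  blood-composition phenotype latents, so cell-composition signatures are
  learnable and can partially overlap psychosocial ones.
- **Genotypes.** Per-variant allele frequency uniform on (0.05, 0.5),
  dosages Binomial(2, f); a dosage mode adds truncated imputation noise.
  One chromosome with genes every 100 kb and variants uniform over the
  span, so a 1 Mb cis window holds tens of variants.
- **Expression.** Negative-binomial counts with log-mean = gene baseline +
  β_g·dosage + β_e·latent + β_gxe·dosage·latent + confounder and
  cell-composition terms + log library share; relative abundances are
  renormalized per sample so column totals track the log-uniform library
  sizes (1–3 M for the default 2,000 genes, i.e. realistic per-gene depth).
  var = mu + dispersion·mu², dispersion 0.1 (a typical cohort median);
  dispersion 0 degenerates to Poisson. Three Gaussian confounders load
  sparsely (30% of genes, N(0, 0.4) weights) and are exported as measurable
  covariates, mirroring RIN/batch-style axes.
- **Effects.** Defaults: 30% of genes carry a cis effect β_g = ±0.8 on an
  assigned variant inside the window; each phenotype variable has 20
  environmentally responsive genes at β_e = ±0.25; GxE effects β_gxe = ±0.4
  are placed on genes having both. The magnitudes are chosen for
  testability — they make recovery measurable at n = 250 — since no
  empirical GxE effect-size distribution exists to emulate; explicit
  per-gene (β_g, β_e, β_gxe) triples can be passed instead.
- **Longitudinal wave.** Wave-2 latents are wave-1 latents plus per-sample
  Gaussian drift (optionally restricted to chosen variables); genotypes are
  identical, expression and measurement noise are redrawn, and a
  configurable subset of samples returns.

One master seed; each stage draws from `default_rng([seed, stage_offset])`,
so stages are independently reproducible and identical configurations are
byte-identical after serialization.

What the generator does **not** emulate: LD between variants (each variant
is drawn independently, so lead-variant identification is easier than in
real data), population structure and relatedness, count outliers and
batch-by-gene interactions, non-Gaussian phenotype distributions, and
informative missingness. Passing recovery tests therefore demonstrates the
estimators' correctness and calibration under the assumed model, not
robustness to those real-data pathologies.

## Problem sizes and runtime

The test suite and the acceptance script run the statistical experiments at
the cohort scale the methods target (n = 250; 1,000–2,000 genes; pooled
nulls of 10⁵–10⁶), with permutation depths of 10⁴ where a single gene's
null is examined. The end-to-end pipeline run in the acceptance script uses
800 genes and 2,500 variants with a 10⁵-value pooled null per signature —
large enough that every stage's statistics are in their asymptotic regime
while keeping a complete run in minutes on one core. Pooled nulls of 10⁸
(as a production run would use) change only the resolution floor of the
corrected p-values, (1 + n_null)⁻¹.

## Known limitations

- Nominal eQTL tests use df = n − 2 without correcting for the residual
  degrees of freedom consumed upstream; permutation corrections absorb the
  resulting (small) miscalibration.
- The beta approximation assumes the permutation minima are well described
  by a two-parameter Beta; with very few effective tests per gene and
  adaptive early stopping the MLE sees as few as 1,000 minima.
- The elastic-net CV r² of null phenotypes has the heavy right tail
  discussed above; selection at r² ≥ 0.01 is a screen, not a test.
- The interaction model assumes homoskedastic Gaussian residuals on the
  log2-CPM scale; strongly dispersed low-count genes violate this, which is
  why calibration is verified on NB-generated counts.
- The CLI pipeline is single-threaded by design; `--threads` is accepted
  for interface stability but not yet used.
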