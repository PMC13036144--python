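# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `tobgs`.

## Mixed model and REML

All variance-component analyses use the linear mixed model

    y = X b + Σ_i u_i + e,   u_i ~ N(0, σ²_i G_i),   e ~ N(0, σ²_e I)

with intercept-only fixed effects by default (covariates are opt-in).
Estimation maximizes the restricted likelihood. Implementation:

* **Single genetic component.** The model is rotated into the
  eigenbasis of G, where the covariance is diagonal; the residual
  variance is profiled out analytically and the variance ratio
  θ = σ²_g/σ²_e is optimized by bounded Brent search on log θ over
  [−14, 14]. Because a derivative-free search is √eps-limited near the
  flat optimum, the solution is polished by analytic average-information
  (AI) Newton steps computed in the same eigenbasis (O(n) per step).
  The phenotype is internally standardized to unit variance and the
  estimates transformed back, which makes scale equivariance of the
  estimates exact rather than approximate.
* **Two or more components** (RHM windows, multi-kernel RKHS) use
  general AI-REML with step-halving and an EM fallback whenever an AI
  step would leave the parameter space. Convergence requires both
  max|Δσ²|/σ²_total < tol and |Δ log L| < tol (tol = 1e−6,
  max_iter = 100 by default; the multi-kernel fit uses 1e−5/300 because
  near-collinear kernels flatten the likelihood). Non-convergent fits
  are returned flagged, never silently dropped.
* Negative estimates are clamped to zero with a boundary flag (no
  reflection). Standard errors come from the inverse AI matrix at the
  optimum; the heritability SE uses the delta method on
  h² = σ²_g/(σ²_g+σ²_e).
* The likelihood-ratio test of a genetic component doubles the
  restricted log-likelihood gap and refers it to χ²₁. At the zero
  boundary the true null distribution is a 50:50 mixture of χ²₀ and
  χ²₁, so the plain-χ²₁ convention used here is conservative; the
  type-I-error test verifies this empirically.

GRMs are VanRaden method 1 (dosages centered by 2p_j, denominator
Σ 2p_j(1−p_j), in-sample allele frequencies); a per-marker-standardized
("GCTA-style") variant is available via `method="gcta"`. Missing
dosages must be imputed before GRM construction — a hard precondition
mirroring the impute-then-analyze order of the original pipeline.
Eigenvalues in (−1e−8, 0) are clamped to zero; more negative values are
an error. GRM PCA double-centers the matrix before eigendecomposition
and reports variance fractions over the non-negative spectrum.

## GWAS (MLMA)

Variance components are estimated once on the null (no-SNP) model and
held fixed across the scan — the standard population-parameters-
previously-determined approximation; per-SNP estimates would cost three
orders of magnitude more and the reference analysis reports none. Each
SNP is then a GLS fit under V̂ = σ̂²_g G + σ̂²_e I, vectorized across
markers in the GRM eigenbasis; p-values are Wald χ²₁. The candidate SNP
stays inside the background GRM (plain MLMA); leave-one-chromosome-out
is available but not default. The genome-wide threshold is the 1/N
convention (not 0.05/N). Per-SNP variance explained is
r² = β²·var(s)/var(y) from the mixed-model β; whether the original
per-SNP r² used this or simple regression is not documented, so the
choice is declared here.

## Regional heritability mapping

Windows are 2 Mb wide with a 500-kb step on the lattice 1 + k·step,
1-based inclusive, truncated at chromosome ends; the printed lead-
window convention (a truncated trailing window keeps its lattice start)
fixes this layout. Windows with fewer than `min_markers = 10` markers
are dropped with a logged count — no documented floor exists and
smaller windows are REML-unstable. Each window is fitted with its local
GRM plus a background GRM built from all *other* chromosomes (LOCO), so
local and background marker scopes are disjoint by construction and the
code enforces the scope tags rather than trusting callers. The
background GRM and the background-only null fit are computed once per
chromosome and cached. Because neighbouring windows overlap, local
variances are never summed into a "genome heritability"; summaries are
fractions of ΣVG1 only (ranked windows, cumulative top-k fractions,
per-chromosome contributions), and the lead window is reported with its
model-internal share VG1/(VG1+VG2). Window p-values are reported raw;
a Bonferroni-by-window-count threshold is trivial for callers to apply
and no canonical RHM threshold rule exists.

## Genomic prediction models

All twelve statistical models sit behind one `train`/`predict`
contract; hyperparameters are pinned in `GSConfig` rather than
inherited from package defaults, because defaults drift across
versions and reproducibility requires declared values.

* **rrBLUP / GBLUP.** rrBLUP estimates (σ²_u, σ²_e) by REML on the
  marker model and back-solves ridge marker effects through the n×n
  (Woodbury) system â = σ²_u Wᵀ V⁻¹ (y − μ̂); GBLUP fits the
  individual-level model on the VanRaden GRM and back-solves BLUPs,
  predicting new individuals through the cross-kinship
  W_new Wᵀ_train / Σ 2p(1−p). With the shared centering the two are
  algebraically identical; the tests assert agreement within 1e−6,
  and this identity is the package's central algebraic cross-check.
* **RR / LASSO / EN** run scikit-learn coordinate descent on markers
  standardized by (2p, √(2p(1−p))), with the penalty chosen by inner
  5-fold CV over a 50-point log-spaced path (EN mixing 0.5). A
  `fixed_penalty` override exists for limit checks.
* **Bayesian alphabet.** Single-site Gibbs samplers (numba-compiled)
  with defaults 12,000 iterations / 2,000 burn-in / thinning 5 and
  scaled-inverse-χ² priors, df 5, scales set by splitting var(y) half
  genetic / half residual (the per-marker prior scale divides the
  genetic half by the marker count, since markers are standardized).
  Bayes A draws a per-marker variance; Bayes B adds a fixed exclusion
  probability π = 0.95 (excluded markers redraw their variance from
  the prior to keep the chain proper); Bayes C shares one marker
  variance and samples its inclusion probability under a Beta(1, 9)
  prior; BRR is the common-variance ridge; BL is the Park–Casella
  Bayesian LASSO with inverse-Gaussian local scales and a vague
  Gamma(1.1, 0.1) prior on λ². Posterior-mean effects are the
  predictor; chains are bitwise reproducible under a fixed seed, and a
  non-finite residual variance aborts with the seed reported. The
  effective sample size of the σ²_e chain is recorded per fit.
* **RKHS / MKRKHS.** Gaussian kernel K = exp(−h·D²/median(D²)) on
  standardized genotypes with h = 1; the multi-kernel variant averages
  h ∈ {0.25, 1, 4}, one REML variance component per kernel. The
  bandwidths are declared package choices — no reference values exist.
  Prediction uses the cross-kernel to training individuals with the
  training median-D² scaling.

## Cross-validation and external validation

k-fold CV (default k = 5) draws one seeded permutation partition with
fold sizes differing by at most one (436 → 88+87·4); the same fold
assignment is shared by every model, and each sample is predicted
exactly once out-of-fold. Accuracy is reported both as the pooled
Pearson r over all out-of-fold predictions (headline) and as per-fold
mean ± spread: the underlying definition ("correlation across the five
folds") is ambiguous, and the pooled number is stable under a single
partition — though for aggressively sparse models (Bayes B) between-
fold intercept shifts can depress pooled r below the per-fold mean,
which is why both are shown. CV runs once by default with the seed
recorded. External validation predicts a held-out cohort with a model
trained on the full panel and reports Pearson r plus the per-sample
scatter table. The runtime/memory benchmark resamples individuals with
replacement to the requested sizes and is informational only —
hardware-dependent numbers are never asserted.

## Synthetic data generator

Genotypes follow a founder-haplotype mosaic: per chromosome,
`n_founder_haplotypes` (default 20) founder haplotypes are drawn from a
Beta(0.5, 0.5) allele-frequency spectrum truncated to the MAF floor,
and each gamete is a mosaic of founders with Poisson(recomb_rate)
crossovers. This produces block-wise LD whose length scale is
chromosome_length/(recomb_rate+1); the default panel (24 chromosomes ×
~210 markers, n = 436, m ≈ 5,000) is the desk-scale stand-in for the
full 95,308-SNP panel, whose size is reachable by config alone. Markers
whose realized MAF lands below the floor have their founder alleles
redrawn under the same mosaics, so the floor holds exactly. A
coalescent model was deliberately avoided: the mosaic is seedable,
fast, and yields GBS-like block LD, which is all the downstream
statistics consume.

Traits are strictly additive: QTLs are sampled uniformly among markers,
effects are N(0, 1) per allele (equal prior variance — the infinitesimal
architecture), then rescaled so that (a) in-window QTLs contribute
exactly `focal_fraction` of the frequency-weighted genetic variance and
(b) the realized genetic/phenotypic variance ratio equals `h2_target`
for the draw — the residual vector is centered, decorrelated from the
genetic values in-sample, and scaled to the exact residual variance, so
generative heritability is a calibrated condition rather than an
expectation. Default trait scale: mean 29.7, SD 9.0 mg/cigarette,
matching the published tar distribution (range ≈ 7.6–61.8). QC-testing
inputs come from `degrade_genotypes`, which masks calls at compound
per-site/per-individual rates and attaches Gamma-distributed (shape 4)
per-site mean depths; it does not inject genotype errors, so
concordance on degraded data tests matching/masking mechanics, not
caller accuracy.

What the generator does *not* emulate: selection, drift-driven
population structure beyond founder sharing, dominance/epistasis,
genotype-by-environment, linkage between chromosomes, or sequencing
error in retained calls. Passing tests therefore demonstrate correct
recovery under the stated additive model, not robustness to real-data
violations of it.

## Problem sizes used by the checks

The statistical test battery runs at sizes chosen to give each check
adequate power on a single CPU: heritability recovery uses 20
replicates of n = 500, m ≈ 5,000, 500 QTLs at generative h² = 0.70
(each estimate carries SE ≈ 0.07–0.08, so the mean of 20 resolves
±0.05); RHM enrichment recovery uses n = 400 on 2 chromosomes × 1,000
markers with `recomb_rate = 10`, i.e. LD blocks (~1 Mb) shorter than
the 2-Mb window — the regime the window width presumes; the
model-ordering benchmark uses n = 436, 6 chromosomes × 200 markers,
500 QTLs, a single 80/20 holdout per seed, and Gibbs chains shortened
to 1,500/300, which at these dimensions leaves posterior-mean rankings
unchanged while keeping the run in minutes. The analysis drivers use
3,000/600 chains for the same reason.

## QC semantics

Thresholds follow the literal reading of the filter description:
*mean depth greater than 2* and *MAF above 0.03* are strict (values
equal to the threshold are removed); *missing below 0.5* removes rates
≥ 0.5. Marker removal is attributed to the first failing rule in the
fixed order depth → MAF → site-missingness (no documented order exists;
a fixed order makes reports deterministic); individuals are filtered
after markers, and MAF is recomputed afterwards. MAF is always computed
from non-missing calls, before imputation. When depth metadata is
absent (plain GT-only VCF), the depth rule is skipped with a warning.
Mean imputation (fractional dosages allowed downstream) stands in for
haplotype-based imputation, which is out of scope.

## Known limitations

* Mean/mode imputation ignores LD; downstream accuracy on heavily
  masked data is accordingly pessimistic relative to haplotype
  imputation.
* The RHM LRT inherits the conservative boundary behaviour of the
  χ²₁ convention, and overlapping windows make neighbouring tests
  strongly dependent; ΣVG1 summaries are descriptive, not additive
  decompositions of heritability.
* Machine-learning regressors (SVM, RF, GBM, DNN) are outside the
  model zoo by design; the contract accommodates adapters but none are
  shipped or tested.
* Multi-kernel REML can report non-convergence on near-collinear
  kernels; fits remain usable and are flagged.
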