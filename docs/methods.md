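# Methods

## Problem setting

`macrovar` implements a genome-wide case-control association strategy for
sequencing data in which many variants are individually too rare to test.
Rare variants are aggregated *within genes* into a small number of
supervised components ("macrovariants"), and the phenotype is then
associated simultaneously with all common variants, isolated rare variants,
macrovariants, and environmental covariates by a sparse linear discriminant
analysis.  Analyses are repeated over many phenotype replicates (re-draws
of the phenotype on fixed genotypes) and summarised as the frequency with
which each variant or gene receives a nonzero estimated effect.

## Variant categories

With minor allele frequency (MAF) computed as `min(f, 1 - f)`,
`f = sum(dosage) / (2 * non-missing)`, each variant lands in exactly one
category:

| category | rule | design contribution |
|---|---|---|
| COMMON | MAF ≥ 0.05 | own column |
| ISOLATED_RARE | 0.005 ≤ MAF < 0.05, no rare gene-mate | own column |
| GROUPED_RARE | MAF < 0.05 in a gene with ≥ 2 rare variants | collapsed |
| EXCLUDED | monomorphic, undefined MAF, or isolated MAF < 0.005 | none |

Isolated variants below MAF 0.005 have no home in this scheme and are
excluded; grouped rare variants have no lower MAF bound because grouping is
defined by gene membership alone.  Monomorphic-in-sample variants are
dropped before categorisation (zero variance carries no information), and
zero-variance design columns are dropped with a logged warning.

Missing dosages are kept as NaN by the readers (so that file round-trips
are exact) and mean-imputed per variant once, at design assembly, before
centering.

## Supervised collapsing (PLS1)

For each gene with grouped rare variants, the member matrix `X_g` is
reduced by univariate-response partial least squares with NIPALS-style
deflation: component *c* uses the unit-norm weight vector proportional to
the deflated cross-covariance `X_d' r`, the score `t_c = X_d w_c`, deflation
of `X_d` by its projection on `t_c`, and a response-residual update by
regression on `t_c`.  Components maximise the covariance between genotype
and phenotype, so the collapse is supervised.  The sign of each weight
vector is fixed by making its largest-magnitude entry positive.

The number of components per gene is chosen by 5-fold cross-validation,
stratified by case/control status, minimising out-of-fold squared error on
the ±1-coded phenotype; candidate 0 is the intercept-only model, and ties
go to the smaller count.  A gene whose CV prefers 0 components contributes
nothing to the design — neither raw SNPs nor macrovariants.  The default
component cap is `min(5, gene size)`, keeping the reduction well below the
gene's dimension.

To avoid using the same data twice, the collapse is fitted on one phenotype
replicate and the association is run on the others (re-using the same fixed
genotypes, so macrovariant score columns are computed once).  Collapsing
and associating on the same replicate is possible only behind an explicit
flag and logs a warning, since it can magnify the type I error.

## Sparse LDA via penalized orthogonal components (POCRE)

The phenotype is coded `y_i = +1` (case) / `-1` (control) and regressed on
the centered design `X` by sequentially constructing mutually orthogonal
components.  At step *k*, with deflated matrix `X_d` and response residual
`r`:

1. score vector `v = X_d' r`; robust noise scale `s = MAD(v)/0.6745`
   (SD fallback when the MAD degenerates);
2. `gamma = postmed(v / s)` — the empirical Bayes posterior median under a
   spike-and-slab prior (below); if `gamma = 0`, stop;
3. loading `w_k = gamma / ||gamma||`, component `omega_k = X_d w_k`;
4. deflate `X_d` by its projection on `omega_k`; update `r` by its
   regression on `omega_k` (coefficient `q_k`).

Because `P'W` is unit upper triangular (`P` the deflation projections, `W`
the loadings), `beta = W (P'W)^{-1} q` reproduces the component-pathway
predictions exactly, and `support(beta)` is contained in the union of the
loading supports — the exact zeros of the thresholding rule survive
back-mapping.  Classification applies the LDA threshold `c = 0` to
`x'beta + intercept` with the intercept equal to the mean of the uncentered
±1 response; a score of exactly 0 is called control (deterministic,
conservative for case-calling).

Columns are standardised to unit variance inside the model (coefficients
are mapped back to the raw scale), so each component maximises
*correlation* with the response residual and the thresholded scores are
comparable across columns measured in different units — without this, a
covariate like Age (years, SD ≈ 17) dominates the shared noise-scale
standardisation and genotype columns can never reach the threshold.

For a univariate response the loading direction is obtained in a single
pass: the scaling of the response enters only through a sign, which the
sign-preserving thresholding rule resolves automatically, so no inner
iteration is needed.  Deflation is sequential (Gram–Schmidt style), which
is equivalent to a joint re-fit in exact arithmetic because the components
are orthogonal.

### Empirical Bayes thresholding

Each standardised score is modelled as `z ~ N(theta, 1)` with prior
`theta ~ (1 - w) delta_0 + w Laplace(a)` (slab density
`(a/2) exp(-a|theta|)`).  The estimate is the posterior median, computed
from the closed-form normal/Laplace convolution in log space; it is a
genuine thresholding rule (exactly zero below a threshold `t(w, a)`,
shrinkage by at most `a` noise units far from zero), antisymmetric and
monotone.  The heavy-tailed default `a = 0.5` follows standard empirical
Bayes thresholding practice.

The sparsity tuning parameter `lambda` in (0, 1) is defined as the prior
point mass at zero, so larger `lambda` means sparser fits; it is tuned on a
held-out test set over the grid 0.80, 0.81, …, 0.90 (11 candidates) by
misclassification rate, ties going to the smallest value.

By default the slab weight actually used at each component is estimated by
marginal maximum likelihood constrained to `[w_universal(p), 1 - lambda]`,
where `w_universal(p)` is the weight whose threshold equals the universal
threshold `sqrt(2 log p)` for `p` design columns.  `lambda` therefore acts
as a *floor* on sparsity while the data can demand more.  The rationale: a
fixed weight `w = 1 - lambda` in the 0.10–0.20 range puts the threshold
near 2.4–2.8 noise units, so with hundreds of null columns every component
would pick up several false loadings and a pure-noise response would
essentially never yield the empty model; the bounded-likelihood estimate
adapts the threshold to the apparent signal content and recovers the
expected null behaviour (`K = 0` for most pure-noise fits).  A fixed-weight
mode (`weight_mode="fixed"`) is retained for study of the raw rule.

### Reporting

A design column has a "nonzero estimated effect" when `beta_j != 0`
exactly (the thresholding rule produces exact zeros, so no epsilon is
involved).  Per replicate, each SNP column contributes its own indicator; a
gene is flagged when *any* of its macrovariant columns is nonzero.
Aggregated over replicates, per-SNP and per-gene/covariate frequencies are
`100 * count / n_replicates`, written as two TSVs sorted by frequency
descending with ties broken by name.  Covariates are listed with
chromosome NA.  No permutation p-values or multiple-testing corrections are
computed: the method's output is the raw detection frequency.

## Synthetic cohorts

Real mini-exome case-control data of this design (697 individuals, 200
phenotype replicates) are access-restricted, so the `synthetic_data` module
generates structurally matched cohorts:

* **Genotypes** — fixed across replicates; per variant, dosages are
  binomial(2, f) under Hardy–Weinberg, oriented to the realized minor
  allele.  Defaults: 150 common variants (MAF uniform on [0.05, 0.5]) and
  ~60 genes with 1 + Poisson(4) rare variants each (MAF log-uniform on
  [0.001, 0.05)).  Optional within-gene LD ties the alleles of a gene's
  variants to a shared per-haplotype Gaussian factor (a copula haplotype
  block); it is off by default and exercised in a dedicated test.
* **Phenotypes** — a liability threshold model: the latent risk is the sum
  of causal allele effects, covariate effects, and N(0, 1) noise redrawn
  per replicate; cases are the individuals above the per-replicate
  (1 − case fraction) liability quantile, with case fraction 0.3.  A
  liability model was chosen over a logistic one because it makes the case
  threshold explicit and matches the latent-risk spirit of the emulated
  data.
* **Covariates** — Age uniform on 20–80 years, Sex and Smoke Bernoulli,
  drawn once and constant across replicates.

The standard preset plants one common variant with MAF 0.067 and liability
effect 0.65 per allele, one with MAF 0.171 and effect 0.244, one causal
gene acting only through 8 rare variants (MAF 0.005–0.03, effect 1.0
each), and Age (0.03 per year) and Smoke (1.0) effects sized so the
covariates are detectable in nearly all replicates.  The zeroed copy of
the preset (all effects 0) provides the null-calibration condition.

What the generator does *not* emulate: pedigree structure, realistic LD
beyond the optional within-gene block, genotyping error, population
stratification, and the full 24k-variant exome scale.  Passing tests
demonstrate calibration and power under Hardy–Weinberg-clean, unconfounded
conditions; real cohorts can behave worse in all of these respects.

## Problem sizes and numerical choices

* Calibration/power runs in the tests and the acceptance script use the
  697-individual preset with ~430 variants and 50 association replicates
  (one further replicate drives the collapse) — sizes chosen so the whole
  suite completes in a couple of minutes while keeping every pathway of the
  method active.
* POCRE component cap `min(n - 1, 30)`; zero/convergence tolerance 1e-10;
  training-score orthogonality holds to 1e-8 relative and back-mapped
  predictions to 1e-10 relative.
* Train/test split for lambda selection: 50/50, stratified by case status,
  seeded per replicate; CV folds for collapse sizing: 5.
* Degenerate inputs: all-missing variants carry undefined MAF and are
  excluded; constant (or numerically constant) columns are zeroed and
  dropped from consideration; a replicate whose stratified split leaves a
  single class in either half is an error.
* All randomness (simulation, fold assignment, splits) flows from explicit
  integer seeds; identical inputs and seeds give byte-identical reports.

## Known limitations

* The single-pass loading construction is specific to a univariate
  response; no multivariate-response mode is provided.
* Detection frequencies have no attached significance measure; they should
  be read as stability-selection-style evidence, not p-values.
* With fixed genotypes across replicates, a null variant that happens to
  correlate with the cohort's fixed risk profile is repeatedly
  near-threshold, so null frequencies are heavier-tailed than independent
  binomials — visible in the synthetic power runs and inherent to the
  replicate design.
* Genes whose CV chooses 0 components vanish from the analysis entirely;
  no burden-indicator fallback is attempted.
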