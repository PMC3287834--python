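# macrovar

Case-control genome-wide association with **collapsed rare variants**:
rare variants within each gene are aggregated into a few supervised
"macrovariants" by partial least squares (PLS), and the binary phenotype is
then associated *simultaneously* with all common variants, isolated rare
variants, macrovariants, and environmental covariates through a sparse
linear discriminant analysis implemented by penalized orthogonal-components
regression (POCRE) with empirical Bayes thresholding.  Repeating the
analysis across phenotype replicates yields, for every SNP and gene, the
frequency of a nonzero estimated effect — a stability-style evidence score
for association.

The package is aimed at statistical geneticists working with sequencing
case-control data (or simulated workshop-style cohorts of fixed genotypes
and replicated phenotypes) who want gene-level rare-variant signals and
SNP-level common-variant signals from a single joint model.

## The model

Within each gene, the rare-variant genotypes `X_1 … X_k` are collapsed by
PLS1 components that maximise covariance with the phenotype; the number of
components per gene is chosen by stratified 5-fold cross-validation (0
components ⇒ the gene drops out).  For the association, with `y_i = +1`
for cases and `−1` for controls and a centered design `X`, POCRE builds
orthogonal components `ω_k = X_d w_k` sequentially, where

```
w_k ∝ postmed( X_d' r / s ),
```

`r` is the current response residual, `s` a robust noise scale, and
`postmed` the posterior median under a spike-and-slab prior
`θ ~ (1−λ)-weighted Laplace slab + λ point mass at 0` — an exact-zero
thresholding rule.  Back-mapping through the deflation sequence gives a
sparse coefficient vector `β`; classification is `sign(x'β + intercept)`
with LDA threshold `c = 0`.  The sparsity parameter λ is tuned on a
held-out split over the grid 0.80:0.01:0.90.  A variant (or a gene, via
*any* of its macrovariants) is "detected" in a replicate when its `β`
entry is exactly nonzero.

## Worked example

```python
import macrovar as mv
from macrovar.synthetic_data import gaw17_like_preset, simulate_cohort

cfg = gaw17_like_preset(n_replicates=11, seed=1)   # 697 individuals
gm, gene_map, phen = simulate_cohort(cfg)

plan = mv.ReplicatePlan(collapse_replicate=1,
                        association_replicates=list(range(2, 12)), seed=7)
report, details = mv.run_all(gm, gene_map, phen, plan)
print(report.snp_table.nlargest(3, "frequency_pct").to_string(index=False))
print(details[0]["results"].summary(top=6))
```

prints (abridged):

```
      snp gene chromosome  frequency_pct
CV_STRONG              20           40.0
  C6S0006               6           10.0
  C1S0023               1           10.0

POCRE-LDA Results
====================================================
n individuals:     348
design columns:    178
lambda:            0.8
components:        1
nonzero effects:   4
intercept:         -0.402299
----------------------------------------------------
column                                  beta
G_RARE_CAUSAL::mv1                   0.99456
smoke                               0.609224
CV_STRONG                           0.533509
age                                0.0190718
====================================================
```

`CV_STRONG` is the planted common causal variant (MAF ≈ 0.067, liability
effect 0.65): it is detected in 40% of the ten analysed replicates and
tops the SNP table, while null SNPs sit at ≤10%.  The per-replicate
summary shows the fitted classifier: the rare-variant-only causal gene
enters through its first macrovariant, the Smoke and Age covariates are
picked up, and everything else is thresholded to exactly zero.  The
companion gene table reports Age/Smoke at 100% and the rare causal gene at
100% via its macrovariants.

The same workflow is available from the shell:

```
macrovar simulate --out-dir sim --seed 1 --n-replicates 11
macrovar run-all --ped sim/genotypes.ped --map sim/genotypes.map \
    --gene-map sim/gene_map.tsv --phenotypes sim/phenotypes.tsv \
    --seed 7 --out-prefix results/study
```

which writes `results/study.snps.tsv` and `results/study.genes.tsv`
(frequency-sorted, as above) plus a small JSON of per-replicate metadata.

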