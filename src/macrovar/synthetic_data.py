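"""Mini-exome-style synthetic cohorts for exercising the full pipeline.

Generates a fixed genotype matrix — common variants plus gene-clustered rare
variants under Hardy-Weinberg sampling, with optional within-gene LD — and
any number of binary-phenotype replicates from a liability-threshold model:
a latent risk score sums causal allele effects and Age/Sex/Smoke covariate
effects plus Gaussian noise redrawn per replicate, and an individual is a
case when the score exceeds the cohort quantile implied by the case
fraction.  Genotypes and covariates are held fixed across replicates; only
the liability noise is redrawn.

The default cohort mirrors the structure of the workshop mini-exome data
this design emulates: 697 individuals, 200 phenotype replicates, a common
causal variant with MAF ~0.067 and additive effect ~0.65, a second with MAF
~0.171 and effect ~0.244, and one causal gene acting only through several
rare variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass
class CausalVariant:
    variant_id: str
    effect: float  # additive liability effect per minor-allele copy


@dataclass
class SimulationConfig:
    """Generating model for a synthetic cohort.

    MAFs are allele frequencies in (0, 0.5]; effects are on the liability
    scale (per minor-allele copy); ``age_effect`` is per year.  The case
    threshold is the per-replicate (1 - case_fraction) liability quantile.
    """

    n_individuals: int = 697
    n_replicates: int = 200
    seed: int = 0
    # genotype structure
    n_common: int = 150
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 60
    mean_variants_per_gene: float = 5.0
    rare_maf_range: tuple[float, float] = (0.001, 0.05)
    ld_rho: float = 0.0  # within-gene haplotype-factor correlation
    # causal architecture
    causal_common: list[CausalVariant] = field(default_factory=list)
    causal_rare_gene: str = ""
    causal_rare_effect: float = 0.0
    # covariates and noise
    age_effect: float = 0.0
    sex_effect: float = 0.0
    smoke_effect: float = 0.0
    liability_noise_sd: float = 1.0
    case_fraction: float = 0.3

    def __post_init__(self) -> None:
        for lo, hi in (self.common_maf_range, self.rare_maf_range):
            if not (0.0 < lo < hi <= 0.5):
                raise ValueError("MAF ranges must satisfy 0 < lo < hi <= 0.5")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.liability_noise_sd <= 0:
            raise ValueError("liability_noise_sd must be positive")
        for cv in self.causal_common:
            if not np.isfinite(cv.effect):
                raise ValueError("effect sizes must be finite")

    def zeroed(self) -> "SimulationConfig":
        """Null copy: every genetic and covariate effect set to zero."""
        return replace(
            self,
            causal_common=[],
            causal_rare_gene="",
            causal_rare_effect=0.0,
            age_effect=0.0,
            sex_effect=0.0,
            smoke_effect=0.0,
        )


def gaw17_like_preset(
    n_replicates: int = 200, seed: int = 0, ld_rho: float = 0.0
) -> SimulationConfig:
    """Cohort preset with the two common causal profiles, a rare-variant-only
    causal gene, and strong Age/Smoke effects.

    The covariate effects are sized so Age and Smoke are detectable in
    nearly all replicates; the strong common variant (MAF 0.067, effect
    0.65) is the leading single-SNP signal and the causal gene is reachable
    only through collapsed rare variants.
    """
    return SimulationConfig(
        n_individuals=697,
        n_replicates=n_replicates,
        seed=seed,
        ld_rho=ld_rho,
        causal_common=[
            CausalVariant("CV_STRONG", 0.65),  # MAF 0.067 assigned below
            CausalVariant("CV_MODERATE", 0.244),  # MAF 0.171
        ],
        causal_rare_gene="G_RARE_CAUSAL",
        causal_rare_effect=1.0,
        age_effect=0.03,
        sex_effect=0.0,
        smoke_effect=1.0,
        liability_noise_sd=1.0,
        case_fraction=0.3,
    )


_CAUSAL_COMMON_MAF = {"CV_STRONG": 0.067, "CV_MODERATE": 0.171}
_N_CAUSAL_RARE = 8


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, dict[str, str], pd.DataFrame]:
    """Draw the fixed genotype matrix, gene map, and covariate table.

    Dosages are binomial(2, f) per variant under Hardy-Weinberg; when
    ``ld_rho > 0`` the alleles of a gene's variants share a per-haplotype
    latent Gaussian factor (a Gaussian-copula haplotype block).  Covariates
    (Age uniform 20-80, Sex/Smoke Bernoulli) are drawn once and shared by
    all replicates.
    """
    rng = np.random.default_rng([config.seed, 17])
    n = config.n_individuals

    ids, freqs, chroms, genes_of = [], [], [], []
    gene_map: dict[str, str] = {}

    for j in range(config.n_common):
        vid = f"C{j % 22 + 1}S{j + 1:04d}"
        ids.append(vid)
        chroms.append(str(j % 22 + 1))
        freqs.append(rng.uniform(*config.common_maf_range))
        genes_of.append("")
    for name, maf in _CAUSAL_COMMON_MAF.items():
        if any(cv.variant_id == name for cv in config.causal_common):
            ids.append(name)
            chroms.append(str(len(ids) % 22 + 1))
            freqs.append(maf)
            genes_of.append("")

    gene_sizes = 1 + rng.poisson(config.mean_variants_per_gene - 1, config.n_genes)
    lo, hi = config.rare_maf_range
    counter = 0
    gene_names = [f"G{g + 1:03d}" for g in range(config.n_genes)]
    if config.causal_rare_gene:
        gene_names[0] = config.causal_rare_gene
        gene_sizes[0] = _N_CAUSAL_RARE
    causal_rare_ids: list[str] = []
    for g, gene in enumerate(gene_names):
        chrom = str(g % 22 + 1)
        for _ in range(gene_sizes[g]):
            counter += 1
            vid = f"R{chrom}S{counter:04d}"
            ids.append(vid)
            chroms.append(chrom)
            if gene == config.causal_rare_gene:
                freqs.append(np.exp(rng.uniform(np.log(0.005), np.log(0.03))))
                causal_rare_ids.append(vid)
            else:
                freqs.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            genes_of.append(gene)
            gene_map[vid] = gene

    freqs = np.asarray(freqs)
    m = len(ids)
    dosages = np.empty((n, m))
    gene_arr = np.asarray(genes_of)
    if config.ld_rho > 0.0:
        from scipy.stats import norm as _norm

        rho = config.ld_rho
        for gene in [""] + gene_names:
            cols = np.where(gene_arr == gene)[0]
            if cols.size == 0:
                continue
            if gene == "":
                for j in cols:
                    dosages[:, j] = rng.binomial(2, freqs[j], size=n)
                continue
            cut = _norm.ppf(freqs[cols])
            for hap in range(2):
                u = rng.standard_normal(n)
                eps = rng.standard_normal((n, cols.size))
                z = rho * u[:, None] + np.sqrt(1 - rho**2) * eps
                allele = (z < cut[None, :]).astype(float)
                if hap == 0:
                    dosages[:, cols] = allele
                else:
                    dosages[:, cols] += allele
    else:
        dosages[:] = rng.binomial(2, freqs[None, :], size=(n, m))

    # orient each column to the realized minor allele
    flip = dosages.mean(axis=0) > 1.0
    dosages[:, flip] = 2.0 - dosages[:, flip]
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chroms,
            "position": np.arange(1, m + 1) * 1000,
            "allele_minor": np.where(flip, "G", "A"),
            "allele_major": np.where(flip, "A", "G"),
            "gene": genes_of,
            "flipped": False,
            "assigned_maf": freqs,
        }
    )
    monomorphic = dosages.std(axis=0) == 0.0
    variants["monomorphic"] = monomorphic
    individual_ids = [f"IND{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(dosages, variants, individual_ids)

    covariates = pd.DataFrame(
        {
            "individual_id": individual_ids,
            "age": rng.integers(20, 81, size=n),
            "sex": rng.integers(0, 2, size=n),
            "smoke": rng.binomial(1, 0.3, size=n),
        }
    )
    return gm, gene_map, covariates


def _liability_fixed_part(
    gm: GenotypeMatrix, covariates: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Genetic + covariate liability contribution (identical across replicates)."""
    col_of = {v: j for j, v in enumerate(gm.variants["variant_id"])}
    L = np.zeros(gm.n_individuals)
    for cv in config.causal_common:
        L += cv.effect * gm.dosages[:, col_of[cv.variant_id]]
    if config.causal_rare_gene:
        members = [
            v
            for v, g in zip(gm.variants["variant_id"], gm.variants["gene"])
            if g == config.causal_rare_gene
        ]
        for v in members:
            L += config.causal_rare_effect * gm.dosages[:, col_of[v]]
    L += config.age_effect * covariates["age"].to_numpy(dtype=float)
    L += config.sex_effect * covariates["sex"].to_numpy(dtype=float)
    L += config.smoke_effect * covariates["smoke"].to_numpy(dtype=float)
    return L


def simulate_phenotypes(
    gm: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    replicate_index: int,
) -> pd.DataFrame:
    """One phenotype replicate (rows of the phenotype table).

    The liability adds replicate-specific Gaussian noise to the fixed
    genetic/covariate part; cases are the individuals above the
    (1 - case_fraction) liability quantile.  Deterministic in
    (config.seed, replicate_index).
    """
    if replicate_index < 1 or replicate_index > config.n_replicates:
        raise ValueError("replicate_index out of range")
    rng = np.random.default_rng([config.seed, 1000 + replicate_index])
    L = _liability_fixed_part(gm, covariates, config)
    L = L + rng.normal(0.0, config.liability_noise_sd, size=gm.n_individuals)
    threshold = np.quantile(L, 1.0 - config.case_fraction)
    affected = (L > threshold).astype(int)
    if affected.sum() in (0, len(affected)):
        raise ValueError("case_fraction produced a single-class replicate")
    return pd.DataFrame(
        {
            "individual_id": covariates["individual_id"],
            "replicate": replicate_index,
            "affected": affected,
            "age": covariates["age"],
            "sex": covariates["sex"],
            "smoke": covariates["smoke"],
        }
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, dict[str, str], pd.DataFrame]:
    """Genotypes, gene map, and the stacked phenotype table of all replicates."""
    gm, gene_map, covariates = simulate_genotypes(config)
    phen = pd.concat(
        [
            simulate_phenotypes(gm, covariates, config, r)
            for r in range(1, config.n_replicates + 1)
        ],
        ignore_index=True,
    )
    return gm, gene_map, phen
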