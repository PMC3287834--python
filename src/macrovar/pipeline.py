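"""Orchestration of the replicate-based association study.

One phenotype replicate is used to collapse each gene's rare variants into
macrovariants (supervised PLS, CV-sized); the remaining replicates are each
analysed by POCRE-LDA on a design of covariates + common SNPs + isolated
rare SNPs + macrovariant scores, with the sparsity parameter tuned on a
held-out half of the individuals.  Nonzero estimated effects are aggregated
across replicates into per-SNP and per-gene detection frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .pls_collapse import MacroVariant, build_gene_models, score_macrovariants
from .pocre import DEFAULT_LAMBDA_GRID, PocreLDA
from .preprocess import (
    DesignMatrix,
    VariantCategory,
    center_columns,
    classify_variants,
    compute_maf,
    drop_zero_variance,
)

logger = logging.getLogger(__name__)

COVARIATE_ORDER = ("age", "sex", "smoke")


@dataclass
class ReplicatePlan:
    """Which replicate collapses rare variants and which are associated."""

    collapse_replicate: int
    association_replicates: list[int]
    train_fraction: float = 0.5
    seed: int = 0
    allow_same_replicate: bool = False

    def __post_init__(self) -> None:
        if (
            self.collapse_replicate in self.association_replicates
            and not self.allow_same_replicate
        ):
            raise ValueError(
                "collapse replicate reused for association; this reuses the "
                "same data twice and may magnify the type I error — set "
                "allow_same_replicate=True to proceed deliberately"
            )
        if self.collapse_replicate in self.association_replicates:
            logger.warning(
                "collapse replicate %d also analysed for association; "
                "same-data-twice mode can magnify the type I error",
                self.collapse_replicate,
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class AssociationReport:
    """Nonzero-effect counts/frequencies aggregated over replicates."""

    snp_table: pd.DataFrame  # snp, gene, chromosome, count, frequency_pct
    gene_table: pd.DataFrame  # name, chromosome, count, frequency_pct
    n_replicates: int

    def write(self, snp_path, gene_path) -> None:
        from .io_formats import write_report

        write_report(self, snp_path, gene_path)

    def plot_top(self, k: int = 15, ax=None):
        """Horizontal bar chart of the k most frequently detected SNPs."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * k + 1))
        top = self.snp_table.nlargest(k, "frequency_pct", keep="first")
        ax.barh(top["snp"][::-1], top["frequency_pct"][::-1])
        ax.set_xlabel("nonzero-effect frequency (%)")
        ax.set_title(f"top SNPs over {self.n_replicates} replicates")
        return ax


def assemble_design(
    genotypes: GenotypeMatrix,
    categories: pd.Series,
    macrovariants: list[MacroVariant],
    covariates: pd.DataFrame,
) -> DesignMatrix:
    """Column-assemble covariates, retained SNPs, and macrovariant scores.

    Column order is covariates (Age, Sex, Smoke), COMMON SNPs,
    ISOLATED_RARE SNPs, then macrovariants grouped by gene; every column is
    centered and zero-variance columns are dropped with a warning.
    """
    cov_ids = list(covariates["individual_id"])
    if cov_ids != list(genotypes.individual_ids):
        raise ValueError("covariate rows do not match genotype individuals")

    dos = genotypes.imputed_dosages()
    vids = list(genotypes.variants["variant_id"])
    chrom_of = dict(zip(vids, genotypes.variants["chromosome"]))
    gene_of = dict(zip(vids, genotypes.variants["gene"]))
    col_of = {v: j for j, v in enumerate(vids)}

    blocks, meta = [], []
    for cov in COVARIATE_ORDER:
        blocks.append(covariates[cov].to_numpy(dtype=float))
        meta.append((cov, "covariate", "", "", 0, "NA"))
    for cat, kind in (
        (VariantCategory.COMMON, "common"),
        (VariantCategory.ISOLATED_RARE, "isolated_rare"),
    ):
        for v in vids:
            if categories[v] is cat:
                blocks.append(dos[:, col_of[v]])
                meta.append((v, kind, v, gene_of[v], 0, chrom_of[v]))
    for mv in macrovariants:
        blocks.append(mv.scores)
        meta.append(
            (
                f"{mv.gene}::mv{mv.component_index}",
                "macrovariant",
                "",
                mv.gene,
                mv.component_index,
                "NA",
            )
        )

    columns = pd.DataFrame(
        meta, columns=["name", "kind", "variant_id", "gene", "component", "chromosome"]
    )
    values = np.column_stack(blocks) if blocks else np.empty((len(cov_ids), 0))
    design = DesignMatrix(values, columns, list(genotypes.individual_ids))
    return drop_zero_variance(center_columns(design))


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train = np.zeros(len(y), dtype=bool)
    for cls in (-1.0, 1.0):
        idx = rng.permutation(np.where(y == cls)[0])
        n_tr = int(round(train_fraction * len(idx)))
        train[idx[:n_tr]] = True
    return train, ~train


def run_replicate(
    y: np.ndarray,
    design: DesignMatrix,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    train_fraction: float = 0.5,
    seed: int = 0,
    max_comp: int | None = None,
) -> dict:
    """Tune lambda on a held-out split and return the nonzero-effect mask.

    ``y`` is the replicate's phenotype in +/-1 (or 0/1) coding.  The split
    is a seeded stratified partition; a split that leaves a single class in
    either half is an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) <= {0.0, 1.0}:
        y = 2.0 * y - 1.0
    rng = np.random.default_rng(seed)
    train, test = _stratified_split(y, train_fraction, rng)
    for part, label in ((train, "train"), (test, "test")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"degenerate split: single class in {label} set")
    model = PocreLDA(
        y[train], design.values[train], column_names=design.names
    )
    res = model.fit_select_lambda(
        y[test], design.values[test], grid=lambda_grid, max_comp=max_comp
    )
    return {
        "nonzero": res.nonzero_mask,
        "lambda": res.lambda_,
        "n_components": res.n_components,
        "test_error": min(e for _, e, _, _ in res.lambda_path),
        "results": res,
    }


def aggregate(
    indicators: list[np.ndarray], columns: pd.DataFrame
) -> AssociationReport:
    """Count nonzero-effect indicators per design column across replicates.

    SNP columns are reported individually; a gene counts as detected in a
    replicate when *any* of its macrovariant columns is nonzero; covariates
    are reported alongside genes with chromosome NA.
    """
    if not indicators:
        raise ValueError("need at least one replicate indicator")
    p = len(columns)
    for ind in indicators:
        if len(ind) != p:
            raise ValueError("indicator length does not match design columns")
    R = len(indicators)
    stack = np.vstack([np.asarray(i, dtype=bool) for i in indicators])
    counts = stack.sum(axis=0)

    snp_rows, gene_rows = [], []
    kinds = columns["kind"].to_numpy()
    for j, row in columns.iterrows():
        freq = 100.0 * counts[j] / R
        if row["kind"] in ("common", "isolated_rare"):
            snp_rows.append(
                (row["variant_id"], row["gene"], row["chromosome"], int(counts[j]), freq)
            )
        elif row["kind"] == "covariate":
            gene_rows.append((row["name"].capitalize(), "NA", int(counts[j]), freq))

    mv_cols = columns.index[kinds == "macrovariant"]
    for gene in sorted(columns.loc[mv_cols, "gene"].unique()):
        member_idx = [j for j in mv_cols if columns.loc[j, "gene"] == gene]
        any_hit = stack[:, member_idx].any(axis=1)
        chrom = columns.loc[member_idx[0], "chromosome"]
        gene_rows.append((gene, chrom, int(any_hit.sum()), 100.0 * any_hit.sum() / R))

    snp_table = pd.DataFrame(
        snp_rows, columns=["snp", "gene", "chromosome", "count", "frequency_pct"]
    )
    gene_table = pd.DataFrame(
        gene_rows, columns=["name", "chromosome", "count", "frequency_pct"]
    )
    return AssociationReport(snp_table, gene_table, R)


def run_all(
    genotypes: GenotypeMatrix,
    gene_map: dict[str, str],
    phenotypes: pd.DataFrame,
    plan: ReplicatePlan,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    common_threshold: float = 0.05,
    isolated_min: float = 0.005,
    cv_folds: int = 5,
    max_pls_comp: int | None = None,
    max_comp: int | None = None,
) -> tuple[AssociationReport, list[dict]]:
    """Full analysis: classify variants, collapse, associate, aggregate."""
    genotypes.attach_gene_map(gene_map)
    maf = compute_maf(genotypes)
    vids = list(genotypes.variants["variant_id"])
    categories, groups = classify_variants(
        maf, vids, gene_map, common_threshold, isolated_min
    )
    # assign each grouped gene the chromosome of its first member
    chrom_of = dict(zip(vids, genotypes.variants["chromosome"]))

    dos = genotypes.imputed_dosages()
    collapse_phen = phenotypes[phenotypes["replicate"] == plan.collapse_replicate]
    if collapse_phen.empty:
        raise ValueError(f"collapse replicate {plan.collapse_replicate} absent")
    collapse_phen = collapse_phen.set_index("individual_id").loc[
        genotypes.individual_ids
    ]
    y_collapse = 2.0 * collapse_phen["affected"].to_numpy(dtype=float) - 1.0
    gene_models = build_gene_models(
        y_collapse, dos, vids, groups,
        max_comp=max_pls_comp, folds=cv_folds, seed=plan.seed,
    )
    logger.info(
        "collapsed %d genes; %d yield macrovariants",
        len(gene_models),
        sum(m.n_components > 0 for m in gene_models.values()),
    )

    col_of = {v: j for j, v in enumerate(vids)}
    macrovariants: list[MacroVariant] = []
    for gene in sorted(gene_models):
        model = gene_models[gene]
        if model.n_components == 0:
            continue
        Xg = dos[:, [col_of[v] for v in model.member_variants]]
        for mv in score_macrovariants(model, Xg):
            macrovariants.append(mv)

    covariates = collapse_phen.reset_index()[
        ["individual_id", "age", "sex", "smoke"]
    ]
    design = assemble_design(genotypes, categories, macrovariants, covariates)
    # macrovariant gene chromosomes (design stores NA placeholders)
    for j, row in design.columns.iterrows():
        if row["kind"] == "macrovariant":
            members = groups[row["gene"]]
            design.columns.loc[j, "chromosome"] = chrom_of[members[0]]

    details = []
    indicators = []
    ss = np.random.SeedSequence([plan.seed, 2025])
    rep_seeds = ss.generate_state(max(plan.association_replicates) + 1)
    for rep in plan.association_replicates:
        rp = phenotypes[phenotypes["replicate"] == rep]
        if rp.empty:
            raise ValueError(f"association replicate {rep} absent")
        rp = rp.set_index("individual_id").loc[genotypes.individual_ids]
        y = rp["affected"].to_numpy(dtype=float)
        out = run_replicate(
            y,
            design,
            lambda_grid=lambda_grid,
            train_fraction=plan.train_fraction,
            seed=int(rep_seeds[rep] % (2**31)),
            max_comp=max_comp,
        )
        out["replicate"] = rep
        indicators.append(out["nonzero"])
        details.append(out)
        logger.info(
            "replicate %d: lambda=%.2f K=%d support=%d test_err=%.3f",
            rep, out["lambda"], out["n_components"],
            int(out["nonzero"].sum()), out["test_error"],
        )

    report = aggregate(indicators, design.columns)
    return report, details
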