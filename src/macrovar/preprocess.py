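"""Minor-allele frequencies, variant categories, and design-matrix centering.

Variants are partitioned into four categories before association:

* ``COMMON`` — MAF >= 0.05; enters the design as its own column.
* ``ISOLATED_RARE`` — 0.005 <= MAF < 0.05 and no other rare variant in the
  same gene; enters as its own column.
* ``GROUPED_RARE`` — MAF < 0.05 in a gene holding at least two rare
  variants; these are collapsed into per-gene macrovariants.
* ``EXCLUDED`` — monomorphic / undefined-MAF variants, and isolated
  variants with MAF < 0.005, which have no home in the scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

COMMON_MAF_THRESHOLD = 0.05
ISOLATED_RARE_MIN_MAF = 0.005


class VariantCategory(str, Enum):
    COMMON = "COMMON"
    ISOLATED_RARE = "ISOLATED_RARE"
    GROUPED_RARE = "GROUPED_RARE"
    EXCLUDED = "EXCLUDED"


def compute_maf(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency, NaN where all dosages are missing.

    MAF = min(f, 1 - f) with f = sum(dosage) / (2 * non-missing count); the
    result lies in [0, 0.5].
    """
    d = genotypes.dosages
    nonmiss = np.sum(~np.isnan(d), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(d, axis=0) / (2.0 * nonmiss)
    f = np.where(nonmiss == 0, np.nan, f)
    return np.minimum(f, 1.0 - f)


def classify_variants(
    maf: np.ndarray,
    variant_ids: list[str],
    gene_map: dict[str, str],
    common_threshold: float = COMMON_MAF_THRESHOLD,
    isolated_min: float = ISOLATED_RARE_MIN_MAF,
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Assign each variant a :class:`VariantCategory` and group rare variants.

    Returns the per-variant category (indexed by variant_id) and, for every
    gene with at least two rare variants, the ordered list of its grouped
    members.  Monomorphic (MAF 0) and undefined-MAF variants are excluded
    before categorisation.
    """
    maf = np.asarray(maf, dtype=float)
    cats = {}
    rare_by_gene: dict[str, list[str]] = {}
    for vid, m in zip(variant_ids, maf):
        if np.isnan(m) or m == 0.0:
            cats[vid] = VariantCategory.EXCLUDED
            continue
        if m >= common_threshold:
            cats[vid] = VariantCategory.COMMON
            continue
        gene = gene_map.get(vid, "")
        if gene:
            rare_by_gene.setdefault(gene, []).append(vid)
        cats[vid] = None  # rare; resolved below

    groups = {g: vids for g, vids in rare_by_gene.items() if len(vids) >= 2}
    maf_by_id = dict(zip(variant_ids, maf))
    for vid, cat in cats.items():
        if cat is not None:
            continue
        gene = gene_map.get(vid, "")
        if gene in groups:
            cats[vid] = VariantCategory.GROUPED_RARE
        elif isolated_min <= maf_by_id[vid] < common_threshold:
            cats[vid] = VariantCategory.ISOLATED_RARE
        else:
            cats[vid] = VariantCategory.EXCLUDED
    series = pd.Series([cats[v] for v in variant_ids], index=variant_ids)
    return series, groups


@dataclass
class DesignMatrix:
    """Centered covariate + SNP + macrovariant design with column provenance.

    ``columns`` carries one row per design column with fields ``name``,
    ``kind`` (covariate / common / isolated_rare / macrovariant),
    ``variant_id``, ``gene``, ``component`` and ``chromosome``.
    """

    values: np.ndarray
    columns: pd.DataFrame
    individual_ids: list[str]
    column_means: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individual_ids), len(self.columns)):
            raise ValueError("design shape does not match metadata")
        if self.column_means is None:
            self.column_means = np.zeros(self.values.shape[1])

    @property
    def names(self) -> list[str]:
        return list(self.columns["name"])


def center_columns(design: DesignMatrix) -> DesignMatrix:
    """Center every column at 0, storing the means for later scoring.

    Idempotent; zero-variance columns are flagged in ``columns['zero_variance']``.
    """
    means = self_means = design.values.mean(axis=0)
    centered = design.values - means
    cols = design.columns.copy()
    cols["zero_variance"] = centered.std(axis=0) == 0.0
    return DesignMatrix(
        centered,
        cols,
        design.individual_ids,
        column_means=design.column_means + self_means,
    )


def drop_zero_variance(design: DesignMatrix) -> DesignMatrix:
    """Drop constant columns (they carry no association information)."""
    if "zero_variance" not in design.columns:
        design = center_columns(design)
    keep = ~design.columns["zero_variance"].to_numpy()
    if not keep.all():
        dropped = [n for n, k in zip(design.names, keep) if not k]
        logger.warning("dropping %d zero-variance column(s): %s", len(dropped), dropped)
    return DesignMatrix(
        design.values[:, keep],
        design.columns.loc[keep].reset_index(drop=True),
        design.individual_ids,
        column_means=design.column_means[keep],
    )
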