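"""Readers and writers for genotype, gene-map, phenotype and report files.

Genotypes are held as an individuals x variants additive dosage matrix in
which each entry counts copies of the minor allele (0, 1, 2, or NaN for
missing).  Supported on-disk formats are the whitespace-separated PLINK text
dialect (.ped/.map) and VCF with a GT field; gene maps and phenotype tables
are headered TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.nan


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class GenotypeMatrix:
    """Additive minor-allele dosages with per-variant metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_individuals, n_variants)
        Minor-allele counts in {0, 1, 2}; NaN marks a missing genotype.
    variants : DataFrame
        One row per variant with columns ``variant_id``, ``chromosome``,
        ``position``, ``allele_minor``, ``allele_major``, ``gene`` (empty
        string when unmapped) and ``flipped`` (True when the stored dosage
        counts the REF/ALT-opposite allele relative to the source file).
    individual_ids : list of str
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.variants)):
            raise ValueError("dosage shape does not match metadata")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FormatError(f"duplicate variant_id {dup!r}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean.

        All-missing variants impute to 0 (they are monomorphic-by-ignorance
        and are excluded from analysis downstream).
        """
        out = self.dosages.copy()
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(out))
        out[idx] = col_mean[idx[1]]
        return out

    def attach_gene_map(self, gene_map: dict[str, str]) -> None:
        """Fill the ``gene`` column from a variant_id -> gene mapping."""
        self.variants["gene"] = [
            gene_map.get(v, "") for v in self.variants["variant_id"]
        ]


def _minor_major(counts: dict[str, int], variant_id: str) -> tuple[str, str]:
    alleles = sorted(counts)  # alphabetical tie-break, deterministic
    if len(alleles) > 2:
        raise FormatError(f"variant {variant_id!r} is not biallelic: {alleles}")
    if len(alleles) == 1:
        return alleles[0], alleles[0]
    a, b = alleles
    return (a, b) if counts[a] <= counts[b] else (b, a)


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a whitespace-separated PLINK .ped/.map pair.

    The additive dosage counts the minor allele, with the minor allele
    determined from this file's allele frequencies (alphabetical tie-break at
    frequency 0.5).  '0 0' genotypes become NaN.
    """
    map_rows = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"malformed .map line: {line!r}")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    individual_ids: list[str] = []
    allele_rows: list[list[str]] = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f".ped row has {len(parts) - 6} allele fields for {m} mapped "
                "variants"
            )
        individual_ids.append(parts[1])
        allele_rows.append(parts[6:])

    n = len(individual_ids)
    dosages = np.full((n, m), MISSING)
    alleles = np.array(allele_rows, dtype="U8") if n else np.empty((0, 2 * m), "U8")
    minors, majors = [], []
    for j, (_, vid, _) in enumerate(map_rows):
        pair = alleles[:, 2 * j : 2 * j + 2]
        observed = pair[pair != "0"]
        if observed.size == 0:
            minors.append("0")
            majors.append("0")
            continue
        uniq, cnt = np.unique(observed, return_counts=True)
        minor, major = _minor_major(dict(zip(uniq, cnt)), vid)
        minors.append(minor)
        majors.append(major)
        ok = ~np.any(pair == "0", axis=1)
        dosages[ok, j] = (pair[ok] == minor).sum(axis=1)

    variants = pd.DataFrame(
        {
            "variant_id": [r[1] for r in map_rows],
            "chromosome": [r[0] for r in map_rows],
            "position": [r[2] for r in map_rows],
            "allele_minor": minors,
            "allele_major": majors,
            "gene": "",
            "flipped": False,
        }
    )
    return GenotypeMatrix(dosages, variants, individual_ids)


def write_plink_text(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write the PLINK text dialect; inverse of :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for _, v in gm.variants.iterrows():
            fh.write(f"{v.chromosome} {v.variant_id} 0 {v.position}\n")
    minor = gm.variants["allele_minor"].to_numpy(dtype="U8")
    major = gm.variants["allele_major"].to_numpy(dtype="U8")
    d = gm.dosages
    miss = np.isnan(d)
    a1 = np.where(d >= 1, minor, major)
    a2 = np.where(d >= 2, minor, major)
    a1[miss] = "0"
    a2[miss] = "0"
    pairs = np.empty((d.shape[0], 2 * d.shape[1]), dtype="U8")
    pairs[:, 0::2] = a1
    pairs[:, 1::2] = a2
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(gm.individual_ids):
            fh.write(f"{ind} {ind} 0 0 0 -9 " + " ".join(pairs[i]) + "\n")


def read_vcf(vcf_path) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into minor-allele dosages.

    The ALT count per genotype is re-oriented so the stored dosage counts the
    minor allele (``flipped`` records the orientation).  Half-calls and
    ``./.`` become NaN; multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    individual_ids = list(vcf.samples)
    n = len(individual_ids)
    cols, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        if "GT" not in var.FORMAT:
            raise FormatError(f"record at {var.CHROM}:{var.POS} lacks GT")
        d = np.full(n, MISSING)
        for i, gt in enumerate(var.genotypes):
            a = [x for x in gt[:-1]]
            if len(a) >= 2 and a[0] >= 0 and a[1] >= 0:
                d[i] = a[0] + a[1]
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append((vid, var.CHROM, var.POS, var.ALT[0], var.REF))
        cols.append(d)
    vcf.close()

    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "position", "allele_minor", "allele_major"]
    )
    variants["gene"] = ""
    variants["flipped"] = False
    # re-orient to the minor allele
    with np.errstate(invalid="ignore"):
        f_alt = np.nanmean(dosages, axis=0) / 2.0
    for j in range(dosages.shape[1]):
        if np.isfinite(f_alt[j]) and f_alt[j] > 0.5:
            obs = ~np.isnan(dosages[:, j])
            dosages[obs, j] = 2.0 - dosages[obs, j]
            variants.loc[j, ["allele_minor", "allele_major"]] = list(
                variants.loc[j, ["allele_major", "allele_minor"]]
            )
            variants.loc[j, "flipped"] = True
    return GenotypeMatrix(dosages, variants, individual_ids)


def write_vcf(gm: GenotypeMatrix, vcf_path) -> None:
    """Write a minimal VCF 4.2 with GT only (REF = major, ALT = minor)."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.variants["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (_, v) in enumerate(gm.variants.iterrows()):
            ref = v.allele_major if v.allele_major != "0" else "A"
            alt = v.allele_minor if v.allele_minor not in ("0", ref) else "T"
            calls = [
                "./."
                if np.isnan(gm.dosages[i, j])
                else gts[int(round(gm.dosages[i, j]))]
                for i in range(gm.n_individuals)
            ]
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.variant_id}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_gene_map(tsv_path) -> dict[str, str]:
    """Read a two-column headered TSV mapping variant_id -> gene."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("gene map must have two columns (variant_id, gene)")
    df = df.iloc[:, :2]
    df.columns = ["variant_id", "gene"]
    df["gene"] = df["gene"].fillna("")
    conflicts = df.groupby("variant_id")["gene"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise FormatError(
            f"variant {bad.index[0]!r} maps to multiple genes"
        )
    return dict(zip(df["variant_id"], df["gene"]))


def read_phenotypes(tsv_path) -> pd.DataFrame:
    """Read the phenotype/covariate table (one row per individual x replicate).

    Expected columns: individual_id, replicate, affected, age, sex, smoke.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "replicate", "affected", "age", "sex", "smoke"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"phenotype table lacks columns {sorted(missing)}")
    if df.duplicated(["individual_id", "replicate"]).any():
        raise FormatError("duplicate (individual, replicate) rows")
    if not df["affected"].isin([0, 1]).all():
        raise FormatError("affected must be binary 0/1")
    return df


def write_phenotypes(df: pd.DataFrame, tsv_path) -> None:
    df.to_csv(tsv_path, sep="\t", index=False)


def write_gene_map(gene_map: dict[str, str], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("variant_id\tgene\n")
        for vid, gene in gene_map.items():
            fh.write(f"{vid}\t{gene}\n")


def _fmt_pct(x: float) -> str:
    """Format a percentage the way the tables print them (41, 6.5, 92)."""
    return f"{x:g}"


def write_report(report, snp_path, gene_path) -> None:
    """Write the per-SNP and per-gene/covariate nonzero-frequency tables.

    Both TSVs are sorted by frequency descending with ties broken by name;
    frequencies are percentages of replicates with a nonzero estimated
    effect.
    """
    snp = report.snp_table.sort_values(
        ["frequency_pct", "snp"], ascending=[False, True], kind="mergesort"
    )
    with open(snp_path, "w") as fh:
        fh.write("snp\tgene\tchromosome\tfrequency_pct\n")
        for _, r in snp.iterrows():
            fh.write(
                f"{r.snp}\t{r.gene}\t{r.chromosome}\t{_fmt_pct(r.frequency_pct)}\n"
            )
    gene = report.gene_table.sort_values(
        ["frequency_pct", "name"], ascending=[False, True], kind="mergesort"
    )
    with open(gene_path, "w") as fh:
        fh.write("name\tchromosome\tfrequency_pct\n")
        for _, r in gene.iterrows():
            fh.write(f"{r['name']}\t{r['chromosome']}\t{_fmt_pct(r['frequency_pct'])}\n")
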