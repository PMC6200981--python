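"""Genotype containers, readers, filters.

The unified variant universe mixes two kinds of variants:

* **SNPs** — biallelic nucleotide variants with a replicon and 1-based
  position.  Bacterial calls are haploid; VCF input may encode them as
  pseudo-diploid genotypes (``0/0``, ``1/1``), in which case heterozygous
  calls (``0/1``) are artifacts of read mapping and are converted to
  missing data.
* **PAVs** — gene presence/absence variants derived from pangenome gene
  clusters.  Presence is dosage 1, absence 0.  PAV clusters absent from
  the reference genome carry no coordinates and are placed on the
  pseudo-replicon ``"unplaced"``.

Dosages are stored as a dense ``float64`` strains x variants array with
``NaN`` marking missing calls; per-variant metadata live in a pandas
DataFrame aligned to the columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNPLACED = "unplaced"

#: columns every ``GenotypeMatrix.variants`` table carries
VARIANT_COLUMNS = ["id", "vtype", "replicon", "position"]


@dataclass
class VariantRecord:
    """One row of the variant table plus its dosage column."""

    id: str
    vtype: str  # "SNP" or "PAV"
    replicon: str
    position: int | None
    dosage: np.ndarray
    maf: float
    missing_fraction: float


class GenotypeMatrix:
    """Strains x variants haploid dosage matrix with variant metadata.

    Parameters
    ----------
    strain_ids
        Unique strain names, one per row of ``dosage``.
    dosage
        ``(n_strains, n_variants)`` float array with values 0, 1 or NaN.
    variants
        DataFrame with at least ``id``, ``vtype``, ``replicon``,
        ``position`` (nullable integer; NA for unplaced PAVs).
    het_mask
        Optional boolean array marking calls that were heterozygous in
        the source data (already set to NaN in ``dosage``); kept only so
        the VCF writer can round-trip them.
    """

    def __init__(
        self,
        strain_ids: Sequence[str],
        dosage: np.ndarray,
        variants: pd.DataFrame,
        het_mask: np.ndarray | None = None,
    ):
        strain_ids = [str(s) for s in strain_ids]
        if len(set(strain_ids)) != len(strain_ids):
            raise ValueError("duplicate strain ids")
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2 or dosage.shape != (len(strain_ids), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(strain_ids)} strains x {len(variants)} variants"
            )
        ok = np.isnan(dosage) | (dosage == 0) | (dosage == 1)
        if not ok.all():
            raise ValueError("dosage values must be 0, 1 or missing (NaN)")
        variants = variants.reset_index(drop=True).copy()
        for col in VARIANT_COLUMNS:
            if col not in variants.columns:
                raise ValueError(f"variant table lacks column {col!r}")
        variants["position"] = variants["position"].astype("Int64")
        self.strain_ids = strain_ids
        self.dosage = dosage
        self.variants = variants
        self.het_mask = het_mask

    # -- basic shape -------------------------------------------------
    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_snp = int((self.variants["vtype"] == "SNP").sum())
        return (
            f"GenotypeMatrix({self.n_strains} strains x {self.n_variants} "
            f"variants; {n_snp} SNPs, {self.n_variants - n_snp} PAVs)"
        )

    # -- per-variant statistics --------------------------------------
    def allele_frequency(self) -> np.ndarray:
        """Alt/presence allele frequency among non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.dosage, axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency; the rarer state, computed on
        non-missing calls only."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def variant_table(self) -> pd.DataFrame:
        """Variant metadata augmented with ``maf`` and ``missing_fraction``."""
        out = self.variants.copy()
        out["maf"] = self.maf()
        out["missing_fraction"] = self.missing_fraction()
        return out

    # -- subsetting ---------------------------------------------------
    def take_variants(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        het = self.het_mask[:, index] if self.het_mask is not None else None
        return GenotypeMatrix(
            self.strain_ids,
            self.dosage[:, index],
            self.variants.iloc[index],
            het_mask=het,
        )

    def take_strains(self, strain_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.strain_ids)}
        idx = np.array([pos[s] for s in strain_ids])
        het = self.het_mask[idx] if self.het_mask is not None else None
        return GenotypeMatrix(
            list(strain_ids), self.dosage[idx], self.variants, het_mask=het
        )

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == variant_id]
        if len(j) != 1:
            raise KeyError(variant_id)
        return self.dosage[:, j[0]]

    def concat_variants(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if other.strain_ids != self.strain_ids:
            raise ValueError("strain ids differ; cannot concatenate")
        het = None
        if self.het_mask is not None or other.het_mask is not None:
            a = (
                self.het_mask
                if self.het_mask is not None
                else np.zeros_like(self.dosage, dtype=bool)
            )
            b = (
                other.het_mask
                if other.het_mask is not None
                else np.zeros_like(other.dosage, dtype=bool)
            )
            het = np.hstack([a, b])
        return GenotypeMatrix(
            self.strain_ids,
            np.hstack([self.dosage, other.dosage]),
            pd.concat(
                [self.variants[VARIANT_COLUMNS], other.variants[VARIANT_COLUMNS]],
                ignore_index=True,
            ),
            het_mask=het,
        )


# ---------------------------------------------------------------------------
# filtering / imputation
# ---------------------------------------------------------------------------


def filter_variants(
    G: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.20
) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` and missingness <= ``missing_max``.

    MAF is computed on non-missing calls.  Input order is preserved; the
    operation is idempotent.  An empty result triggers a warning, not an
    error.
    """
    maf = G.maf()
    keep = (maf >= maf_min) & ~np.isnan(maf)  # all-missing columns drop too
    keep &= G.missing_fraction() <= missing_max
    n_drop = int((~keep).sum())
    logger.info(
        "filter_variants: kept %d of %d variants (dropped %d; maf_min=%g, "
        "missing_max=%g)",
        int(keep.sum()),
        G.n_variants,
        n_drop,
        maf_min,
        missing_max,
    )
    if not keep.any():
        warnings.warn("no variants survive filtering", stacklevel=2)
    return G.take_variants(keep)


def mean_impute(G: GenotypeMatrix) -> np.ndarray:
    """Replace missing dosages by the per-variant mean of observed calls.

    Returns a dense float matrix; observed entries are unchanged.  A
    fully missing column cannot be imputed and raises.
    """
    X = G.dosage.copy()
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        bad = G.variants.loc[miss.all(axis=0), "id"].tolist()
        raise ValueError(f"cannot impute all-missing variants: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
    X[miss] = np.broadcast_to(mu, X.shape)[miss]
    return X


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def _is_snp_or_mnp(ref: str, alt: str) -> bool:
    # same-length substitutions only; MNPs count as single variants,
    # indels (length change) are dropped
    return len(ref) == len(alt) and len(ref) >= 1


def read_vcf(
    path: str,
    min_qual: float = 20.0,
    drop_indels: bool = True,
) -> GenotypeMatrix:
    """Read SNP/MNP genotypes from a VCF 4.x file.

    Filtering and recoding applied while reading:

    * heterozygous pseudo-diploid calls become missing data;
    * multi-allelic sites are split into one biallelic record per alt
      allele (carriers of a different alt count as reference);
    * MNPs (same-length multi-nucleotide substitutions) are kept as
      single variants; indels are dropped;
    * sites with ``QUAL`` below ``min_qual`` are dropped (missing QUAL
      passes).

    Haploid genotypes (``0``, ``1``) are accepted alongside
    pseudo-diploid ones.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot open VCF {path!r}: {exc}") from exc
    strains = list(vcf.samples)
    if len(set(strains)) != len(strains):
        raise ValueError(f"duplicate strain ids in VCF header of {path!r}")

    columns: list[np.ndarray] = []
    meta: list[tuple[str, str, str, int]] = []
    n_indel = n_lowq = 0
    for v in vcf:
        if v.QUAL is not None and v.QUAL < min_qual:
            n_lowq += 1
            continue
        alts = v.ALT or []
        # allele index per strain: -1 missing, -2 het, else allele number
        allele = np.empty(len(strains), dtype=int)
        for i, gt in enumerate(v.genotypes):
            calls = [a for a in gt[:-1] if a != -2]  # -2: absent second allele
            obs = [a for a in calls if a >= 0]
            if not obs:
                allele[i] = -1
            elif len(set(obs)) > 1:
                allele[i] = -2  # heterozygous -> missing
            else:
                allele[i] = obs[0]
        for k, alt in enumerate(alts, start=1):
            if drop_indels and not _is_snp_or_mnp(v.REF, alt):
                n_indel += 1
                continue
            col = np.where(allele == k, 1.0, 0.0)
            col[allele < 0] = np.nan
            vid = f"{v.CHROM}:{v.POS}:{alt}"
            columns.append(col)
            meta.append((vid, "SNP", v.CHROM, v.POS))
    if n_indel or n_lowq:
        logger.info(
            "read_vcf: dropped %d indel alleles and %d sites with QUAL<%g",
            n_indel,
            n_lowq,
            min_qual,
        )
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(strains), 0))
    )
    return GenotypeMatrix(strains, dosage, variants)


def write_vcf(G: GenotypeMatrix, path: str, contig_lengths: dict | None = None) -> None:
    """Write the SNP part of a GenotypeMatrix as pseudo-diploid VCF.

    Dosage 0 -> ``0/0``, 1 -> ``1/1``, missing -> ``./.``; calls flagged
    in ``het_mask`` are rendered ``0/1`` so the heterozygote-to-missing
    read path can be exercised on round trip.  Allele letters are
    placeholders (the pipeline uses only dosages).
    """
    snp = G.take_variants((G.variants["vtype"] == "SNP").to_numpy())
    order = np.lexsort(
        (snp.variants["position"].to_numpy(dtype=float), snp.variants["replicon"])
    )
    snp = snp.take_variants(order)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rhizogwas\n")
        for name in dict.fromkeys(snp.variants["replicon"]):
            if contig_lengths and name in contig_lengths:
                fh.write(f"##contig=<ID={name},length={contig_lengths[name]}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(snp.strain_ids)
            + "\n"
        )
        het = (
            snp.het_mask
            if snp.het_mask is not None
            else np.zeros_like(snp.dosage, dtype=bool)
        )
        for j in range(snp.n_variants):
            row = snp.variants.iloc[j]
            gts = []
            for i in range(snp.n_strains):
                if het[i, j]:
                    gts.append("0/1")
                elif np.isnan(snp.dosage[i, j]):
                    gts.append("./.")
                else:
                    gts.append("0/0" if snp.dosage[i, j] == 0 else "1/1")
            fh.write(
                f"{row['replicon']}\t{row['position']}\t{row['id']}\t"
                f"A\tC\t99\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# PAV table input/output
# ---------------------------------------------------------------------------


def read_pav(path: str) -> GenotypeMatrix:
    """Read a gene presence/absence matrix from TSV.

    Layout: one row per gene cluster; first column ``cluster_id``;
    optional ``replicon``/``position`` placement columns; remaining
    columns are strains with cells 0 (absent), 1 (present) or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "cluster_id":
        raise ValueError("PAV table must start with a 'cluster_id' column")
    placement = [c for c in ("replicon", "position") if c in df.columns]
    strain_cols = [c for c in df.columns[1:] if c not in placement]
    vals = np.full((len(df), len(strain_cols)), np.nan)
    for jc, c in enumerate(strain_cols):
        col = df[c]
        for ir, cell in enumerate(col):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell in (
                "NA",
                "",
                ".",
            ):
                continue
            if cell not in ("0", "1"):
                raise ValueError(
                    f"non-binary PAV cell {cell!r} at cluster "
                    f"{df['cluster_id'][ir]!r}, strain {c!r}"
                )
            vals[ir, jc] = float(cell)
    variants = pd.DataFrame(
        {
            "id": df["cluster_id"],
            "vtype": "PAV",
            "replicon": df["replicon"] if "replicon" in placement else UNPLACED,
            "position": pd.array(
                pd.to_numeric(df["position"], errors="coerce")
                if "position" in placement
                else [None] * len(df),
                dtype="Int64",
            ),
        }
    )
    variants.loc[variants["replicon"].isna(), "replicon"] = UNPLACED
    return GenotypeMatrix(strain_cols, vals.T, variants)


def write_pav(G: GenotypeMatrix, path: str) -> None:
    pav = G.take_variants((G.variants["vtype"] == "PAV").to_numpy())
    placed = pav.variants["replicon"].ne(UNPLACED).any()
    with open(path, "w") as fh:
        cols = ["cluster_id"] + (["replicon", "position"] if placed else [])
        fh.write("\t".join(cols + pav.strain_ids) + "\n")
        for j in range(pav.n_variants):
            row = pav.variants.iloc[j]
            cells = [row["id"]]
            if placed:
                cells += [
                    str(row["replicon"]),
                    "" if pd.isna(row["position"]) else str(row["position"]),
                ]
            for i in range(pav.n_strains):
                d = pav.dosage[i, j]
                cells.append("NA" if np.isnan(d) else str(int(d)))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# phenotypes and variant-table output
# ---------------------------------------------------------------------------


def read_phenotypes(path: str) -> pd.DataFrame:
    """Strain x trait table; first column ``strain_id``; NA allowed."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "strain_id":
        raise ValueError("phenotype table must start with a 'strain_id' column")
    df = df.set_index("strain_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate strain ids in phenotype table")
    return df.astype(float)


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index_label="strain_id", na_rep="NA")


def write_variant_table(G: GenotypeMatrix, path: str) -> None:
    G.variant_table().to_csv(path, sep="\t", index=False, na_rep="NA")
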