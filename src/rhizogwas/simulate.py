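"""Synthetic pangenome genotypes and phenotypes.

The generator emulates a worldwide collection of ~150 clonally
structured bacterial strains carrying a multi-replicon genome: a large
chromosome with long haplotype blocks (extensive linkage
disequilibrium) and two megaplasmids whose variation is shuffled into
much shorter blocks by more frequent recombination.  Strains fall into
clades that diverged from a common ancestor (a star-of-clades
genealogy); strains within a clade differ only by a small number of
private mutations.  Gene presence/absence variants (PAVs) arise from
gain/loss events on clade branches, independent of the SNP haplotypes,
so SNP-PAV linkage is weak.

Phenotypes are drawn under a polygenic-plus-sparse-effects model: a
polygenic component with covariance proportional to the kinship matrix,
a handful of large-effect causal variants, and microenvironmental
noise.  Binary traits threshold the continuous liability at the
quantile giving a requested class imbalance.

All randomness flows from explicit integer seeds; identical
configuration and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import UNPLACED, GenotypeMatrix

__all__ = ["SimConfig", "PhenoModel", "PhenotypeResult", "simulate_genotypes",
           "simulate_phenotype"]

# Default replicon layout: sizes mirror a rhizobial genome
# (3.5-Mb chromosome, 1.8-Mb and 1.5-Mb megaplasmids); SNP counts are a
# desk-scale fraction of the >100k common variants such genomes carry.
DEFAULT_REPLICONS = [
    ("chromosome", 3_500_000, 4_500),
    ("pSymB", 1_800_000, 3_500),
    ("pSymA", 1_500_000, 2_000),
]

# Haplotype-block lengths per replicon: long blocks on the chromosome,
# sub-kb blocks on the recombining megaplasmids (matching the ~170 kb
# vs ~0.5-1 kb spanned distances of LD groups the two regimes produce).
DEFAULT_BLOCKS = {"chromosome": 175_000, "pSymB": 520, "pSymA": 1_000}


@dataclass
class SimConfig:
    """Parameters of the genotype generator.

    ``within_clade_mutations`` is the number of private mutations per
    strain (sites flipped relative to the clade haplotype).
    ``ld_block_length`` maps replicon name to haplotype-block length in
    bp; variants within a block share a clade-level genealogy and are
    in strong mutual LD, variants in different blocks are independent.
    """

    n_strains: int = 153
    n_clades: int = 10
    within_clade_mutations: int = 50
    replicon_spec: Sequence[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_REPLICONS)
    )
    n_pav_genes: int = 1_300
    ld_block_length: dict = field(default_factory=lambda: dict(DEFAULT_BLOCKS))
    pav_placed_fraction: float = 0.2
    missing_rate: float = 0.20
    het_rate: float = 0.01
    maf_floor: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        names = [r[0] for r in self.replicon_spec]
        if len(set(names)) != len(names):
            raise ValueError("replicon names must be unique")
        for name, length, n_snp in self.replicon_spec:
            if length <= 0 or n_snp < 0 or n_snp > length:
                raise ValueError(f"bad replicon spec for {name!r}")
            if self.ld_block_length.get(name, 0) <= 0:
                raise ValueError(f"missing/invalid ld_block_length for {name!r}")
        if not (0 <= self.missing_rate <= 0.3):
            raise ValueError("missing_rate must be in [0, 0.3]")
        for rate in (self.het_rate, self.pav_placed_fraction):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")
        if self.n_strains < 2 or self.n_clades < 1:
            raise ValueError("need >=2 strains and >=1 clade")
        # a MAF floor q needs ceil(q n) minor-allele carriers and the
        # minor count cannot exceed n/2
        if math.ceil(self.maf_floor * self.n_strains) > self.n_strains // 2:
            raise ValueError(
                f"maf_floor {self.maf_floor} unattainable with "
                f"{self.n_strains} strains"
            )


def _draw_maf(rng: np.random.Generator, floor: float, size: int) -> np.ndarray:
    """Frequencies from a folded neutral-like spectrum, density ~ 1/q on
    [floor, 0.5] (uniform on log q)."""
    lo = max(floor, 1e-3)
    u = rng.random(size)
    return lo * (0.5 / lo) ** u


def _clade_assignment(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    perm = rng.permutation(n)
    clade = np.empty(n, dtype=int)
    clade[perm] = np.arange(n) % k
    return clade


def _block_patterns(
    rng: np.random.Generator,
    clade_sizes: np.ndarray,
    n_snps: int,
    floor: float,
) -> np.ndarray:
    """Clade-level 0/1 patterns for the SNPs of one haplotype block.

    All SNPs of a block share one random ordering of the clades (the
    block genealogy); each SNP assigns the derived allele to the prefix
    of that ordering whose cumulative strain count best matches a
    frequency drawn from the folded spectrum.  Nested prefixes give the
    strong within-block LD of clonal haplotypes.
    """
    k = len(clade_sizes)
    n = clade_sizes.sum()
    order = rng.permutation(k)
    cum = np.concatenate([[0], np.cumsum(clade_sizes[order])])
    q = _draw_maf(rng, floor, n_snps)
    targets = q * n
    # prefix length whose cumulative size is closest to the target count
    pref = np.abs(cum[None, :] - targets[:, None]).argmin(axis=1)
    pat = np.zeros((n_snps, k), dtype=np.int8)
    for s in range(n_snps):
        pat[s, order[: pref[s]]] = 1
    flip = rng.random(n_snps) < 0.5  # random ancestral/derived orientation
    pat[flip] = 1 - pat[flip]
    return pat


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Generate a clonally structured SNP + PAV genotype matrix.

    Returns a :class:`GenotypeMatrix` whose ``het_mask`` marks the
    injected heterozygous calls (already missing in the dosage matrix,
    mirroring the heterozygote-to-missing filter downstream readers
    apply).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    clade = _clade_assignment(rng, n, config.n_clades)
    clade_sizes = np.bincount(clade, minlength=config.n_clades)

    cols: list[np.ndarray] = []
    meta: list[tuple[str, str, str, object]] = []

    for name, length, n_snp in config.replicon_spec:
        if n_snp == 0:
            continue
        positions = np.sort(rng.choice(length, size=n_snp, replace=False)) + 1
        block = (positions - 1) // config.ld_block_length[name]
        for b in np.unique(block):
            idx = np.flatnonzero(block == b)
            pat = _block_patterns(rng, clade_sizes, len(idx), config.maf_floor)
            cols.append(pat[:, clade].T.astype(float))  # n x n_snps_in_block
            for j, snp_i in enumerate(idx):
                meta.append(
                    (f"{name}:{positions[snp_i]}:C", "SNP", name,
                     int(positions[snp_i]))
                )

    n_snp_total = sum(c.shape[1] for c in cols)

    # PAVs: gain/loss on clade branches with a fresh clade ordering per
    # gene, so PAV patterns are unlinked from SNP haplotypes.
    if config.n_pav_genes:
        pat = np.zeros((config.n_pav_genes, config.n_clades), dtype=np.int8)
        for g in range(config.n_pav_genes):
            pat[g] = _block_patterns(rng, clade_sizes, 1, config.maf_floor)[0]
        cols.append(pat[:, clade].T.astype(float))
        placed = rng.random(config.n_pav_genes) < config.pav_placed_fraction
        rep_names = [r[0] for r in config.replicon_spec]
        rep_lengths = {r[0]: r[1] for r in config.replicon_spec}
        for g in range(config.n_pav_genes):
            if placed[g] and rep_names:
                rep = rep_names[rng.integers(len(rep_names))]
                pos = int(rng.integers(rep_lengths[rep])) + 1
            else:
                rep, pos = UNPLACED, None
            meta.append((f"cluster_{g:05d}", "PAV", rep, pos))

    dosage = np.hstack(cols) if cols else np.empty((n, 0))
    p = dosage.shape[1]

    # private within-clade mutations: each strain flips a few sites
    if config.within_clade_mutations and p:
        n_mut = min(config.within_clade_mutations, p)
        for i in range(n):
            sites = rng.choice(p, size=n_mut, replace=False)
            dosage[i, sites] = 1 - dosage[i, sites]

    # per-site missingness rate drawn U(0, missing_rate)
    if config.missing_rate and p:
        site_rate = rng.uniform(0, config.missing_rate, size=p)
        miss = rng.random((n, p)) < site_rate
        dosage[miss] = np.nan
    # heterozygous artifacts on SNP calls only
    het = np.zeros((n, p), dtype=bool)
    if config.het_rate and n_snp_total:
        cand = rng.random((n, n_snp_total)) < config.het_rate
        cand &= ~np.isnan(dosage[:, :n_snp_total])
        het[:, :n_snp_total] = cand
        dosage[het] = np.nan

    variants = pd.DataFrame(meta, columns=["id", "vtype", "replicon", "position"])
    variants["position"] = variants["position"].astype("Int64")
    return GenotypeMatrix([f"strain_{i:03d}" for i in range(n)], dosage,
                          variants, het_mask=het)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenoModel:
    """Generative model for one trait.

    ``pve_background`` is the variance fraction from the polygenic
    component (covariance proportional to the kinship matrix);
    ``large_effect_pve`` is split equally across ``n_large_effects``
    sparse causal variants; the remainder is i.i.d. noise.  ``noise_sd``
    rescales the whole trait (unit scale by default).  For binary
    traits the liability is thresholded so the minority class has
    frequency ``imbalance``.
    """

    trait_type: str = "continuous"
    pve_background: float = 0.3
    n_large_effects: int = 0
    large_effect_pve: float = 0.0
    imbalance: float = 0.5
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError("trait_type must be 'continuous' or 'binary'")
        if self.pve_background < 0 or self.large_effect_pve < 0:
            raise ValueError("variance fractions must be >= 0")
        if self.pve_background + self.large_effect_pve > 1:
            raise ValueError("pve_background + large_effect_pve must be <= 1")
        if self.n_large_effects > 0 and self.large_effect_pve == 0:
            raise ValueError("large effects requested but large_effect_pve=0")
        if not (0 < self.imbalance <= 0.5):
            raise ValueError("imbalance must be in (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class PhenotypeResult:
    """Simulated trait plus its generative truth."""

    values: pd.Series  # indexed by strain id
    causal_ids: list
    realized_pve: float  # empirical var(genetic)/var(total) of this draw
    liability: pd.Series | None = None  # pre-threshold values, binary only


def _unit_scale(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate (constant) component in phenotype draw")
    return (x - x.mean()) / sd


def simulate_phenotype(
    G: GenotypeMatrix,
    model: PhenoModel,
    K: np.ndarray,
    seed: int,
) -> PhenotypeResult:
    """Draw one trait on the strains of ``G`` under ``model``.

    ``K`` must be an ``n x n`` kinship matrix aligned with
    ``G.strain_ids``.  Components are empirically standardized before
    mixing, so the realized variance decomposition tracks the requested
    fractions closely even at small n.
    """
    model.validate()
    n = G.n_strains
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError(f"K shape {K.shape} does not match {n} strains")
    rng = np.random.default_rng(seed)

    genetic = np.zeros(n)
    if model.pve_background > 0:
        d, U = np.linalg.eigh((K + K.T) / 2)
        d = np.clip(d, 0, None)
        g = U @ (np.sqrt(d) * rng.standard_normal(n))
        genetic = genetic + _unit_scale(g) * math.sqrt(model.pve_background)

    causal_ids: list = []
    if model.n_large_effects > 0:
        maf = G.maf()
        # prefer common variants so the requested effect variance is
        # realizable on 0/1 dosages
        eligible = np.flatnonzero(maf >= min(0.2, np.nanmax(maf)))
        if len(eligible) < model.n_large_effects:
            eligible = np.argsort(-np.nan_to_num(maf))[: model.n_large_effects]
        chosen = rng.choice(eligible, size=model.n_large_effects, replace=False)
        per_var = model.large_effect_pve / model.n_large_effects
        for j in chosen:
            x = G.dosage[:, j].copy()
            mu = np.nanmean(x)
            x[np.isnan(x)] = mu
            genetic = genetic + _unit_scale(x) * math.sqrt(per_var)
            causal_ids.append(G.variants["id"].iloc[j])

    noise_var = 1.0 - model.pve_background - model.large_effect_pve
    noise = _unit_scale(rng.standard_normal(n)) * math.sqrt(max(noise_var, 1e-12))
    y = (genetic + noise) * model.noise_sd

    var_y = y.var()
    realized = float((genetic * model.noise_sd).var() / var_y) if var_y > 0 else 0.0

    values = pd.Series(y, index=pd.Index(G.strain_ids, name="strain_id"))
    if model.trait_type == "binary":
        k_minor = int(round(model.imbalance * n))
        k_minor = max(k_minor, 1)
        thresh_idx = np.argsort(y)[::-1][:k_minor]
        binary = np.zeros(n)
        binary[thresh_idx] = 1.0
        return PhenotypeResult(
            values=pd.Series(binary, index=values.index),
            causal_ids=causal_ids,
            realized_pve=realized,
            liability=values,
        )
    return PhenotypeResult(values=values, causal_ids=causal_ids,
                           realized_pve=realized)


def write_truth(result: PhenotypeResult, path: str, trait: str = "trait") -> None:
    """Record causal variant ids and realized PVE as TSV."""
    with open(path, "w") as fh:
        fh.write("trait\trealized_pve\tcausal_ids\n")
        fh.write(f"{trait}\t{result.realized_pve:.6f}\t"
                 + ",".join(map(str, result.causal_ids)) + "\n")
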