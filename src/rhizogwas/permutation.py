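"""Permutation empirical nulls.

Randomly reassigning phenotype values to strains destroys any true
genotype-phenotype relationship while preserving the trait
distribution, the missing-data pattern, and the genotypes (hence LD
and kinship, which are reused rather than recomputed).  Re-running the
PVE estimation, the association scan, forward selection and the
enrichment statistics on each of ``n_perms`` permutations yields the
empirical null distributions against which the real data are judged:
with tens of thousands of LD groups one expects a considerable number
of chance associations, and the null quantifies them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .ld import GroupingResult
from .lmm import NullModelFit, assoc_scan, fit_null
from .selection import enrichment_stats, forward_select

logger = logging.getLogger(__name__)

__all__ = ["NullEnsemble", "permute_phenotype", "build_null",
           "null_percentiles"]


@dataclass
class NullEnsemble:
    """Per-permutation statistics of the empirical null.

    ``table`` has one row per permutation with columns ``pve_lmm``,
    ``prve_r<k>`` / ``cum_r<k>`` for ranks 1..max_rank, the enrichment
    means, and optionally ``pve_bslmm``.
    """

    table: pd.DataFrame
    master_seed: int
    max_rank: int

    @property
    def n_perms(self) -> int:
        return len(self.table)

    def rank_columns(self, stat: str) -> pd.DataFrame:
        cols = [f"{stat}_r{k}" for k in range(1, self.max_rank + 1)
                if f"{stat}_r{k}" in self.table.columns]
        return self.table[cols]


def permute_phenotype(y: pd.Series | np.ndarray, seed: int) -> pd.Series | np.ndarray:
    """Shuffle phenotype values across strains, leaving missing entries
    where they are.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    if isinstance(y, pd.Series):
        vals = y.to_numpy(dtype=float, copy=True)
    else:
        vals = np.array(y, dtype=float)
    obs = np.flatnonzero(~np.isnan(vals))
    vals[obs] = vals[obs][rng.permutation(len(obs))]
    if isinstance(y, pd.Series):
        return pd.Series(vals, index=y.index, name=y.name)
    return vals


def build_null(
    y: np.ndarray | pd.Series,
    G: GenotypeMatrix,
    K: np.ndarray,
    grouping: GroupingResult,
    Ximp: np.ndarray,
    seed_ids: list[str],
    n_perms: int = 100,
    master_seed: int = 0,
    max_rank: int = 25,
    top_k: int = 100,
    n_top_groups: int = 10,
    bslmm_fn=None,
) -> NullEnsemble:
    """Run the full per-trait analysis on ``n_perms`` phenotype
    permutations.

    Per permutation (seed ``master_seed + i``): LMM null PVE, seed-
    variant association scan, forward selection over the ``top_k``
    most associated variants to ``max_rank``, and enrichment means of
    the ``n_top_groups`` most associated LD groups.  ``bslmm_fn``, if
    given, maps a permuted phenotype vector to a BSLMM PVE estimate
    (optional because it is the expensive stage).  The kinship and
    grouping are computed once by the caller: genotypes do not change
    under permutation.
    """
    yv = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    id_pos = {vid: j for j, vid in enumerate(G.variants["id"])}
    seed_cols = np.array([id_pos[v] for v in seed_ids])
    Xseed = Ximp[:, seed_cols]

    rows = []
    for i in range(n_perms):
        seed_i = master_seed + i
        yp = permute_phenotype(yv, seed_i)
        try:
            row = _one_null_rep(yp, G, K, grouping, Ximp, Xseed, seed_ids,
                                max_rank, top_k, n_top_groups, bslmm_fn)
        except Exception as exc:
            raise RuntimeError(
                f"permutation {i} (seed {seed_i}) failed: {exc}"
            ) from exc
        row["perm"] = i
        row["seed"] = seed_i
        rows.append(row)
        if (i + 1) % 25 == 0:
            logger.info("permutation null: %d/%d done", i + 1, n_perms)
    return NullEnsemble(pd.DataFrame(rows), master_seed, max_rank)


def _one_null_rep(yp, G, K, grouping, Ximp, Xseed, seed_ids,
                  max_rank, top_k, n_top_groups, bslmm_fn) -> dict:
    null_fit = fit_null(yp, K)
    row: dict = {"pve_lmm": null_fit.pve.estimate}
    scan = assoc_scan(yp, K, Xseed, variant_ids=seed_ids, null=null_fit)
    ranked = scan.dropna(subset=["p_lrt"]).sort_values("p_lrt")
    pool = ranked.head(top_k)
    pool_cols = [seed_ids.index(v) for v in pool["variant_id"]]
    path = forward_select(yp, Xseed[:, pool_cols],
                          pool["variant_id"].tolist(), max_rank=max_rank)
    for _, entry in path.table.iterrows():
        row[f"prve_r{int(entry['rank'])}"] = entry["prve"]
        row[f"cum_r{int(entry['rank'])}"] = entry["cumulative_r2"]
    top_groups = ranked["variant_id"].head(n_top_groups).tolist()
    row.update(enrichment_stats(top_groups, G, grouping))
    if bslmm_fn is not None:
        row["pve_bslmm"] = float(bslmm_fn(yp))
    return row


def null_percentiles(
    ensemble: NullEnsemble, stat: str, q: float
) -> np.ndarray | float:
    """Empirical percentile (linear/type-7 interpolation) of a null
    statistic; per-rank for ``prve`` and ``cum``."""
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    if stat in ("prve", "cum"):
        cols = ensemble.rank_columns(stat)
        return np.nanquantile(cols.to_numpy(), q, axis=0)
    return float(np.nanquantile(ensemble.table[stat].to_numpy(), q))
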