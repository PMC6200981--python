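"""Forward model selection, candidate calling, and enrichment statistics.

From the association scan's most strongly associated variants, a
forward-selection path of up to 25 predictors is built: at each rank
the variant maximizing the model R-squared joins the model.  Two
variance summaries are tracked per rank:

* ``cumulative_r2`` — the R-squared of the rank-r multiple regression;
* ``prve`` — the proportion of *remaining* variance explained at rank
  r, i.e. the R-squared of the phenotype residuals from the rank-(r-1)
  model on the newly chosen variant (orthogonalized against the
  previous selections), so that
  ``1 - cumulative_r2(r) = prod_{k<=r} (1 - prve(k))`` holds exactly.

Candidates are the leading path entries whose PRVE exceeds the
rank-matched 95th percentile of the permutation null; the total PVE of
top variants is the best cumulative R-squared after subtracting the
null median at the same rank, floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import UNPLACED, GenotypeMatrix
from .ld import GroupingResult

logger = logging.getLogger(__name__)

__all__ = ["SelectionPath", "CandidateSet", "forward_select",
           "call_candidates", "enrichment_stats", "enrichment_test",
           "annotate_candidates"]


@dataclass
class SelectionPath:
    """Ordered forward-selection result, one row per rank."""

    table: pd.DataFrame  # columns: rank, variant_id, cumulative_r2, prve

    @property
    def prve(self) -> np.ndarray:
        return self.table["prve"].to_numpy()

    @property
    def cumulative_r2(self) -> np.ndarray:
        return self.table["cumulative_r2"].to_numpy()

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()


@dataclass
class CandidateSet:
    trait: str
    candidate_ids: list[str]
    candidate_groups: dict[str, list[str]]  # candidate id -> full LD group
    stop_rank: int
    total_pve_top_variants: float


def forward_select(
    y: np.ndarray,
    Xcand: np.ndarray,
    candidate_ids: list[str],
    max_rank: int = 25,
) -> SelectionPath:
    """Greedy forward selection maximizing model R-squared.

    ``Xcand`` holds the (imputed) dosage columns of the candidate pool,
    ordered arbitrarily; selection order is determined by fit, not pool
    order.  Candidates collinear with the current model (no residual
    variance) are skipped.  Runs to ``max_rank`` or pool exhaustion.
    """
    y = np.asarray(y, dtype=float)
    Xcand = np.asarray(Xcand, dtype=float)
    if Xcand.ndim == 1:
        Xcand = Xcand[:, None]
    n, p = Xcand.shape
    if len(candidate_ids) != p:
        raise ValueError("candidate_ids length mismatch")
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("constant phenotype")

    # residualized candidate columns, updated in place as the model grows
    R = Xcand - Xcand.mean(axis=0)
    r = yc.copy()
    avail = np.ones(p, dtype=bool)
    rows = []
    cum = 0.0
    for rank in range(1, min(max_rank, p) + 1):
        norms = np.einsum("ij,ij->j", R, R)
        ok = avail & (norms > tss * 1e-12)
        if not ok.any():
            logger.info("forward_select: pool exhausted at rank %d", rank)
            break
        proj = R.T @ r
        gain = np.where(ok, proj**2 / np.where(norms > 0, norms, 1.0), -1.0)
        j = int(np.argmax(gain))
        q = R[:, j] / np.sqrt(norms[j])
        r = r - q * (q @ r)
        rss = float(r @ r)
        cum_new = 1.0 - rss / tss
        prve = (cum_new - cum) / (1.0 - cum) if cum < 1.0 else 0.0
        rows.append({
            "rank": rank,
            "variant_id": candidate_ids[j],
            "cumulative_r2": cum_new,
            "prve": min(max(prve, 0.0), 1.0),
        })
        cum = cum_new
        avail[j] = False
        # orthogonalize remaining candidates against the accepted one
        R = R - np.outer(q, q @ R)
    return SelectionPath(pd.DataFrame(rows))


def call_candidates(
    path: SelectionPath,
    null_prve_95: np.ndarray,
    null_cum_median: np.ndarray,
    grouping: GroupingResult | None = None,
    trait: str = "trait",
) -> CandidateSet:
    """Apply the stop-at-null rule and total-PVE rule.

    ``null_prve_95`` and ``null_cum_median`` are per-rank statistics of
    the permutation ensemble (length >= the path length).  Candidates
    are the path entries before the first rank whose PRVE falls below
    the rank-matched null 95th percentile; the reported total PVE of
    top variants is ``max_m(cumulative_r2(m) - null_median(m))``
    floored at 0.
    """
    prve = path.prve
    m = len(prve)
    if len(null_prve_95) < m or len(null_cum_median) < m:
        raise ValueError("null percentiles shorter than the selection path")
    stop = m + 1
    for r in range(m):
        if prve[r] < null_prve_95[r]:
            stop = r + 1
            break
    cand_ids = path.variant_ids[: stop - 1]
    groups: dict[str, list[str]] = {}
    if grouping is not None:
        by_seed = {g.seed_id: g.member_ids for g in grouping.groups}
        for vid in cand_ids:
            groups[vid] = list(by_seed.get(vid, [vid]))
    else:
        groups = {vid: [vid] for vid in cand_ids}
    total = float(np.max(path.cumulative_r2[:m] - null_cum_median[:m],
                         initial=0.0))
    return CandidateSet(
        trait=trait,
        candidate_ids=cand_ids,
        candidate_groups=groups,
        stop_rank=min(stop, m + 1),
        total_pve_top_variants=max(total, 0.0),
    )


def enrichment_stats(
    top_seed_ids: list[str],
    G: GenotypeMatrix,
    grouping: GroupingResult,
) -> dict[str, float]:
    """Composition statistics of the LD groups most strongly associated
    with a trait (normally the top 10 by seed p-value).

    Returns flat means over member variants (``mean_maf``) and over
    groups (``mean_group_size``, ``snp_proportion``); an ungrouped
    variant counts as a group of size 1, and a mixed group contributes
    its within-group SNP fraction (fractional counting).  A variant-wise
    SNP proportion is also reported since the group-wise and
    variant-wise conventions differ when group sizes vary.
    """
    by_seed = {g.seed_id: g.member_ids for g in grouping.groups}
    v = G.variant_table().set_index("id")
    mafs: list[float] = []
    sizes: list[int] = []
    snp_fracs: list[float] = []
    n_snp_members = 0
    n_members = 0
    for sid in top_seed_ids:
        members = by_seed.get(sid, [sid])
        sub = v.loc[members]
        mafs.extend(sub["maf"].tolist())
        sizes.append(len(members))
        is_snp = (sub["vtype"] == "SNP").to_numpy()
        snp_fracs.append(float(is_snp.mean()))
        n_snp_members += int(is_snp.sum())
        n_members += len(members)
    return {
        "mean_maf": float(np.mean(mafs)),
        "mean_group_size": float(np.mean(sizes)),
        "snp_proportion": float(np.mean(snp_fracs)),
        "snp_proportion_variantwise": n_snp_members / n_members,
    }


def enrichment_test(
    real_stats: dict[str, float],
    null_table: pd.DataFrame,
    direction: str = "greater",
) -> dict[str, float]:
    """Empirical p-value per statistic with add-one correction:
    ``p = (#{null >= real} + 1) / (n + 1)`` for the 'greater'
    direction."""
    out = {}
    for key, real in real_stats.items():
        if key not in null_table.columns:
            continue
        null = null_table[key].to_numpy()
        if direction == "greater":
            r = int((null >= real).sum())
        else:
            r = int((null <= real).sum())
        out[key] = (r + 1) / (len(null) + 1)
    return out


def _read_gff_genes(gff_path: str) -> dict[str, list[tuple[int, int, str]]]:
    genes: dict[str, list] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2].lower() not in ("gene", "cds"):
                continue
            rep, start, end, attrs = parts[0], int(parts[3]), int(parts[4]), parts[8]
            label = ""
            for field_ in attrs.split(";"):
                if field_.startswith(("ID=", "Name=", "locus_tag=")):
                    label = field_.split("=", 1)[1]
                    break
            genes.setdefault(rep, []).append((start, end, label or attrs))
    return genes


def annotate_candidates(
    cands: CandidateSet,
    G: GenotypeMatrix,
    gff_path: str,
) -> pd.DataFrame:
    """Map every member variant of the called LD groups to the gene
    interval containing it (1-based, inclusive) or 'intergenic';
    unplaced PAVs are reported without coordinates."""
    from intervaltree import IntervalTree

    genes = _read_gff_genes(gff_path)
    trees = {rep: IntervalTree() for rep in genes}
    for rep, lst in genes.items():
        for start, end, label in lst:
            trees[rep][start : end + 1] = label  # inclusive end

    v = G.variants.set_index("id")
    known_reps = set(trees) | {UNPLACED}
    member_reps = {
        str(v.loc[m, "replicon"])
        for ids in cands.candidate_groups.values()
        for m in ids
    }
    missing = member_reps - known_reps
    if missing:
        raise ValueError(
            f"replicons absent from GFF: {sorted(missing)}"
        )
    rows = []
    for cid in cands.candidate_ids:
        for m in cands.candidate_groups[cid]:
            rep = str(v.loc[m, "replicon"])
            pos = v.loc[m, "position"]
            if rep == UNPLACED or pd.isna(pos):
                rows.append({"trait": cands.trait, "variant_id": m,
                             "replicon": rep, "position": pd.NA,
                             "annotation": m if v.loc[m, "vtype"] == "PAV"
                             else "unplaced"})
                continue
            hits = trees[rep][int(pos)] if rep in trees else set()
            ann = ";".join(sorted(h.data for h in hits)) if hits else "intergenic"
            rows.append({"trait": cands.trait, "variant_id": m,
                         "replicon": rep, "position": int(pos),
                         "annotation": ann})
    return pd.DataFrame(rows,
                        columns=["trait", "variant_id", "replicon",
                                 "position", "annotation"])
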