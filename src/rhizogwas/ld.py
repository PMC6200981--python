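"""Greedy MAF-seeded linkage-disequilibrium grouping.

Variants in strong LD are statistically indistinguishable in
association tests, so the pipeline collapses them into groups before
testing: repeatedly take the ungrouped variant with the highest MAF
(ties broken by fewest missing calls, then input order) as a *seed*,
and group with it every ungrouped variant whose squared correlation
with the seed reaches the threshold.  Only seeds (plus variants that
matched nothing) are carried into association testing; the full group
membership is kept for annotation.

r-squared is computed on pairwise-complete strains; a pair with fewer
than two complete observations, or with a constant column on the
complete set, has undefined r-squared and never joins a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import UNPLACED, GenotypeMatrix

__all__ = ["LDGroup", "GroupingResult", "pairwise_r2", "build_groups",
           "annotate_groups", "seed_set"]


@dataclass
class LDGroup:
    group_id: int
    seed_id: str
    member_ids: list[str]  # includes the seed; length >= 2
    composition: str | None = None  # snp_only | pav_only | mixed
    replicons: frozenset | None = None
    spanned_bp: int | None = None


@dataclass
class GroupingResult:
    groups: list[LDGroup]
    ungrouped_ids: list[str]
    threshold: float
    summary: pd.DataFrame | None = None


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over
    pairwise-complete strains.

    Returns ``nan`` when fewer than two complete pairs exist, and 0.0
    (by contract) when either column is constant on the complete set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def _r2_vs_all(dosage: np.ndarray, j: int, cols: np.ndarray) -> np.ndarray:
    """Pairwise-complete r2 between column j and each column in ``cols``.

    Vectorized over candidate columns with masked matrix products.
    """
    x = dosage[:, j]
    mx = ~np.isnan(x)
    Y = dosage[:, cols]
    MY = ~np.isnan(Y)
    M = MY & mx[:, None]
    Y0 = np.where(M, Y, 0.0)
    x0 = np.where(mx, x, 0.0)
    n = M.sum(axis=0).astype(float)
    sx = x0 @ M
    sy = Y0.sum(axis=0)
    sxx = (x0 * x0) @ M
    syy = (Y0 * Y0).sum(axis=0)
    sxy = x0 @ Y0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2[(vx <= 0) | (vy <= 0)] = 0.0  # constant on complete set: contract 0
    r2[n < 2] = np.nan  # undefined
    return r2


def build_groups(G: GenotypeMatrix, threshold: float = 0.95) -> GroupingResult:
    """Run the greedy grouping over all variants of ``G``.

    Groups and ungrouped variants partition the variant universe; each
    group member has r2 >= threshold with its seed.  Deterministic
    under the MAF / missingness / input-order tie-break.
    """
    p = G.n_variants
    maf = np.nan_to_num(G.maf(), nan=-1.0)
    n_missing = np.isnan(G.dosage).sum(axis=0)
    # seed priority: highest MAF, then fewest missing, then input order
    order = np.lexsort((np.arange(p), n_missing, -maf))
    ids = G.variants["id"].to_numpy()

    ungrouped = np.ones(p, dtype=bool)
    groups: list[LDGroup] = []
    single: list[str] = []
    for j in order:
        if not ungrouped[j]:
            continue
        ungrouped[j] = False
        cand = np.flatnonzero(ungrouped)
        if len(cand):
            r2 = _r2_vs_all(G.dosage, j, cand)
            hits = cand[np.where(np.isnan(r2), False, r2 >= threshold)]
        else:
            hits = np.array([], dtype=int)
        if len(hits) == 0:
            single.append(ids[j])
            continue
        ungrouped[hits] = False
        groups.append(
            LDGroup(
                group_id=len(groups) + 1,
                seed_id=ids[j],
                member_ids=[ids[j]] + list(ids[hits]),
            )
        )
    return GroupingResult(groups=groups, ungrouped_ids=single,
                          threshold=threshold)


def annotate_groups(result: GroupingResult, G: GenotypeMatrix) -> GroupingResult:
    """Fill per-group composition, replicon set and spanned distance,
    and attach a summary table.

    Spanned distance (max - min SNP position) is defined only for
    groups whose SNP members all lie on a single replicon.
    """
    v = G.variants.set_index("id")
    for g in result.groups:
        sub = v.loc[g.member_ids]
        types = set(sub["vtype"])
        g.composition = (
            "mixed" if types == {"SNP", "PAV"}
            else "snp_only" if types == {"SNP"} else "pav_only"
        )
        g.replicons = frozenset(sub["replicon"])
        snps = sub[sub["vtype"] == "SNP"]
        if len(snps) and snps["replicon"].nunique() == 1:
            pos = snps["position"].astype(int)
            g.spanned_bp = int(pos.max() - pos.min())
        else:
            g.spanned_bp = None

    rows = []
    sizes = np.array([len(g.member_ids) for g in result.groups])
    comp = pd.Series([g.composition for g in result.groups])
    rows.append({
        "statistic": "n_groups", "value": len(result.groups)})
    rows.append({"statistic": "n_ungrouped", "value": len(result.ungrouped_ids)})
    if len(sizes):
        rows.append({"statistic": "median_group_size",
                     "value": float(np.median(sizes))})
        rows.append({"statistic": "max_group_size", "value": int(sizes.max())})
    for c in ("snp_only", "pav_only", "mixed"):
        rows.append({"statistic": f"n_groups_{c}", "value": int((comp == c).sum())})
    # median spanned distance per replicon (single-replicon SNP groups)
    for rep in sorted({r for g in result.groups for r in (g.replicons or ())}):
        spans = [g.spanned_bp for g in result.groups
                 if g.spanned_bp is not None and g.replicons == frozenset({rep})]
        if spans:
            rows.append({"statistic": f"median_spanned_bp_{rep}",
                         "value": float(np.median(spans))})
    result.summary = pd.DataFrame(rows)
    return result


def seed_set(result: GroupingResult) -> list[str]:
    """Variant ids carried into association testing: one seed per
    group plus every ungrouped variant."""
    return [g.seed_id for g in result.groups] + list(result.ungrouped_ids)


def group_of_variant(result: GroupingResult) -> dict[str, int]:
    """Map variant id -> group id (ungrouped variants map to 0)."""
    out = {vid: 0 for vid in result.ungrouped_ids}
    for g in result.groups:
        for vid in g.member_ids:
            out[vid] = g.group_id
    return out


def write_membership(result: GroupingResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tis_seed\tvariant_id\n")
        for g in result.groups:
            for vid in g.member_ids:
                fh.write(f"{g.group_id}\t{int(vid == g.seed_id)}\t{vid}\n")
        for vid in result.ungrouped_ids:
            fh.write(f"0\t1\t{vid}\n")
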