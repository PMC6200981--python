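"""End-to-end orchestration: config, staging, outputs, report data.

A run reads genotypes (VCF + PAV table) and phenotypes, applies the
MAF/missingness filters, computes per-replicon diversity, builds LD
groups, and then per trait: kinship-based chip heritability, the
seed-variant association scan, optional BSLMM, the permutation null
ensemble, forward-selection candidate calling, enrichment statistics
and (with a GFF3) candidate gene annotation.  All outputs are TSV/JSON
under one output directory; a manifest records the configuration,
seeds and per-stage row counts.  Reruns with the same config and
master seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bslmm as bslmm_mod
from .diversity import replicon_diversity
from .genotypes import (
    GenotypeMatrix,
    filter_variants,
    mean_impute,
    read_pav,
    read_phenotypes,
    read_vcf,
    write_variant_table,
)
from .ld import annotate_groups, build_groups, group_of_variant, seed_set, write_membership
from .lmm import assoc_scan, fit_null, qq_diagnostics
from .permutation import build_null, null_percentiles
from .selection import (
    annotate_candidates,
    call_candidates,
    enrichment_stats,
    enrichment_test,
    forward_select,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    vcf: str | None = None
    pav: str | None = None
    phenotypes: str | None = None
    gff: str | None = None
    replicon_lengths: dict = field(default_factory=dict)  # for diversity
    out_dir: str = "rhizogwas_out"
    maf_min: float = 0.05
    missing_max: float = 0.20
    r2_thresholds: tuple = (0.95, 0.80)
    n_perms: int = 100
    max_rank: int = 25
    top_k_candidates: int = 100
    n_top_groups: int = 10
    run_bslmm: bool = False
    bslmm: bslmm_mod.BslmmConfig = field(default_factory=bslmm_mod.BslmmConfig)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bs = raw.pop("bslmm", None)
        cfg = cls(**raw)
        if bs:
            cfg.bslmm = bslmm_mod.BslmmConfig(**bs)
        return cfg

    def validate(self) -> None:
        for p in (self.vcf, self.pav, self.phenotypes, self.gff):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not (0 <= self.maf_min <= 0.5 and 0 <= self.missing_max <= 1):
            raise ValueError("filter thresholds out of range")
        for t in self.r2_thresholds:
            if not 0 < t <= 1:
                raise ValueError("r2 thresholds must be in (0, 1]")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_genotypes(config: PipelineConfig) -> GenotypeMatrix:
    parts = []
    if config.vcf:
        parts.append(read_vcf(config.vcf))
    if config.pav:
        parts.append(read_pav(config.pav))
    if not parts:
        raise ValueError("need at least one of vcf / pav inputs")
    G = parts[0]
    for extra in parts[1:]:
        G = G.concat_variants(extra)
    return G


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "master_seed": config.master_seed,
        "stages": {},
    }

    def stage(name):
        t0 = time.time()
        logger.info("stage %s: start", name)

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 2), **counts}
            logger.info("stage %s: done in %.1fs %s", name,
                        time.time() - t0, counts)
        return done

    # --- load & filter -------------------------------------------------
    done = stage("load_filter")
    G_raw = _load_genotypes(config)
    G = filter_variants(G_raw, config.maf_min, config.missing_max)
    write_variant_table(G, out / "variants_filtered.tsv")
    done(n_raw=G_raw.n_variants, n_filtered=G.n_variants,
         n_strains=G.n_strains)

    # --- diversity ------------------------------------------------------
    if config.replicon_lengths:
        done = stage("diversity")
        div = replicon_diversity(G_raw, config.replicon_lengths)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        done(n_replicons=len(div))

    # --- LD grouping (first threshold drives association) ---------------
    groupings = {}
    summary_rows = []
    for thr in config.r2_thresholds:
        done = stage(f"ld_grouping_r2_{thr}")
        res = annotate_groups(build_groups(G, thr), G)
        groupings[thr] = res
        write_membership(res, out / f"ld_groups_r2_{thr}.tsv")
        s = res.summary.set_index("statistic")["value"].to_dict()
        summary_rows.append({"r2_threshold": thr, **s})
        done(n_groups=len(res.groups), n_ungrouped=len(res.ungrouped_ids))
    pd.DataFrame(summary_rows).to_csv(out / "ld_summary.tsv", sep="\t",
                                      index=False)
    primary = groupings[config.r2_thresholds[0]]
    seeds = seed_set(primary)
    gmap = group_of_variant(primary)

    # --- per-trait analyses ---------------------------------------------
    pheno = read_phenotypes(config.phenotypes) if config.phenotypes else None
    if pheno is None:
        manifest["traits"] = []
        _write_manifest(manifest, out)
        return manifest

    id_pos = {v: j for j, v in enumerate(G.variants["id"])}
    trait_reports = []
    for t_idx, trait in enumerate(pheno.columns):
        done = stage(f"trait_{trait}")
        y_all = pheno[trait]
        keep = [s for s in G.strain_ids if s in y_all.index
                and np.isfinite(y_all[s])]
        Gt = G.take_strains(keep)
        y = y_all.loc[keep].to_numpy(dtype=float)
        Ximp = mean_impute(Gt)
        # drop variants made constant by strain subsetting from K and scan
        nonconst = Ximp.std(axis=0) > 0
        from .lmm import kinship as _kin

        K = _kin(Ximp[:, nonconst])
        null_fit = fit_null(y, K)
        seeds_t = [s for s in seeds if nonconst[id_pos[s]]]
        Xseed = Ximp[:, [id_pos[s] for s in seeds_t]]
        scan = assoc_scan(y, K, Xseed, variant_ids=seeds_t, null=null_fit)
        scan["group_id"] = [gmap.get(v, 0) for v in scan["variant_id"]]
        scan.to_csv(out / f"assoc_{trait}.tsv", sep="\t", index=False)
        qq, inflation = qq_diagnostics(scan)
        qq.to_csv(out / f"qq_{trait}.tsv", sep="\t", index=False)

        report = {
            "trait": trait,
            "n_strains": len(keep),
            "pve_lmm": null_fit.pve.estimate,
            "pve_lmm_interval": list(null_fit.pve.interval),
            "inflation_factor": inflation,
        }

        bslmm_fn = None
        if config.run_bslmm:
            cfg_b = bslmm_mod.BslmmConfig(
                **{**asdict(config.bslmm),
                   "seed": config.master_seed + 1000 * (t_idx + 1)})
            post = bslmm_mod.run_bslmm(y, Ximp[:, nonconst], K, cfg_b)
            post.trace.to_csv(out / f"bslmm_trace_{trait}.tsv", sep="\t",
                              index=False)
            est = bslmm_mod.pve_summary(post, min_records=10)
            report["pve_bslmm"] = est.estimate
            report["pve_bslmm_interval"] = list(est.interval)
            report["bslmm_converged"] = post.converged

            def bslmm_fn(yp, _X=Ximp[:, nonconst], _K=K, _cfg=cfg_b):
                post_p = bslmm_mod.run_bslmm(yp, _X, _K, _cfg)
                return bslmm_mod.pve_summary(post_p, min_records=10).estimate

        ranked = scan.dropna(subset=["p_lrt"]).sort_values("p_lrt")
        pool = ranked.head(config.top_k_candidates)
        pool_cols = [seeds_t.index(v) for v in pool["variant_id"]]
        path = forward_select(y, Xseed[:, pool_cols],
                              pool["variant_id"].tolist(),
                              max_rank=config.max_rank)
        path.table.to_csv(out / f"selection_path_{trait}.tsv", sep="\t",
                          index=False)
        top_groups = ranked["variant_id"].head(config.n_top_groups).tolist()
        real_enrich = enrichment_stats(top_groups, Gt, primary)

        if config.n_perms > 0:
            ens = build_null(
                y, Gt, K, primary, Ximp, seeds_t,
                n_perms=config.n_perms,
                master_seed=config.master_seed + 10_000 * (t_idx + 1),
                max_rank=config.max_rank, top_k=config.top_k_candidates,
                n_top_groups=config.n_top_groups,
                bslmm_fn=bslmm_fn if config.run_bslmm else None,
            )
            ens.table.to_csv(out / f"null_ensemble_{trait}.tsv", sep="\t",
                             index=False)
            m = len(path.table)
            prve95 = np.atleast_1d(null_percentiles(ens, "prve", 0.95))[:m]
            cum50 = np.atleast_1d(null_percentiles(ens, "cum", 0.50))[:m]
            # pad if the null paths were shorter than the real path
            prve95 = np.pad(prve95, (0, m - len(prve95)))
            cum50 = np.pad(cum50, (0, m - len(cum50)))
            cands = call_candidates(path, prve95, cum50, primary, trait)
            report["n_candidates"] = len(cands.candidate_ids)
            report["stop_rank"] = cands.stop_rank
            report["total_pve_top_variants"] = cands.total_pve_top_variants
            report["pve_lmm_null_95"] = null_percentiles(ens, "pve_lmm", 0.95)
            report["signal_beyond_null"] = bool(cands.candidate_ids)
            enrich_p = enrichment_test(real_enrich, ens.table)
            pd.DataFrame([{**real_enrich,
                           **{f"p_{k}": v for k, v in enrich_p.items()}}]
                         ).to_csv(out / f"enrichment_{trait}.tsv", sep="\t",
                                  index=False)
            cand_rows = [{"trait": trait, "rank": i + 1, "variant_id": v,
                          "group_id": gmap.get(v, 0),
                          "group_members": ",".join(cands.candidate_groups[v])}
                         for i, v in enumerate(cands.candidate_ids)]
            pd.DataFrame(cand_rows, columns=["trait", "rank", "variant_id",
                                             "group_id", "group_members"]
                         ).to_csv(out / f"candidates_{trait}.tsv", sep="\t",
                                  index=False)
            if config.gff and cands.candidate_ids:
                ann = annotate_candidates(cands, Gt, config.gff)
                ann.to_csv(out / f"candidate_annotation_{trait}.tsv",
                           sep="\t", index=False, na_rep="NA")
            # chart-ready PRVE-vs-null data
            chart = path.table.copy()
            chart["null_prve_95"] = prve95
            chart["null_cum_median"] = cum50
            chart.to_csv(out / f"prve_chart_{trait}.tsv", sep="\t",
                         index=False)
        else:
            logger.warning(
                "trait %s: n_perms=0, candidate calling skipped (no "
                "empirical null available)", trait)
            report["n_candidates"] = None
            report["note"] = "candidate calling skipped: no permutations"

        trait_reports.append(report)
        done(n_seeds_tested=len(seeds_t))

    manifest["traits"] = trait_reports
    pd.DataFrame(trait_reports).to_csv(out / "trait_summary.tsv", sep="\t",
                                       index=False)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)


def make_report(out_dir: str) -> list[str]:
    """Render summary figures from a completed run's TSV outputs.

    Returns the list of files written.  Chart data are already emitted
    as TSV during the run; this adds rendered PNGs for quick viewing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []
    for chart in sorted(out.glob("prve_chart_*.tsv")):
        trait = chart.stem.replace("prve_chart_", "")
        df = pd.read_csv(chart, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.vlines(df["rank"], 0, df["null_prve_95"], color="0.7", lw=4,
                  label="null 95th pct")
        ax.plot(df["rank"], df["prve"], "ko-", ms=4, label="observed PRVE")
        ax.set_xlabel("variant rank (forward selection)")
        ax.set_ylabel("proportion of remaining variance")
        ax.set_title(trait)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = out / f"prve_{trait}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    for qqf in sorted(out.glob("qq_*.tsv")):
        trait = qqf.stem.replace("qq_", "")
        df = pd.read_csv(qqf, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(df["expected_neglog10p"], df["observed_neglog10p"], "k.",
                ms=3)
        lim = max(df["expected_neglog10p"].max(),
                  df["observed_neglog10p"].max())
        ax.plot([0, lim], [0, lim], "r--", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(trait)
        fig.tight_layout()
        path = out / f"qqplot_{trait}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
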