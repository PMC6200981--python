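"""Per-replicon nucleotide diversity: Watterson's theta and pairwise pi.

Both estimators are reported per base pair of callable sequence and
adjust for missing data site by site: each segregating site contributes
with the sample size actually observed there.  The callable length L is
an input (how many bp had adequate coverage is determined upstream of
variant calling and is not recomputed here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["DiversityResult", "watterson_theta", "theta_pi",
           "replicon_diversity"]


@dataclass
class DiversityResult:
    replicon: str
    n_sites_callable: int
    S: int
    theta_w: float
    theta_pi: float


def _harmonic(n: np.ndarray) -> np.ndarray:
    """a(n) = sum_{i=1}^{n-1} 1/i, vectorized over per-site sample sizes."""
    n = np.asarray(n, dtype=int)
    if (n < 2).any():
        raise ValueError("every counted site needs >= 2 called strains")
    top = int(n.max())
    cum = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, top))])
    return cum[n - 1]


def watterson_theta(S: int, n_by_site: np.ndarray, L: float) -> float:
    """Watterson's estimator per bp with per-site sample sizes.

    theta_W = sum_sites 1/a(n_s) / L over the S segregating sites;
    ``n_by_site`` holds the number of non-missing calls at each of
    those sites.  Monomorphic callable sites enter only through L.
    """
    if L <= 0:
        raise ValueError("callable length L must be positive")
    n_by_site = np.asarray(n_by_site)
    if S != len(n_by_site):
        raise ValueError("n_by_site must have one entry per segregating site")
    if S == 0:
        return 0.0
    return float(np.sum(1.0 / _harmonic(n_by_site)) / L)


def theta_pi(dosage: np.ndarray, L: float) -> float:
    """Pairwise nucleotide diversity per bp.

    Per site with n_s non-missing calls and alt frequency p,
    pi_s = 2 p (1-p) n_s/(n_s - 1) (the unbiased mean pairwise
    difference); theta_pi = sum_s pi_s / L.  Fixed sites contribute 0.
    """
    if L <= 0:
        raise ValueError("callable length L must be positive")
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim == 1:
        dosage = dosage[:, None]
    obs = ~np.isnan(dosage)
    n_s = obs.sum(axis=0)
    if (n_s < 2).any():
        raise ValueError("every site needs >= 2 non-missing calls")
    p = np.nansum(dosage, axis=0) / n_s
    pi_s = 2.0 * p * (1.0 - p) * n_s / (n_s - 1.0)
    return float(pi_s.sum() / L)


def replicon_diversity(
    G: GenotypeMatrix, callable_lengths: dict[str, float]
) -> pd.DataFrame:
    """Diversity summary with one row per replicon carrying SNPs.

    ``callable_lengths`` maps replicon name to callable bp; replicons
    without an entry are skipped.  PAVs are excluded (they are not
    nucleotide variants).
    """
    rows = []
    snp = G.take_variants((G.variants["vtype"] == "SNP").to_numpy())
    for rep, L in callable_lengths.items():
        sub = snp.take_variants((snp.variants["replicon"] == rep).to_numpy())
        if sub.n_variants == 0:
            rows.append(DiversityResult(rep, int(L), 0, 0.0, 0.0))
            continue
        maf = sub.maf()
        seg = np.flatnonzero(maf > 0)
        n_by_site = (~np.isnan(sub.dosage[:, seg])).sum(axis=0)
        tw = watterson_theta(len(seg), n_by_site, L)
        tp = theta_pi(sub.dosage[:, seg], L) if len(seg) else 0.0
        rows.append(DiversityResult(rep, int(L), int(len(seg)), tw, tp))
    return pd.DataFrame([r.__dict__ for r in rows])
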