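"""Linear mixed model machinery: kinship, chip heritability, association.

Model: ``y = X b + g + e`` with ``g ~ N(0, sigma_g^2 K)`` and
``e ~ N(0, sigma_e^2 I)``.  After one eigendecomposition ``K = U D U'``
the covariance is diagonal in the rotated basis, so the likelihood
profile over the variance ratio ``lambda = sigma_g^2 / sigma_e^2``
costs O(n) per evaluation.  ``lambda`` is optimized by bounded Brent
search on log10(lambda) in [-5, 5], multi-started over 10 equal
subintervals to guard against multimodal profiles.

Conventions:

* likelihood-ratio association tests use ML likelihoods (the
  alternative model adds one fixed effect; the statistic is referred
  to chi-square with 1 df);
* the null-model chip-heritability PVE uses REML, reported as
  ``PVE = lambda * dbar / (lambda * dbar + 1)`` where ``dbar`` is the
  mean diagonal of K (exactly 1 for a standardized kinship, making PVE
  the genetic fraction of phenotypic variance);
* binary traits are analyzed as 0/1 quantitative values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["kinship", "fit_null", "assoc_scan", "qq_diagnostics",
           "PVEEstimate", "NullModelFit", "AssocResult"]

_LOG10_BOUNDS = (-5.0, 5.0)
_N_STARTS = 10


def kinship(Ximp: np.ndarray) -> np.ndarray:
    """Standardized kinship: columns centered and scaled to unit
    (population) variance, then ``K = Z Z' / p``.

    Every column must be non-constant (guaranteed after MAF
    filtering + imputation).  The mean diagonal of the result is
    exactly 1.
    """
    X = np.asarray(Ximp, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("kinship requires non-constant variant columns")
    Z = (X - mu) / sd
    return Z @ Z.T / X.shape[1]


@dataclass
class PVEEstimate:
    method: str
    estimate: float
    interval: tuple[float, float]  # central/profile 95% interval
    note: str = ""


@dataclass
class NullModelFit:
    lambda_ml: float
    loglik_ml: float
    lambda_reml: float
    pve: PVEEstimate
    # eigen cache reused by assoc_scan
    eigenvalues: np.ndarray = field(repr=False, default=None)
    U: np.ndarray = field(repr=False, default=None)
    yt: np.ndarray = field(repr=False, default=None)
    ones_t: np.ndarray = field(repr=False, default=None)
    dbar: float = 1.0


def _profile_loglik(lam: float, d: np.ndarray, yt: np.ndarray,
                    Xt: np.ndarray, reml: bool) -> float:
    v = lam * d + 1.0
    Xv = Xt / v[:, None]
    A = Xt.T @ Xv
    b = Xv.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = yt - Xt @ beta
    rss = float(np.sum(resid * resid / v))
    if rss <= 0:
        return np.inf
    n, c = Xt.shape
    logdv = float(np.sum(np.log(v)))
    if reml:
        df = n - c
        s2 = rss / df
        _, ldA = np.linalg.slogdet(A)
        _, ldX = np.linalg.slogdet(Xt.T @ Xt)
        return -0.5 * (df * np.log(2 * np.pi * s2) + df + logdv + ldA - ldX)
    s2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * s2) + n + logdv)


def _optimize_lambda(d, yt, Xt, reml):
    """Maximize the profile likelihood over log10(lambda).

    The search region [-5, 5] is scanned on a grid covering the 10
    subintervals (guarding against multimodal profiles), then refined
    by bounded Brent search around the best grid point.
    """
    lo, hi = _LOG10_BOUNDS
    grid = np.linspace(lo, hi, 2 * _N_STARTS + 1)
    lls = np.array([
        _profile_loglik(10.0 ** t, d, yt, Xt, reml) for t in grid
    ])
    b = int(np.nanargmax(lls))
    a = grid[max(b - 1, 0)]
    c = grid[min(b + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(10.0 ** t, d, yt, Xt, reml),
        bounds=(a, c), method="bounded", options={"xatol": 1e-6},
    )
    if -res.fun >= lls[b]:
        return 10.0 ** float(res.x), float(-res.fun)
    return 10.0 ** grid[b], float(lls[b])


def _gls_beta_se(lam, d, yt, Xt, reml=False):
    v = lam * d + 1.0
    Xv = Xt / v[:, None]
    A = Xt.T @ Xv
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (Xv.T @ yt)
    resid = yt - Xt @ beta
    rss = float(np.sum(resid * resid / v))
    n, c = Xt.shape
    s2 = rss / (n - c if reml else n)
    se = np.sqrt(np.diag(Ainv) * s2)
    return beta, se


def fit_null(y: np.ndarray, K: np.ndarray) -> NullModelFit:
    """Fit the intercept-only mixed model and estimate chip heritability.

    Returns the ML variance-ratio optimum and log-likelihood (the
    reference point for association LRTs) plus the REML-based PVE with
    a profile-likelihood 95% interval.  A near-unstructured K makes the
    genetic and residual components indistinguishable; this is flagged
    through a wide interval and a warning note rather than an error.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    n = len(y)
    if n < 10:
        raise ValueError("need >= 10 strains with phenotype")
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("K not conformable with phenotype")
    d, U = np.linalg.eigh((K + K.T) / 2)
    d = np.clip(d, 0.0, None)
    dbar = float(np.trace(K) / n)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    Xt = ones_t[:, None]

    if y.std() == 0:
        warnings.warn("constant phenotype: PVE set to 0", stacklevel=2)
        pve = PVEEstimate("lmm", 0.0, (0.0, 0.0), note="constant phenotype")
        return NullModelFit(0.0, -np.inf, 0.0, pve, d, U, yt, ones_t, dbar)

    lam_ml, ll_ml = _optimize_lambda(d, yt, Xt, reml=False)
    lam_reml, ll_reml = _optimize_lambda(d, yt, Xt, reml=True)

    def to_pve(lam):
        return lam * dbar / (lam * dbar + 1.0)

    # profile 95% interval on a log10(lambda) grid (chi2_1/2 cutoff)
    grid = np.linspace(*_LOG10_BOUNDS, 201)
    prof = np.array([
        _profile_loglik(10.0 ** t, d, yt, Xt, reml=True) for t in grid
    ])
    keep = prof >= ll_reml - stats.chi2.ppf(0.95, 1) / 2
    lam_keep = 10.0 ** grid[keep]
    interval = (float(to_pve(lam_keep.min())), float(to_pve(lam_keep.max())))
    note = ""
    if interval[1] - interval[0] > 0.9:
        note = "PVE weakly identified (K has little structure or n small)"
        warnings.warn(note, stacklevel=2)
    pve = PVEEstimate("lmm", float(to_pve(lam_reml)), interval, note=note)
    return NullModelFit(lam_ml, ll_ml, lam_reml, pve, d, U, yt, ones_t, dbar)


@dataclass
class AssocResult:
    variant_id: str
    beta: float
    se: float
    lambda_hat: float
    lrt_stat: float
    p_lrt: float
    testable: bool = True


def assoc_scan(
    y: np.ndarray,
    K: np.ndarray,
    Ximp: np.ndarray,
    variant_ids: list[str] | None = None,
    null: NullModelFit | None = None,
) -> pd.DataFrame:
    """Single-variant LMM scan with likelihood-ratio tests.

    ``Ximp`` holds the (mean-imputed) dosage columns to test — in the
    standard pipeline, only LD-group seeds.  The variance ratio is
    re-optimized per variant; the LRT compares against the shared
    intercept-only ML fit.  Constant columns are reported untestable
    (NaN statistics) rather than dropped, preserving alignment.
    """
    y = np.asarray(y, dtype=float)
    Ximp = np.asarray(Ximp, dtype=float)
    if Ximp.ndim == 1:
        Ximp = Ximp[:, None]
    p = Ximp.shape[1]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(p)]
    if null is None or null.U is None:
        null = fit_null(y, K)
    d, U, yt, ones_t = null.eigenvalues, null.U, null.yt, null.ones_t
    Xt_all = U.T @ Ximp

    # coarse stage, vectorized across variants: profile ML log-likelihood
    # on the log10(lambda) grid for every variant at once (2x2 GLS in
    # closed form), keeping the best grid point per variant
    n = len(yt)
    grid = np.linspace(*_LOG10_BOUNDS, 2 * _N_STARTS + 1)
    best_ll = np.full(p, -np.inf)
    best_t = np.zeros(p, dtype=int)
    for gi, tval in enumerate(grid):
        v = (10.0 ** tval) * d + 1.0
        w = 1.0 / v
        a11 = float(ones_t @ (w * ones_t))
        a12 = (w * ones_t) @ Xt_all
        a22 = np.einsum("ij,ij->j", Xt_all, w[:, None] * Xt_all)
        b1 = float(ones_t @ (w * yt))
        b2 = (w * yt) @ Xt_all
        det = a11 * a22 - a12 * a12
        with np.errstate(invalid="ignore", divide="ignore"):
            beta0 = (a22 * b1 - a12 * b2) / det
            beta1 = (a11 * b2 - a12 * b1) / det
            rss = float(yt @ (w * yt)) - (beta0 * b1 + beta1 * b2)
            ll = -0.5 * (n * np.log(2 * np.pi * rss / n) + n
                         + np.sum(np.log(v)))
        upd = np.isfinite(ll) & (ll > best_ll)
        best_ll[upd] = ll[upd]
        best_t[upd] = gi

    rows = []
    for j in range(p):
        x = Ximp[:, j]
        if np.ptp(x) == 0:
            rows.append(AssocResult(variant_ids[j], np.nan, np.nan, np.nan,
                                    np.nan, np.nan, testable=False))
            continue
        Xt = np.column_stack([ones_t, Xt_all[:, j]])
        a = grid[max(best_t[j] - 1, 0)]
        c = grid[min(best_t[j] + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -_profile_loglik(10.0 ** t, d, yt, Xt, False),
            bounds=(a, c), method="bounded", options={"xatol": 1e-6},
        )
        if -res.fun >= best_ll[j]:
            lam, ll = 10.0 ** float(res.x), float(-res.fun)
        else:
            lam, ll = 10.0 ** grid[best_t[j]], float(best_ll[j])
        lrt = max(0.0, 2.0 * (ll - null.loglik_ml))
        pval = float(stats.chi2.sf(lrt, 1))
        beta, se = _gls_beta_se(lam, d, yt, Xt)
        rows.append(AssocResult(variant_ids[j], float(beta[1]), float(se[1]),
                                lam, lrt, max(pval, np.nextafter(0, 1))))
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["rank"] = df["p_lrt"].rank(method="first").astype("Int64")
    return df


def qq_diagnostics(results: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10 p quantiles and the genomic
    inflation factor (median LRT statistic / 0.456, the chi-square_1
    median)."""
    p = results["p_lrt"].dropna().to_numpy()
    if len(p) < 10:
        raise ValueError("need >= 10 tested variants for QQ diagnostics")
    obs = np.sort(p)
    m = len(obs)
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame({
        "expected_neglog10p": -np.log10(expected),
        "observed_neglog10p": -np.log10(obs),
    })
    chi = stats.chi2.isf(p, 1)
    inflation = float(np.median(chi) / stats.chi2.ppf(0.5, 1))
    return qq, inflation
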