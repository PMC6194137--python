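"""Univariate linear-mixed-model association scan.

Model per SNP:  y = mu + x beta + u + e,  u ~ N(0, sg^2 K), e ~ N(0, se^2 I).
K is eigendecomposed once; for each SNP the restricted likelihood is
profiled over lambda = sg^2/se^2 by a vectorized grid + golden-section
search on log(lambda) over [1e-5, 1e5].  The Wald statistic (beta/se)^2 is
referred to F(1, n-2), which makes the scan collapse exactly onto ordinary
least squares when K = I and lambda -> 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from haplopop.types import GenotypeMatrix

log = logging.getLogger(__name__)

LOG_LAMBDA_RANGE = (-5.0, 5.0)  # log10 bounds of the variance-ratio search


@dataclass
class RelatednessMatrix:
    K: np.ndarray
    n_snps_used: int
    sample_ids: list[str]
    construction: str = "centered"


def compute_grm(gm: GenotypeMatrix, ingroup_only: bool = True) -> RelatednessMatrix:
    """Centered genomic relatedness matrix K = G G^T / m.

    Missing entries are mean-imputed per SNP before centering.
    """
    sub = gm.take_samples(gm.ingroup_mask) if ingroup_only else gm
    if sub.n_variants == 0:
        raise ValueError("cannot build a GRM from 0 SNPs")
    d = sub.dosage(impute_mean=True)
    d = d - d.mean(axis=1, keepdims=True)
    k = (d.T @ d) / sub.n_variants
    return RelatednessMatrix(K=k, n_snps_used=sub.n_variants, sample_ids=sub.sample_ids)


def _reml_loglik_terms(
    lam: np.ndarray,
    d_eig: np.ndarray,
    y_t: np.ndarray,
    one_t: np.ndarray,
    x_t: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorized GLS pieces for per-SNP lambda values.

    ``lam`` has one entry per SNP; returns the 2x2 normal-equation terms,
    the residual quadratic form, and the restricted log-likelihood (up to
    an additive constant shared across lambda).
    """
    n = len(d_eig)
    w = 1.0 / (lam[None, :] * d_eig[:, None] + 1.0)  # n x m
    logdet_v = -np.log(w).sum(axis=0)
    a11 = (w * (one_t**2)[:, None]).sum(axis=0)
    a12 = ((w * one_t[:, None]) * x_t).sum(axis=0)
    a22 = (w * x_t**2).sum(axis=0)
    b1 = ((w * one_t[:, None]) * y_t[:, None]).sum(axis=0)
    b2 = ((w * y_t[:, None]) * x_t).sum(axis=0)
    yy = (w * (y_t**2)[:, None]).sum(axis=0)
    det = a11 * a22 - a12**2
    with np.errstate(invalid="ignore", divide="ignore"):
        ypy = yy - (b1**2 * a22 - 2.0 * b1 * b2 * a12 + b2**2 * a11) / det
        loglik = -0.5 * (logdet_v + np.log(det) + (n - 2) * np.log(ypy))
    return {
        "a11": a11, "a12": a12, "a22": a22, "b1": b1, "b2": b2,
        "det": det, "ypy": ypy, "loglik": loglik,
    }


def _optimize_lambda(
    d_eig: np.ndarray,
    y_t: np.ndarray,
    one_t: np.ndarray,
    x_t: np.ndarray,
    n_grid: int = 41,
    n_refine: int = 35,
) -> np.ndarray:
    """Per-SNP REML-optimal lambda by grid search + golden-section refinement."""
    lo, hi = LOG_LAMBDA_RANGE
    grid = np.logspace(lo, hi, n_grid)
    m = x_t.shape[1]
    best_ll = np.full(m, -np.inf)
    best_idx = np.zeros(m, dtype=int)
    for g, lam in enumerate(grid):
        ll = _reml_loglik_terms(np.full(m, lam), d_eig, y_t, one_t, x_t)["loglik"]
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_idx[better] = g
    log_grid = np.log10(grid)
    left = log_grid[np.maximum(best_idx - 1, 0)]
    right = log_grid[np.minimum(best_idx + 1, n_grid - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    c = right - phi * (right - left)
    dpt = left + phi * (right - left)
    fc = _reml_loglik_terms(10**c, d_eig, y_t, one_t, x_t)["loglik"]
    fd = _reml_loglik_terms(10**dpt, d_eig, y_t, one_t, x_t)["loglik"]
    for _ in range(n_refine):
        move_right = fc < fd  # maximum in [c, right]
        left = np.where(move_right, c, left)
        right = np.where(move_right, right, dpt)
        c = right - phi * (right - left)
        dpt = left + phi * (right - left)
        fc = _reml_loglik_terms(10**c, d_eig, y_t, one_t, x_t)["loglik"]
        fd = _reml_loglik_terms(10**dpt, d_eig, y_t, one_t, x_t)["loglik"]
    return 10 ** ((left + right) / 2.0)


def reml_loglik(
    lam: float | np.ndarray,
    d_eig: np.ndarray,
    y_t: np.ndarray,
    one_t: np.ndarray,
    x_t: np.ndarray,
) -> np.ndarray:
    """Restricted log-likelihood at a given lambda (for diagnostics/tests)."""
    lam = np.broadcast_to(np.atleast_1d(np.asarray(lam, dtype=float)), (x_t.shape[1],))
    return _reml_loglik_terms(np.array(lam), d_eig, y_t, one_t, x_t)["loglik"]


def lmm_scan(
    y: np.ndarray,
    gm: GenotypeMatrix,
    grm: RelatednessMatrix,
    per_snp_lambda: bool = True,
    ingroup_only: bool = True,
    chunk_size: int = 4000,
) -> pd.DataFrame:
    """Per-SNP mixed-model Wald test.

    Returns a frame with scaffold, pos, variant, beta, se, lambda, wald_p
    and status ('ok', 'zero_variance', 'degenerate').  Zero-variance SNPs
    are skipped (NaN stats); degenerate optima are reported with p = 1.
    With ``per_snp_lambda=False`` the variance ratio is estimated once under
    the null model and shared across SNPs (fast mode).
    """
    sub = gm.take_samples(gm.ingroup_mask) if ingroup_only else gm
    y = np.asarray(y, dtype=float)
    if len(y) != sub.n_samples:
        raise ValueError("phenotype length must match sample count")
    if np.isnan(y).any():
        raise ValueError("missing phenotypes are not supported")
    if grm.sample_ids != sub.sample_ids:
        raise ValueError("GRM sample order does not match genotype matrix")

    n = sub.n_samples
    d_eig, u = np.linalg.eigh(grm.K)
    d_eig = np.clip(d_eig, 0.0, None)
    y_t = u.T @ y
    one_t = u.T @ np.ones(n)

    dose = sub.dosage(impute_mean=True)  # variants x samples
    variance = dose.var(axis=1)
    nz = variance > 0

    m = sub.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    lam_out = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    status = np.array(["zero_variance"] * m, dtype=object)

    idx_nz = np.flatnonzero(nz)
    for start in range(0, len(idx_nz), chunk_size):
        idx = idx_nz[start : start + chunk_size]
        x_t = u.T @ dose[idx].T  # n x chunk
        if per_snp_lambda:
            lam = _optimize_lambda(d_eig, y_t, one_t, x_t)
        else:
            lam_null = _null_lambda(d_eig, y_t, one_t)
            lam = np.full(len(idx), lam_null)
        terms = _reml_loglik_terms(lam, d_eig, y_t, one_t, x_t)
        det = terms["det"]
        with np.errstate(invalid="ignore", divide="ignore"):
            b = (terms["a11"] * terms["b2"] - terms["a12"] * terms["b1"]) / det
            sigma2 = terms["ypy"] / (n - 2)
            var_b = sigma2 * terms["a11"] / det
            fstat = b**2 / var_b
        p = sps.f.sf(fstat, 1, n - 2)
        good = np.isfinite(p) & np.isfinite(b) & (var_b > 0)
        beta[idx] = b
        se[idx] = np.sqrt(np.where(var_b > 0, var_b, np.nan))
        lam_out[idx] = lam
        pvals[idx] = np.where(good, p, 1.0)
        status[idx] = np.where(good, "ok", "degenerate")

    return pd.DataFrame(
        {
            "scaffold": sub.scaffolds,
            "pos": sub.positions,
            "variant": [v.name for v in sub.variants],
            "beta": beta,
            "se": se,
            "lambda": lam_out,
            "wald_p": pvals,
            "status": status,
        }
    )


def _null_lambda(d_eig: np.ndarray, y_t: np.ndarray, one_t: np.ndarray) -> float:
    """REML lambda under the intercept-only model (shared-lambda fast mode)."""
    n = len(d_eig)
    grid = np.logspace(*LOG_LAMBDA_RANGE, 201)
    best, best_ll = grid[0], -np.inf
    for lam in grid:
        w = 1.0 / (lam * d_eig + 1.0)
        a11 = float(np.sum(w * one_t**2))
        b1 = float(np.sum(w * one_t * y_t))
        yy = float(np.sum(w * y_t**2))
        ypy = yy - b1**2 / a11
        ll = -0.5 * (-np.log(w).sum() + np.log(a11) + (n - 1) * np.log(ypy))
        if ll > best_ll:
            best, best_ll = lam, ll
    return float(best)


def fdr_correct(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    q = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return q


def attach_fdr(result: pd.DataFrame) -> pd.DataFrame:
    out = result.copy()
    out["fdr_q"] = fdr_correct(out["wald_p"].to_numpy())
    return out


def significant_hits(result: pd.DataFrame, q_threshold: float = 5e-5) -> pd.DataFrame:
    """SNPs with fdr_q < threshold, sorted by q then coordinate."""
    if "fdr_q" not in result.columns:
        result = attach_fdr(result)
    hits = result[result["fdr_q"] < q_threshold]
    return hits.sort_values(["fdr_q", "scaffold", "pos"], kind="mergesort").reset_index(
        drop=True
    )


def genomic_inflation(pvals: np.ndarray) -> float:
    """lambda_GC: median implied 1-df chi-square over its null median (0.4549)."""
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals)]
    chi = sps.chi2.isf(pvals, 1)
    return float(np.median(chi) / sps.chi2.ppf(0.5, 1))
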