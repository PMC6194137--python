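"""Diversity, differentiation, LD and PCA on haploid genotype matrices.

The Weir–Cockerham estimator is the haploid analogue of the classic
variance-components form: each individual contributes a single allele, so
the within-individual (heterozygosity) component vanishes.  With r groups
of n_i called alleles and alt frequencies p_i at a site,

    nbar = mean(n_i),  N = sum(n_i),  nc = (N - sum(n_i^2)/N) / (r - 1)
    pbar = sum(n_i p_i) / N
    s2   = sum(n_i (p_i - pbar)^2) / ((r - 1) nbar)
    b    = nbar/(nbar - 1) * (pbar(1 - pbar) - s2 (r - 1)/r)
    a    = nbar/nc * (s2 - (pbar(1 - pbar) - s2 (r - 1)/r) / (nbar - 1))

F_ST(site) = a / (a + b); genome-wide F_ST = sum(a) / sum(a + b)
(ratio of sums, not mean of ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from haplopop.types import ALT, REF, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    pi_per_site: float
    watterson_theta_per_site: float
    segregating_sites: int
    genome_length: int
    n_haploids: int
    harmonic_sum: float


def harmonic_sum(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise ValueError("need n >= 2 haploids")
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(s: int, n: int, genome_length: int) -> float:
    """Watterson's theta per site from S segregating sites and n haploids."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    return s / (harmonic_sum(n) * genome_length)


def nucleotide_diversity(gm: GenotypeMatrix, genome_length: int) -> DiversityResult:
    """Average pairwise difference per bp over ingroup haploids.

    Per segregating site, pi = 2 p (1 - p) * n/(n - 1) with n the number of
    called haploids and p the alt frequency there; sites with n < 2 are
    skipped.  Both pi and Watterson's theta (computed from the count of
    sample-segregating sites) are reported per bp of ``genome_length``.
    """
    sub = gm.calls[:, gm.ingroup_mask]
    alt = (sub == ALT).sum(axis=1).astype(float)
    n = ((sub == REF) | (sub == ALT)).sum(axis=1).astype(float)
    usable = n >= 2
    if not np.all(usable):
        log.info("nucleotide_diversity: skipping %d sites with <2 calls", int((~usable).sum()))
    p = alt[usable] / n[usable]
    nn = n[usable]
    pi_sites = 2.0 * p * (1.0 - p) * nn / (nn - 1.0)
    seg = int(np.sum((alt[usable] > 0) & (alt[usable] < nn)))
    n_haploids = int(gm.ingroup_mask.sum())
    return DiversityResult(
        pi_per_site=float(pi_sites.sum() / genome_length),
        watterson_theta_per_site=watterson_theta(seg, n_haploids, genome_length),
        segregating_sites=seg,
        genome_length=genome_length,
        n_haploids=n_haploids,
        harmonic_sum=harmonic_sum(n_haploids),
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST (haploid)
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    per_site: pd.DataFrame  # scaffold, pos, a, d (= a + b), fst
    genome_wide: float
    groups: tuple[str, ...]


def _wc_from_counts(n_gi: np.ndarray, alt_gi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site variance components from group call/alt counts.

    ``n_gi``/``alt_gi`` have shape [r x sites].  Returns (a, a + b), NaN at
    sites where any group has fewer than 2 calls.
    """
    r = n_gi.shape[0]
    if r < 2:
        raise ValueError("need at least 2 groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (n_gi >= 2).all(axis=0)
        n_tot = n_gi.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n_gi**2).sum(axis=0) / n_tot) / (r - 1)
        p_gi = alt_gi / n_gi
        pbar = alt_gi.sum(axis=0) / n_tot
        s2 = (n_gi * (p_gi - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        inner = pbar * (1.0 - pbar) - s2 * (r - 1) / r
        b = nbar / (nbar - 1.0) * inner
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
    a = np.where(valid, a, np.nan)
    d = np.where(valid, a + b, np.nan)
    return a, d


def weir_cockerham_fst(
    gm: GenotypeMatrix, grouping: np.ndarray | list
) -> FstResult:
    """Haploid Weir-Cockerham F_ST per site plus the ratio-of-sums estimate.

    ``grouping`` assigns a label per sample; samples labelled None (or NaN)
    are excluded.  Sites where any group has <2 called genotypes, or where
    a + b = 0, are excluded from the genome-wide sums (per-site value NaN).
    """
    grouping = np.asarray(grouping, dtype=object)
    labels = sorted({g for g in grouping if g is not None and g == g})
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n_gi = np.empty((len(labels), gm.n_variants))
    alt_gi = np.empty((len(labels), gm.n_variants))
    for k, lab in enumerate(labels):
        cols = gm.calls[:, grouping == lab]
        n_gi[k] = ((cols == REF) | (cols == ALT)).sum(axis=1)
        alt_gi[k] = (cols == ALT).sum(axis=1)
    a, d = _wc_from_counts(n_gi, alt_gi)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(d != 0, a / d, np.nan)
    ok = np.isfinite(a) & np.isfinite(d) & (d != 0)
    gw = float(a[ok].sum() / d[ok].sum()) if ok.any() else float("nan")
    per_site = pd.DataFrame(
        {
            "scaffold": gm.scaffolds,
            "pos": gm.positions,
            "a": a,
            "d": d,
            "fst": fst,
        }
    )
    return FstResult(per_site=per_site, genome_wide=gw, groups=tuple(labels))


def genome_wide_fst_mean_of_ratios(res: FstResult) -> float:
    """Sensitivity alternative: average of per-site F_ST ratios."""
    vals = res.per_site["fst"].to_numpy()
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# permutation null for behavior-group differentiation
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_fst: float
    null_values: np.ndarray
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if len(self.null_values) > 1 else 0.0


def fst_permutation_test(
    gm: GenotypeMatrix,
    behavior: np.ndarray | list | None = None,
    n_perm: int = 1000,
    subset_size: int = 100_000,
    seed: int | None = 0,
    fresh_subset: bool = True,
) -> PermutationResult:
    """Label-permutation significance test for behavior-group F_ST.

    Each permutation shuffles the behavior labels across ingroup
    individuals and (by default) draws a fresh random SNP subset of
    ``subset_size`` without replacement before computing the genome-wide
    ratio-of-sums F_ST.  p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ingroup = gm.ingroup_mask
    sub = gm.take_samples(ingroup)
    labels = np.asarray(behavior if behavior is not None else sub.behavior_labels, dtype=object)
    if len(labels) != sub.n_samples:
        raise ValueError("behavior labels must match ingroup sample count")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 behavior groups, got {uniq}")

    m = sub.n_variants
    if subset_size > m:
        log.info("subset_size %d > %d variants; using all", subset_size, m)
        subset_size = m

    observed = weir_cockerham_fst(sub, labels).genome_wide

    is_alt = (sub.calls == ALT).astype(np.float64)
    is_called = ((sub.calls == REF) | (sub.calls == ALT)).astype(np.float64)

    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e8 // max(m, 1))))
    g1 = uniq[0]
    base_mask = (labels == g1).astype(float)
    fixed_subset = rng.choice(m, size=subset_size, replace=False) if not fresh_subset else None
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        # permuted group-1 indicator matrix [samples x k]
        M = np.empty((sub.n_samples, k))
        for j in range(k):
            M[:, j] = rng.permutation(base_mask)
        n1 = is_called @ M
        a1 = is_alt @ M
        n2 = is_called.sum(axis=1, keepdims=True) - n1
        a2 = is_alt.sum(axis=1, keepdims=True) - a1
        for j in range(k):
            a, d = _wc_from_counts(
                np.vstack([n1[:, j], n2[:, j]]), np.vstack([a1[:, j], a2[:, j]])
            )
            idx = (
                rng.choice(m, size=subset_size, replace=False)
                if fresh_subset
                else fixed_subset
            )
            aa, dd = a[idx], d[idx]
            ok = np.isfinite(aa) & np.isfinite(dd) & (dd != 0)
            null[done + j] = aa[ok].sum() / dd[ok].sum() if ok.any() else np.nan
        done += k

    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed_fst=observed, null_values=null, p_value=float(p))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    pairs: pd.DataFrame  # scaffold, pos_i, pos_j, distance, r2
    binned_decay: pd.DataFrame  # bin_low, bin_high, mean_r2, n_pairs
    window_bp: int


def default_ld_bins(window_bp: int) -> np.ndarray:
    """0-50 bp, then log-spaced bins out to the window size."""
    edges = np.unique(
        np.concatenate([[0.0, 50.0], np.geomspace(50.0, window_bp, 12)])
    )
    return edges


def ld_r2(
    gm: GenotypeMatrix,
    window_bp: int = 50_000,
    bin_edges: np.ndarray | None = None,
    ingroup_only: bool = True,
) -> LDResult:
    """r^2 for every same-scaffold SNP pair within ``window_bp``.

    r^2 is the squared Pearson correlation of the two {0,1} call vectors
    over jointly called samples; pairs with a zero-variance member are
    skipped.  Bins for the decay curve default to 0-50 bp then log-spaced.
    """
    sub = gm.take_samples(gm.ingroup_mask) if ingroup_only else gm
    scaffolds = sub.scaffolds
    positions = sub.positions
    frames = []
    for scaffold in dict.fromkeys(scaffolds):
        idx = np.flatnonzero(scaffolds == scaffold)
        idx = idx[np.argsort(positions[idx], kind="mergesort")]
        pos = positions[idx]
        G = (sub.calls[idx] == ALT).astype(np.float64)
        V = ((sub.calls[idx] == REF) | (sub.calls[idx] == ALT)).astype(np.float64)
        m = len(idx)
        step = 1500
        for lo in range(0, m, step):
            hi = min(lo + step, m)
            far = int(np.searchsorted(pos, pos[hi - 1] + window_bp, side="right"))
            gi, vi = G[lo:hi], V[lo:hi]
            gj, vj = G[lo:far], V[lo:far]
            n = vi @ vj.T
            sx = gi @ vj.T
            sy = vi @ gj.T
            sxy = gi @ gj.T
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = n * sxy - sx * sy
                varx = n * sx - sx**2
                vary = n * sy - sy**2
                r2 = cov**2 / (varx * vary)
            ii, jj = np.nonzero(np.ones_like(r2))
            abs_i = lo + ii
            abs_j = lo + jj
            dist = pos[abs_j] - pos[abs_i]
            keep = (abs_j > abs_i) & (dist <= window_bp) & np.isfinite(r2[ii, jj])
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": scaffold,
                        "pos_i": pos[abs_i[keep]],
                        "pos_j": pos[abs_j[keep]],
                        "distance": dist[keep],
                        "r2": r2[ii[keep], jj[keep]],
                    }
                )
            )
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["scaffold", "pos_i", "pos_j", "distance", "r2"])
    )
    edges = bin_edges if bin_edges is not None else default_ld_bins(window_bp)
    which = np.digitize(pairs["distance"].to_numpy(), edges, right=True)
    rows = []
    for b in range(1, len(edges)):
        sel = which == b
        rows.append(
            (
                edges[b - 1],
                edges[b],
                float(pairs.loc[sel, "r2"].mean()) if sel.any() else np.nan,
                int(sel.sum()),
            )
        )
    binned = pd.DataFrame(rows, columns=["bin_low", "bin_high", "mean_r2", "n_pairs"])
    return LDResult(pairs=pairs, binned_decay=binned, window_bp=window_bp)


# ---------------------------------------------------------------------------
# LD pruning (PLINK --indep style: window, step, VIF)
# ---------------------------------------------------------------------------

def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column against the others, via the correlation-matrix inverse."""
    k = x.shape[1]
    if k == 1:
        return np.ones(1)
    sd = x.std(axis=0)
    vifs = np.ones(k)
    live = sd > 0
    if live.sum() < 2:
        return vifs
    r = np.corrcoef(x[:, live], rowvar=False)
    try:
        inv = np.linalg.inv(r)
        vifs[live] = np.diag(inv)
    except np.linalg.LinAlgError:
        vifs[live] = np.inf
    return vifs


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    vif_threshold: float = 2.0,
    ingroup_only: bool = True,
) -> np.ndarray:
    """VIF-based pruning with a sliding window; returns retained variant indices.

    Within each window the SNP with the highest VIF (regression of its
    dosage on the other retained window SNPs) is removed until every VIF is
    below the threshold; removals are global.  Perfectly duplicated columns
    are resolved by removing the later-coordinate one first.
    """
    sub = gm.take_samples(gm.ingroup_mask) if ingroup_only else gm
    d = sub.dosage(impute_mean=True)
    scaffolds = sub.scaffolds
    positions = sub.positions
    removed = np.zeros(sub.n_variants, dtype=bool)
    for scaffold in dict.fromkeys(scaffolds):
        idx = np.flatnonzero(scaffolds == scaffold)
        idx = idx[np.argsort(positions[idx], kind="mergesort")]
        m = len(idx)
        for lo in range(0, max(m - window_snps, 0) + 1, step_snps):
            win = idx[lo : lo + window_snps]
            while True:
                live = win[~removed[win]]
                if len(live) < 2:
                    break
                x = d[live].T  # samples x snps
                # exact duplicates first: drop the later-coordinate copy
                r = np.corrcoef(x, rowvar=False)
                np.fill_diagonal(r, 0.0)
                dup_i, dup_j = np.nonzero(np.abs(r) > 1 - 1e-12)
                if len(dup_i):
                    removed[live[max(dup_i[0], dup_j[0])]] = True
                    continue
                vifs = _window_vifs(x)
                worst = len(vifs) - 1 - int(np.argmax(vifs[::-1]))  # ties -> later SNP
                if vifs[worst] >= vif_threshold:
                    removed[live[worst]] = True
                else:
                    break
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    coordinates: np.ndarray  # samples x components
    sample_ids: list[str] = field(default_factory=list)
    normalization: str = "frequency-scaled"


def genotype_pca(
    gm: GenotypeMatrix,
    n_components: int = 10,
    scale: bool = True,
    ingroup_only: bool = True,
) -> PCAResult:
    """PCA of the genotype matrix with allele-frequency scaling.

    Missing/artifact entries are imputed to the per-SNP mean dosage,
    columns centered and (optionally) divided by sqrt(p(1-p)); the top
    components of the sample covariance are returned.
    """
    sub = gm.take_samples(gm.ingroup_mask) if ingroup_only else gm
    d = sub.dosage(impute_mean=True)  # variants x samples
    p = d.mean(axis=1)
    x = (d - p[:, None]).T  # samples x variants
    if scale:
        denom = np.sqrt(p * (1.0 - p))
        keep = denom > 0
        x = x[:, keep] / denom[keep]
    k = min(n_components, min(x.shape))
    if k < n_components:
        log.warning("n_components clipped from %d to %d", n_components, k)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigenvalues = (s**2) / max(x.shape[0] - 1, 1)
    return PCAResult(
        eigenvalues=eigenvalues[:k],
        coordinates=u[:, :k] * s[:k],
        sample_ids=sub.sample_ids,
        normalization="frequency-scaled" if scale else "unscaled",
    )
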