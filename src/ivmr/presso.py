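"""MR-PRESSO: global heterogeneity test, per-SNP outlier test, and
distortion test, built on leave-one-out IVW residuals and a seeded
parametric simulation."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .data import HarmonizedInstrumentSet
from .errors import EstimationError, InsufficientInstrumentsError
from .estimators import MREstimate, ivw

__all__ = ["PressoResult", "presso"]


@dataclass(frozen=True)
class PressoResult:
    """Outcome of the MR-PRESSO procedure on one instrument set."""

    rss_obs: float
    global_pval: float
    per_snp_pval: tuple[float, ...]  # Bonferroni-adjusted, one per instrument
    outliers: tuple[str, ...]
    distortion_pval: float | None
    estimate_raw: MREstimate
    estimate_outlier_corrected: MREstimate | None
    n_sim: int
    outlier_threshold: float


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes (regression through the origin of by on bx
    with weights w), vectorized over 2-d inputs of shape (B, J)."""
    num = (w * bx * by).sum(axis=-1, keepdims=True) - w * bx * by
    den = (w * bx * bx).sum(axis=-1, keepdims=True) - w * bx * bx
    return num / den


def _weighted_rss(bx, by, w, weighted: bool):
    """Per-SNP squared LOO residuals and their sum."""
    slopes = _loo_slopes(bx, by, w)
    resid = by - slopes * bx
    contrib = (w if weighted else 1.0) * resid**2
    return contrib, contrib.sum(axis=-1)


def presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | None = 0,
    outlier_threshold: float = 0.10,
    weighted: bool = True,
    n_distortion: int = 1000,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier, and distortion tests.

    The observed statistic is the (inverse-outcome-variance weighted, by
    default) residual sum of squares of each SNP about the leave-one-out
    IVW fit. Its null distribution comes from ``n_sim`` parametric
    draws beta_Xj* ~ N(beta_Xj, sigma_Xj), beta_Yj* ~ N(slope_(-j) *
    beta_Xj, sigma_Yj). Global and per-SNP p-values use the add-one
    estimator (1 + #{>= observed}) / (n_sim + 1); per-SNP p-values are
    Bonferroni-multiplied by J and SNPs below ``outlier_threshold`` are
    flagged. When outliers are found, the distortion test compares the
    raw-vs-corrected IVW difference with differences from removing
    ``n_distortion`` random subsets of the same size.
    """
    j = hset.n_snps
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs J >= 4, got {j}")
    if n_sim < 1000:
        raise EstimationError(f"n_sim must be >= 1000, got {n_sim}")
    bx, by = hset.beta_exposure, hset.beta_outcome
    sx, sy = hset.se_exposure, hset.se_outcome
    w = 1.0 / sy**2
    contrib_obs, rss_obs = _weighted_rss(bx, by, w, weighted)

    loo = _loo_slopes(bx[None, :], by[None, :], w)[0]
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(loo * bx, sy, size=(n_sim, j))
    contrib_star, rss_star = _weighted_rss(bx_star, by_star, w, weighted)
    if float(np.var(rss_star)) == 0.0:
        raise EstimationError("zero variance in simulated RSS distribution")

    global_pval = (1.0 + np.count_nonzero(rss_star >= rss_obs)) / (n_sim + 1.0)
    exceed = (contrib_star >= contrib_obs[None, :]).sum(axis=0)
    per_snp = np.minimum(1.0, (1.0 + exceed) / (n_sim + 1.0) * j)
    rsids = hset.rsids
    outliers = tuple(rsids[i] for i in np.flatnonzero(per_snp < outlier_threshold))

    est_raw, _ = ivw(hset)
    est_corr = None
    distortion_pval = None
    if outliers and j - len(outliers) >= 2:
        corrected_set = hset.subset(drop=list(outliers))
        est_corr, _ = ivw(corrected_set)
        d_obs = est_corr.beta - est_raw.beta
        k = len(outliers)
        n_subsets = math.comb(j, k)
        diffs = []
        if n_subsets <= n_distortion:
            combos = itertools.combinations(range(j), k)
        else:
            combos = (tuple(rng.choice(j, size=k, replace=False))
                      for _ in range(n_distortion))
        for combo in combos:
            keep = [i for i in range(j) if i not in combo]
            red, _ = ivw(hset.subset_indices(keep))
            diffs.append(red.beta - est_raw.beta)
        diffs = np.asarray(diffs)
        distortion_pval = float(
            (1.0 + np.count_nonzero(np.abs(diffs) >= abs(d_obs)))
            / (diffs.size + 1.0)
        )
    return PressoResult(
        rss_obs=float(rss_obs), global_pval=float(global_pval),
        per_snp_pval=tuple(float(p) for p in per_snp), outliers=outliers,
        distortion_pval=distortion_pval, estimate_raw=est_raw,
        estimate_outlier_corrected=est_corr, n_sim=n_sim,
        outlier_threshold=outlier_threshold,
    )
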