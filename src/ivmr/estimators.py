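"""Core causal estimators and diagnostics for two-sample summary MR.

Implements per-SNP Wald ratios, the inverse-variance-weighted (IVW)
estimator with Cochran's Q, the weighted-median estimator with a
parametric-bootstrap SE, Egger regression with its intercept test, the
I2GX instrument-strength statistic, and SIMEX dilution correction of the
Egger slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import HarmonizedInstrumentSet
from .errors import (
    DomainError,
    EstimationError,
    InsufficientInstrumentsError,
    WeakInstrumentError,
)

__all__ = [
    "RatioEstimates",
    "MREstimate",
    "HeterogeneityReport",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "egger",
    "i2_gx",
    "simex_egger",
    "DEFAULT_BOOT_SEED",
]

_Z975 = stats.norm.ppf(0.975)

#: Default seed for the weighted-median bootstrap; fixed for reproducibility.
DEFAULT_BOOT_SEED = 20190226


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios with their SEs and inverse-variance weights."""

    rsids: tuple[str, ...]
    theta: np.ndarray
    se: np.ndarray
    se_order: str = "first"

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.se**2


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log-odds scale with a Wald 95% CI."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    scale: float = 1.0

    @property
    def ci_low(self) -> float:
        return self.beta - _Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z975 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.method}: OR {self.odds_ratio:.2f} "
                f"({self.or_low:.2f}-{self.or_high:.2f}), p={self.pval:.2g}, "
                f"J={self.n_snps}")


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran's Q, instrument-strength I2GX, and Egger-intercept test."""

    cochran_q: float
    q_df: int
    q_pval: float
    i2_gx: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratios(hset: HarmonizedInstrumentSet,
                se_order: str = "first") -> RatioEstimates:
    """Per-SNP causal ratios theta_j = beta_Yj / beta_Xj.

    ``se_order="first"`` uses se_j = sigma_Yj/|beta_Xj|; ``"second"``
    adds the exposure-uncertainty term
    sqrt(sigma_Yj^2/beta_Xj^2 + beta_Yj^2 sigma_Xj^2 / beta_Xj^4).
    """
    bx, by = hset.beta_exposure, hset.beta_outcome
    sx, sy = hset.se_exposure, hset.se_outcome
    zero = np.flatnonzero(bx == 0.0)
    if zero.size:
        names = ", ".join(hset.rsids[i] for i in zero)
        raise WeakInstrumentError(f"exposure beta is exactly 0 for: {names}")
    theta = by / bx
    if se_order == "first":
        se = sy / np.abs(bx)
    elif se_order == "second":
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise DomainError(f"se_order must be 'first' or 'second', got {se_order!r}")
    return RatioEstimates(rsids=tuple(hset.rsids), theta=theta, se=se,
                          se_order=se_order)


def _ivw_from_ratios(theta: np.ndarray, se: np.ndarray,
                     model: str) -> tuple[float, float, float]:
    """Pooled estimate, its SE under ``model``, and Cochran's Q."""
    w = 1.0 / se**2
    beta = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - beta) ** 2))
    se_fixed = float(np.sum(w) ** -0.5)
    j = theta.size
    if model == "fixed":
        se_hat = se_fixed
    elif model == "random":
        se_hat = se_fixed * max(1.0, math.sqrt(q / (j - 1))) if j > 1 else se_fixed
    else:
        raise DomainError(f"model must be fixed|random|auto, got {model!r}")
    return beta, se_hat, q


def ivw(hset: HarmonizedInstrumentSet, model: str = "auto",
        se_order: str = "first") -> tuple[MREstimate, HeterogeneityReport]:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``model="fixed"`` uses the fixed-effect SE (sum of weights)^-1/2;
    ``"random"`` inflates it by the multiplicative dispersion factor
    max(1, sqrt(Q/(J-1))); ``"auto"`` (default) picks fixed for J < 4 and
    random otherwise.
    """
    j = hset.n_snps
    if j < 2:
        raise InsufficientInstrumentsError(f"IVW needs J >= 2, got {j}")
    if model == "auto":
        model = "fixed" if j < 4 else "random"
    ratios = wald_ratios(hset, se_order=se_order)
    beta, se_hat, q = _ivw_from_ratios(ratios.theta, ratios.se, model)
    est = MREstimate(method=f"ivw-{model}", beta=beta, se=se_hat,
                     pval=_two_sided_p(beta / se_hat), n_snps=j,
                     scale=hset.exposure_scale)
    report = HeterogeneityReport(
        cochran_q=q, q_df=j - 1, q_pval=float(stats.chi2.sf(q, j - 1)),
        i2_gx=i2_gx(hset),
    )
    return est, report


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative-midpoint
    CDF at probability one half."""
    order = np.argsort(theta)
    th = np.asarray(theta, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, th))


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000,
                    seed: int | None = DEFAULT_BOOT_SEED) -> MREstimate:
    """Weighted-median estimator; SE from a seeded parametric bootstrap.

    Each bootstrap replicate redraws beta_Xj and beta_Yj from normals at
    the observed values and SEs, recomputes ratios and inverse-variance
    weights, and re-evaluates the weighted median; the SE is the sample
    standard deviation over replicates.
    """
    j = hset.n_snps
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median needs J >= 3, got {j}")
    if n_boot < 100:
        raise DomainError(f"n_boot must be >= 100, got {n_boot}")
    ratios = wald_ratios(hset)
    point = weighted_median_point(ratios.theta, ratios.weights)
    rng = np.random.default_rng(seed)
    bx = rng.normal(hset.beta_exposure, hset.se_exposure, size=(n_boot, j))
    by = rng.normal(hset.beta_outcome, hset.se_outcome, size=(n_boot, j))
    sy = hset.se_outcome
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = bx[b]
        xb = np.where(xb == 0.0, 1e-300, xb)
        boots[b] = weighted_median_point(by[b] / xb, xb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        se = 1e-12  # degenerate agreement across replicates
    return MREstimate(method="weighted-median", beta=point, se=se,
                      pval=_two_sided_p(point / se), n_snps=j,
                      scale=hset.exposure_scale)


def _egger_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted regression of y on (1, x); multiplicative dispersion.

    Returns (intercept, slope, se_intercept, se_slope, rss_w).
    """
    j = x.size
    sw = w.sum()
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    denom = sw * swxx - swx**2
    if denom <= 0 or not np.isfinite(denom):
        raise EstimationError("singular Egger design (no spread in exposure betas)")
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swxx * swy - swx * swxy) / denom
    resid = y - intercept - slope * x
    rss_w = float((w * resid**2).sum())
    scale = max(1.0, math.sqrt(rss_w / (j - 2))) if j > 2 else 1.0
    se_slope = scale * math.sqrt(sw / denom)
    se_intercept = scale * math.sqrt(swxx / denom)
    return float(intercept), float(slope), se_intercept, se_slope, rss_w


def egger(hset: HarmonizedInstrumentSet) -> tuple[MREstimate, HeterogeneityReport]:
    """MR-Egger: weighted regression of outcome betas on exposure betas
    with a free intercept, after orienting all exposure betas positive.

    The slope is the pleiotropy-adjusted causal estimate; the intercept
    and its p-value test for directional pleiotropy. SEs carry the
    multiplicative dispersion factor max(1, sqrt(RSS/(J-2))).
    """
    j = hset.n_snps
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs J >= 3, got {j}")
    bx, by = hset.beta_exposure, hset.beta_outcome
    if np.any(bx == 0.0):
        raise WeakInstrumentError("exposure beta of 0 cannot be oriented")
    s = np.sign(bx)
    x, y = bx * s, by * s
    w = 1.0 / hset.se_outcome**2
    intercept, slope, se_i, se_s, rss_w = _egger_fit(x, y, w)
    est = MREstimate(method="egger", beta=slope, se=se_s,
                     pval=_two_sided_p(slope / se_s), n_snps=j,
                     scale=hset.exposure_scale)
    report = HeterogeneityReport(
        cochran_q=rss_w, q_df=j - 2, q_pval=float(stats.chi2.sf(rss_w, j - 2)),
        i2_gx=i2_gx(hset),
        egger_intercept=intercept, egger_intercept_se=se_i,
        egger_intercept_pval=_two_sided_p(intercept / se_i),
    )
    return est, report


def i2_gx(hset: HarmonizedInstrumentSet) -> float:
    """I2GX instrument-strength statistic in [0, 1].

    Q_GX is Cochran's Q of the (positively oriented) exposure betas
    around their inverse-variance-weighted mean; I2GX = (Q_GX - (J-1)) /
    Q_GX clamped below at 0. Values below 0.9 indicate substantial
    dilution of the Egger slope.
    """
    j = hset.n_snps
    if j < 2:
        raise InsufficientInstrumentsError(f"I2GX needs J >= 2, got {j}")
    sx = hset.se_exposure
    if np.any(sx <= 0):
        raise DomainError("exposure SEs must be positive")
    bx = np.abs(hset.beta_exposure)
    w = 1.0 / sx**2
    mu = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum(w * (bx - mu) ** 2))
    if q_gx <= 0.0:
        return 0.0
    return float(min(1.0, max(0.0, (q_gx - (j - 1)) / q_gx)))


def _egger_slopes_vectorized(bx: np.ndarray, by: np.ndarray,
                             w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Egger slope and its model variance for each row of ``bx``.

    ``bx`` is (B, J); ``by`` and ``w`` are length-J and shared across
    rows. Orientation (exposure betas positive) is applied per row.
    """
    s = np.where(bx < 0, -1.0, 1.0)
    x = bx * s
    y = by[None, :] * s
    wv = w[None, :]
    j = bx.shape[1]
    sw = wv.sum(axis=1)
    swx = (wv * x).sum(axis=1)
    swy = (wv * y).sum(axis=1)
    swxx = (wv * x * x).sum(axis=1)
    swxy = (wv * x * y).sum(axis=1)
    denom = sw * swxx - swx**2
    bad = (denom <= 0) | ~np.isfinite(denom)
    denom = np.where(bad, np.nan, denom)
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swxx * swy - swx * swxy) / denom
    resid = y - intercept[:, None] - slope[:, None] * x
    rss = (wv * resid**2).sum(axis=1)
    scale2 = np.maximum(1.0, rss / (j - 2))
    var_slope = scale2 * sw / denom
    return slope, var_slope


def simex_egger(
    hset: HarmonizedInstrumentSet,
    lambda_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0),
    n_sim: int = 1000,
    seed: int | None = DEFAULT_BOOT_SEED,
    extrapolant: str = "quadratic",
) -> MREstimate:
    """SIMEX dilution correction of the MR-Egger slope.

    For each lambda > 0, ``n_sim`` replicates perturb the exposure betas
    with noise of variance lambda * sigma_Xj^2 and refit the Egger slope;
    a quadratic in lambda is fit to the mean slope (the lambda = 0 point
    is the naive fit) and evaluated at lambda = -1. The SE comes from the
    simulation-extrapolation difference (jackknife-style) variance
    estimator: extrapolate (mean model variance - between-replicate
    variance) to lambda = -1.
    """
    j = hset.n_snps
    if j < 3:
        raise InsufficientInstrumentsError(f"SIMEX-Egger needs J >= 3, got {j}")
    if extrapolant != "quadratic":
        raise DomainError(f"unsupported extrapolant {extrapolant!r}")
    lambdas = np.asarray(sorted(set(lambda_grid)), dtype=float)
    if lambdas.size < 3:
        raise EstimationError("lambda grid too small for a quadratic extrapolant")
    if lambdas[0] != 0.0:
        lambdas = np.concatenate([[0.0], lambdas])
    naive, naive_report = egger(hset)
    bx, by = hset.beta_exposure, hset.beta_outcome
    sx = hset.se_exposure
    w = 1.0 / hset.se_outcome**2
    rng = np.random.default_rng(seed)
    mean_slope = np.empty(lambdas.size)
    var_diff = np.empty(lambdas.size)
    mean_slope[0] = naive.beta
    var_diff[0] = naive.se**2
    for k, lam in enumerate(lambdas[1:], start=1):
        noise = rng.standard_normal((n_sim, j)) * (math.sqrt(lam) * sx)[None, :]
        slopes, model_vars = _egger_slopes_vectorized(bx[None, :] + noise, by, w)
        ok = np.isfinite(slopes)
        if ok.sum() < max(10, n_sim // 10):
            raise EstimationError(
                f"SIMEX: {n_sim - int(ok.sum())}/{n_sim} degenerate refits at "
                f"lambda={lam}"
            )
        mean_slope[k] = float(slopes[ok].mean())
        s2 = float(np.var(slopes[ok], ddof=1))
        tau2 = float(np.nanmean(model_vars[ok]))
        var_diff[k] = tau2 - s2
    try:
        coef_m = np.polyfit(lambdas, mean_slope, 2)
        coef_v = np.polyfit(lambdas, var_diff, 2)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise EstimationError(f"degenerate SIMEX extrapolant fit: {exc}") from exc
    beta = float(np.polyval(coef_m, -1.0))
    var = float(np.polyval(coef_v, -1.0))
    if not np.isfinite(var) or var <= 0:
        var = naive.se**2  # conservative fallback
    se = math.sqrt(var)
    return MREstimate(method="simex-egger", beta=beta, se=se,
                      pval=_two_sided_p(beta / se), n_snps=j,
                      scale=hset.exposure_scale)
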