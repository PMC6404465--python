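"""Heterogeneity-penalized model averaging over instrument subsets.

Every subset S of instruments with |S| >= 2 contributes a normal
likelihood component centred at its within-subset IVW estimate; the
component's weight combines a validity prior with a penalty exp(-Q_S/2)
on within-subset heterogeneity. The averaged criterion is evaluated on a
theta grid; its argmax is the point estimate, and the 95% region is a
likelihood-ratio-style level set that may be a union of disjoint
intervals (reported as such, never bridged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import HarmonizedInstrumentSet
from .errors import ComplexityError, ConfigurationError, InsufficientInstrumentsError
from .estimators import wald_ratios

__all__ = ["SubsetModel", "AveragedEstimate", "hetpen", "subset_models",
           "CHI2_1_95"]

#: chi-square(1) 95th percentile used for the level-set CI cut.
CHI2_1_95 = 3.841458820694124

_MAX_J = 25
_CHUNK = 1 << 16


@dataclass(frozen=True)
class SubsetModel:
    """One instrument subset's IVW estimate and model-averaging weight."""

    subset: tuple[int, ...]
    theta: float
    se: float
    q: float
    weight: float


@dataclass(frozen=True)
class AveragedEstimate:
    """Mode and (possibly disjoint) 95% region of the averaged criterion."""

    mode: float
    ci_set: tuple[tuple[float, float], ...]
    multimodal: bool
    grid: np.ndarray
    log_criterion: np.ndarray
    top_models: tuple[SubsetModel, ...] = ()

    @property
    def ci_low(self) -> float:
        return self.ci_set[0][0]

    @property
    def ci_high(self) -> float:
        return self.ci_set[-1][1]


def _subset_stats(masks: np.ndarray, w: np.ndarray, wt: np.ndarray,
                  wtt: np.ndarray):
    """theta_S, se_S, q_S for each subset membership row of ``masks``."""
    sw = masks @ w
    swt = masks @ wt
    swtt = masks @ wtt
    theta = swt / sw
    se = sw**-0.5
    q = swtt - swt**2 / sw
    return theta, se, np.maximum(q, 0.0)


def _iter_masks(j: int):
    """Yield boolean membership matrices for all subsets with |S| >= 2."""
    total = 1 << j
    bits = np.arange(j)
    for start in range(0, total, _CHUNK):
        idx = np.arange(start, min(start + _CHUNK, total), dtype=np.int64)
        masks = ((idx[:, None] >> bits[None, :]) & 1).astype(float)
        sizes = masks.sum(axis=1)
        keep = sizes >= 2
        if keep.any():
            yield masks[keep], sizes[keep]


def hetpen(
    hset: HarmonizedInstrumentSet,
    prior_valid: float = 0.5,
    grid_lo: float | None = None,
    grid_hi: float | None = None,
    grid_n: int = 2001,
) -> AveragedEstimate:
    """Heterogeneity-penalized model-averaged causal estimate.

    Subset weights are proportional to
    ``prior_valid**|S| * (1-prior_valid)**(J-|S|) * exp(-Q_S/2)``.
    The default grid spans min(theta_S) - 6 max(se_S) to
    max(theta_S) + 6 max(se_S) with ``grid_n`` points.
    """
    j = hset.n_snps
    if j < 2:
        raise InsufficientInstrumentsError(f"HetPen needs J >= 2, got {j}")
    if j > _MAX_J:
        raise ComplexityError(
            f"J={j} exceeds the exhaustive-enumeration bound {_MAX_J}; "
            "subsample the instrument set"
        )
    if not (0.0 < prior_valid < 1.0):
        raise ConfigurationError(f"prior_valid must be in (0,1), got {prior_valid}")
    if grid_n < 3:
        raise ConfigurationError(f"grid_n must be >= 3, got {grid_n}")
    ratios = wald_ratios(hset)
    wts = ratios.weights
    wt = wts * ratios.theta
    wtt = wts * ratios.theta**2
    logp, log1mp = math.log(prior_valid), math.log(1.0 - prior_valid)

    # pass 1: normalizing constant and grid bounds (streaming over chunks)
    log_z = -np.inf
    tmin, tmax, semax = np.inf, -np.inf, 0.0
    for masks, sizes in _iter_masks(j):
        theta, se, q = _subset_stats(masks, wts, wt, wtt)
        logw = sizes * logp + (j - sizes) * log1mp - 0.5 * q
        log_z = np.logaddexp(log_z, logsumexp(logw))
        tmin = min(tmin, float(theta.min()))
        tmax = max(tmax, float(theta.max()))
        semax = max(semax, float(se.max()))
    lo = grid_lo if grid_lo is not None else tmin - 6.0 * semax
    hi = grid_hi if grid_hi is not None else tmax + 6.0 * semax
    if not (lo < hi):
        raise ConfigurationError(f"empty theta grid: [{lo}, {hi}]")
    if lo > tmin or hi < tmax:
        raise ConfigurationError(
            "grid does not cover all subset estimates "
            f"(need [{tmin}, {tmax}], got [{lo}, {hi}])"
        )
    grid = np.linspace(lo, hi, grid_n)

    # pass 2: accumulate the averaged criterion on the grid
    log_terms: list[np.ndarray] = []
    best: list[SubsetModel] = []
    for masks, sizes in _iter_masks(j):
        theta, se, q = _subset_stats(masks, wts, wt, wtt)
        logw = sizes * logp + (j - sizes) * log1mp - 0.5 * q - log_z
        # normal log-density of grid under each subset model
        z = (grid[None, :] - theta[:, None]) / se[:, None]
        comp = logw[:, None] - 0.5 * z**2 - np.log(se)[:, None] \
            - 0.5 * math.log(2.0 * math.pi)
        log_terms.append(logsumexp(comp, axis=0))
        order = np.argsort(logw)[::-1][:5]
        for i in order:
            members = tuple(int(b) for b in np.flatnonzero(masks[i]))
            best.append(SubsetModel(subset=members, theta=float(theta[i]),
                                    se=float(se[i]), q=float(q[i]),
                                    weight=float(np.exp(logw[i]))))
    log_l = logsumexp(np.vstack(log_terms), axis=0)
    k = int(np.argmax(log_l))
    mode = float(grid[k])
    inside = 2.0 * (log_l[k] - log_l) <= CHI2_1_95
    ci_set = _runs_to_intervals(grid, inside)
    best.sort(key=lambda m: m.weight, reverse=True)
    return AveragedEstimate(
        mode=mode, ci_set=ci_set, multimodal=len(ci_set) > 1,
        grid=grid, log_criterion=log_l, top_models=tuple(best[:5]),
    )


def subset_models(hset: HarmonizedInstrumentSet,
                  prior_valid: float = 0.5) -> list[SubsetModel]:
    """All subset models (|S| >= 2) with their normalized weights.

    Intended for inspection and testing at small J; memory grows as 2^J.
    """
    j = hset.n_snps
    if j > 20:
        raise ComplexityError(f"subset_models is enumeration-only; J={j} > 20")
    ratios = wald_ratios(hset)
    wts = ratios.weights
    wt = wts * ratios.theta
    wtt = wts * ratios.theta**2
    logp, log1mp = math.log(prior_valid), math.log(1.0 - prior_valid)
    rows = []
    for masks, sizes in _iter_masks(j):
        theta, se, q = _subset_stats(masks, wts, wt, wtt)
        logw = sizes * logp + (j - sizes) * log1mp - 0.5 * q
        rows.append((masks, theta, se, q, logw))
    all_logw = np.concatenate([r[4] for r in rows])
    log_z = logsumexp(all_logw)
    models = []
    for masks, theta, se, q, logw in rows:
        for i in range(masks.shape[0]):
            members = tuple(int(b) for b in np.flatnonzero(masks[i]))
            models.append(SubsetModel(
                subset=members, theta=float(theta[i]), se=float(se[i]),
                q=float(q[i]), weight=float(np.exp(logw[i] - log_z))))
    return models


def _runs_to_intervals(grid: np.ndarray,
                       inside: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Merge contiguous True runs of ``inside`` into (lo, hi) intervals."""
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    return tuple(intervals)
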