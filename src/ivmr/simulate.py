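"""Synthetic two-sample summary-statistics generator.

Generates per-SNP exposure/outcome association pairs with the structure
the estimators assume: exposure standardized to SD 1, instrument
variance-explained split across SNPs by a Dirichlet draw, binary-outcome
log-odds associations with effective-sample-size SEs, and optional
balanced/directional pleiotropy and planted outliers. Fully seeded and
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data import HarmonizedInstrumentSet, SummaryAssociation, harmonize
from .errors import DomainError

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study"]

# ordered non-palindromic allele pairs, so harmonization never drops SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic two-sample study.

    theta is the true causal log-OR per exposure SD; r2_total the total
    exposure variance explained by the J instruments. Pleiotropy modes:
    "none", "balanced" (mean-zero direct effects), "directional" (mean
    ``pleiotropy_mean``). ``n_outliers`` instruments additionally get a
    direct effect of ``outlier_offset`` outcome SEs.
    """

    n_snps: int = 8
    theta: float = 0.0
    r2_total: float = 0.016
    n_exposure: int = 24_000
    n_cases: int = 34_217
    n_controls: int = 404_630
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_outliers: int = 0
    outlier_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 2:
            raise DomainError(f"n_snps must be >= 2, got {self.n_snps}")
        if not (0.0 < self.r2_total < 1.0):
            raise DomainError(f"r2_total must be in (0,1), got {self.r2_total}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise DomainError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0 or self.outlier_offset < 0:
            raise DomainError("pleiotropy_sd and outlier_offset must be >= 0")
        if not (0 <= self.n_outliers <= self.n_snps):
            raise DomainError("n_outliers must lie in [0, n_snps]")
        if min(self.n_exposure, self.n_cases, self.n_controls) <= 0:
            raise DomainError("sample sizes must be positive")


@dataclass(frozen=True)
class SimulatedStudy:
    """Synthetic exposure/outcome panels plus the generative truth."""

    exposure: tuple[SummaryAssociation, ...]
    outcome: tuple[SummaryAssociation, ...]
    truth: dict

    def harmonized(self) -> HarmonizedInstrumentSet:
        return harmonize(list(self.exposure), list(self.outcome))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        def frame(assocs):
            return pd.DataFrame([{
                "rsid": a.rsid, "effect_allele": a.effect_allele,
                "other_allele": a.other_allele, "eaf": a.eaf,
                "beta": a.beta, "se": a.se, "pval": a.pval, "n": a.n,
            } for a in assocs])
        return frame(self.exposure), frame(self.outcome)

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, sort_keys=True)


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic two-sample summary-statistics study.

    True standardized exposure effects are b_j = +/- sqrt(r2_j) with the
    r2_j a Dirichlet split of ``r2_total``; observed exposure betas add
    N(0, sigma_X^2) noise with sigma_X = 1/sqrt(n_exposure). Outcome
    betas are N(theta * b_j + alpha_j, sigma_Y) with sigma_Y the
    effective-sample-size log-odds SE (n_cases n_controls / N)^(-1/2)
    and alpha_j the per-SNP pleiotropic direct effect.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_snps
    r2_split = rng.dirichlet(np.ones(j)) * config.r2_total
    signs = rng.choice([-1.0, 1.0], size=j)
    b = signs * np.sqrt(r2_split)
    sigma_x = np.full(j, 1.0 / np.sqrt(config.n_exposure))
    beta_x = rng.normal(b, sigma_x)

    # directional effects are defined on the exposure-increasing allele,
    # so they are multiplied by sign(b); a raw constant offset would
    # cancel across randomly signed instruments
    if config.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=j)
    else:
        alpha = signs * rng.normal(config.pleiotropy_mean,
                                   config.pleiotropy_sd, size=j)

    n_eff = config.n_cases * config.n_controls / (config.n_cases + config.n_controls)
    sigma_y = np.full(j, n_eff**-0.5)
    outlier_idx = np.sort(rng.choice(j, size=config.n_outliers, replace=False))
    alpha = alpha.copy()
    alpha[outlier_idx] += (signs[outlier_idx] * config.outlier_offset
                           * sigma_y[outlier_idx])
    beta_y = rng.normal(config.theta * b + alpha, sigma_y)

    eaf = rng.uniform(0.05, 0.95, size=j)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=j)
    n_out = config.n_cases + config.n_controls
    exposure, outcome = [], []
    for i in range(j):
        ea, oa = _ALLELE_PAIRS[pair_idx[i]]
        rsid = f"rs{1000 + i}"
        exposure.append(SummaryAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
            beta=float(beta_x[i]), se=float(sigma_x[i]),
            pval=float(_pvalue(beta_x[i:i+1], sigma_x[i:i+1])[0]),
            n=config.n_exposure))
        outcome.append(SummaryAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
            beta=float(beta_y[i]), se=float(sigma_y[i]),
            pval=float(_pvalue(beta_y[i:i+1], sigma_y[i:i+1])[0]),
            n=n_out))
    truth = {
        "config": asdict(config),
        "theta": config.theta,
        "b": b.tolist(),
        "pleiotropy": alpha.tolist(),
        "outlier_indices": [int(i) for i in outlier_idx],
        "outlier_rsids": [f"rs{1000 + int(i)}" for i in outlier_idx],
    }
    return SimulatedStudy(exposure=tuple(exposure), outcome=tuple(outcome),
                          truth=truth)
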