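"""Leave-one-out and named-SNP exclusion reanalysis, multiplicity
thresholds, and the noncentrality-based binary-outcome power calculation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy import stats

from .data import HarmonizedInstrumentSet
from .errors import ConfigurationError, DomainError, InsufficientInstrumentsError
from .estimators import MREstimate, ivw

__all__ = [
    "ExclusionSpec",
    "PowerInput",
    "BonferroniThreshold",
    "leave_one_out",
    "exclude_and_reestimate",
    "bonferroni_threshold",
    "mr_power",
]


@dataclass(frozen=True)
class ExclusionSpec:
    """A labelled set of rsids to drop, with the reason for dropping."""

    label: str
    rsids: tuple[str, ...]
    reason: str = ""

    def __post_init__(self):
        if not self.rsids:
            object.__setattr__(self, "rsids", ())


@dataclass(frozen=True)
class PowerInput:
    """Inputs for the noncentrality power calculation.

    n_total: combined cases + noncases; case_fraction: K in (0,1);
    r2_gx: exposure variance explained by the instruments, in (0,1);
    or_alt: detectable odds ratio per exposure unit; alpha: two-sided
    significance level.
    """

    n_total: float
    case_fraction: float
    r2_gx: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_total <= 0:
            raise DomainError(f"n_total must be > 0, got {self.n_total}")
        if not (0.0 < self.case_fraction < 1.0):
            raise DomainError(f"case_fraction must be in (0,1), got {self.case_fraction}")
        if not (0.0 <= self.r2_gx < 1.0):
            raise DomainError(f"r2_gx must be in [0,1), got {self.r2_gx}")
        if self.or_alt <= 0:
            raise DomainError(f"or_alt must be > 0, got {self.or_alt}")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass(frozen=True)
class BonferroniThreshold:
    """Family-wise significance threshold, exact and at 2 significant figures."""

    exact: float
    rounded: float
    n_tests: int
    alpha: float


def _default_estimator(hset: HarmonizedInstrumentSet) -> MREstimate:
    return ivw(hset)[0]


def leave_one_out(
    hset: HarmonizedInstrumentSet,
    estimator: Callable[[HarmonizedInstrumentSet], MREstimate] = _default_estimator,
) -> list[tuple[str, MREstimate]]:
    """Re-estimate J times, omitting one instrument each time.

    Returns ``(omitted_rsid, estimate)`` pairs in instrument order.
    """
    j = hset.n_snps
    if j < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs J >= 3, got {j}")
    rows = []
    for rsid in hset.rsids:
        rows.append((rsid, estimator(hset.subset(drop=[rsid]))))
    return rows


def exclude_and_reestimate(
    hset: HarmonizedInstrumentSet,
    spec: ExclusionSpec,
    estimator: Callable[[HarmonizedInstrumentSet], MREstimate] = _default_estimator,
) -> MREstimate:
    """Drop the SNPs named in ``spec`` and rerun the estimator.

    An empty exclusion list returns the full-set estimate. Unknown rsids
    raise a configuration error listing them.
    """
    if not spec.rsids:
        return estimator(hset)
    have = set(hset.rsids)
    unknown = sorted(set(spec.rsids) - have)
    if unknown:
        raise ConfigurationError(
            f"exclusion '{spec.label}' names unknown rsid(s): {', '.join(unknown)}"
        )
    remaining = hset.n_snps - len(set(spec.rsids))
    if remaining < 2:
        raise InsufficientInstrumentsError(
            f"exclusion '{spec.label}' leaves {remaining} instrument(s)"
        )
    return estimator(hset.subset(drop=list(spec.rsids)))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> BonferroniThreshold:
    """alpha / n_tests, exact and rounded to 2 significant figures."""
    if n_tests < 1:
        raise DomainError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    exact = alpha / n_tests
    exponent = math.floor(math.log10(exact))
    rounded = round(exact, -exponent + 1)
    return BonferroniThreshold(exact=exact, rounded=rounded,
                               n_tests=n_tests, alpha=alpha)


def mr_power(inp: PowerInput) -> float:
    """Two-sided power for a binary-outcome MR test.

    Uses the noncentrality approximation
    NCP = N * R2 * K(1-K) * ln(OR)^2 and
    power = Phi(-z_{1-a/2} + sqrt(NCP)) + Phi(-z_{1-a/2} - sqrt(NCP)).
    As r2_gx -> 0 this degenerates to alpha.
    """
    k = inp.case_fraction
    ncp = inp.n_total * inp.r2_gx * k * (1.0 - k) * math.log(inp.or_alt) ** 2
    z = stats.norm.ppf(1.0 - inp.alpha / 2.0)
    root = math.sqrt(ncp)
    return float(stats.norm.cdf(-z + root) + stats.norm.cdf(-z - root))


def power_percent(inp: PowerInput) -> int:
    """Power as an integer percentage (nearest-integer rounding)."""
    return int(round(100.0 * mr_power(inp)))
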