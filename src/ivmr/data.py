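"""Data model, file I/O, allele harmonization and effect-scale handling
for two-sample summary statistics.

The unit of data is a :class:`SummaryAssociation` (one SNP, one trait).
Pairs of exposure/outcome associations aligned to a common effect allele
are held in a :class:`HarmonizedInstrumentSet`, which every estimator in
:mod:`ivmr.estimators` consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientInstrumentsError,
    ParseError,
)

__all__ = [
    "SummaryAssociation",
    "HarmonizedInstrumentSet",
    "InstrumentAllowList",
    "read_summary_stats",
    "harmonize",
    "rescale_exposure",
    "DEFAULT_COLUMN_MAP",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return allele  # indels pass through unchanged


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP's association with one trait.

    Parameters
    ----------
    rsid : str
        Variant identifier.
    effect_allele, other_allele : str
        Alleles; upper-cased on construction. Must differ.
    beta : float
        Per-allele effect (exposure units, or log odds ratio for a
        binary outcome).
    se : float
        Standard error of ``beta``; strictly positive.
    eaf : float or None
        Effect-allele frequency in [0, 1], or None when unavailable.
    pval : float or None
        Association p-value in (0, 1].
    n : float or None
        Sample size.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None
    n: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele == self.other_allele:
            raise DomainError(
                f"{self.rsid}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not (self.se > 0) or not math.isfinite(self.se):
            raise DomainError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise DomainError(f"{self.rsid}: beta must be finite, got {self.beta}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise DomainError(f"{self.rsid}: eaf must lie in [0,1], got {self.eaf}")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise DomainError(f"{self.rsid}: pval must lie in (0,1], got {self.pval}")

    @property
    def is_palindromic(self) -> bool:
        return _is_palindromic(self.effect_allele, self.other_allele)

    def flipped(self) -> "SummaryAssociation":
        """Return the association expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def strand_complemented(self) -> "SummaryAssociation":
        return replace(
            self,
            effect_allele=_complement(self.effect_allele),
            other_allele=_complement(self.other_allele),
        )


@dataclass(frozen=True)
class HarmonizedInstrumentSet:
    """J exposure/outcome association pairs on a shared allele orientation.

    ``exposure_scale`` is the multiplicative unit factor applied so far to
    the exposure side (1.0 = original reported units); see
    :func:`rescale_exposure`. ``provenance`` records one
    ``(rsid, action)`` entry per rsid in the intersection of the two
    input panels, including dropped SNPs.
    """

    records: tuple[tuple[SummaryAssociation, SummaryAssociation], ...]
    exposure_scale: float = 1.0
    provenance: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        seen = set()
        for exp, out in self.records:
            if exp.rsid != out.rsid:
                raise ConfigurationError(
                    f"pair rsid mismatch: {exp.rsid!r} vs {out.rsid!r}"
                )
            if exp.effect_allele != out.effect_allele:
                raise ConfigurationError(
                    f"{exp.rsid}: effect alleles differ after harmonization"
                )
            if exp.rsid in seen:
                raise ConfigurationError(f"duplicate rsid {exp.rsid!r}")
            seen.add(exp.rsid)

    # -- array accessors ------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.records)

    @property
    def rsids(self) -> list[str]:
        return [exp.rsid for exp, _ in self.records]

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([exp.beta for exp, _ in self.records], dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([exp.se for exp, _ in self.records], dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([out.beta for _, out in self.records], dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([out.se for _, out in self.records], dtype=float)

    # -- subsetting -----------------------------------------------------
    def subset(self, keep: Sequence[str] | None = None,
               drop: Sequence[str] | None = None) -> "HarmonizedInstrumentSet":
        """Restrict to ``keep`` rsids or remove ``drop`` rsids."""
        if (keep is None) == (drop is None):
            raise ConfigurationError("give exactly one of keep= or drop=")
        have = set(self.rsids)
        wanted = set(keep) if keep is not None else set(drop)
        unknown = sorted(wanted - have)
        if unknown:
            raise ConfigurationError(f"unknown rsids: {', '.join(unknown)}")
        if keep is not None:
            recs = tuple(r for r in self.records if r[0].rsid in wanted)
        else:
            recs = tuple(r for r in self.records if r[0].rsid not in wanted)
        return replace(self, records=recs)

    def subset_indices(self, idx: Sequence[int]) -> "HarmonizedInstrumentSet":
        recs = tuple(self.records[i] for i in idx)
        return replace(self, records=recs)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-SNP table with harmonization provenance."""
        prov = dict(self.provenance)
        rows = []
        for exp, out in self.records:
            rows.append({
                "rsid": exp.rsid,
                "effect_allele": exp.effect_allele,
                "other_allele": exp.other_allele,
                "eaf_exposure": exp.eaf,
                "beta_exposure": exp.beta,
                "se_exposure": exp.se,
                "eaf_outcome": out.eaf,
                "beta_outcome": out.beta,
                "se_outcome": out.se,
                "harmonization": prov.get(exp.rsid, "kept"),
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class InstrumentAllowList:
    """rsID allow-list with gene labels and a trait tag."""

    trait: str
    entries: tuple[tuple[str, str], ...]  # (rsid, gene)

    @property
    def rsids(self) -> list[str]:
        return [r for r, _ in self.entries]

    def gene_of(self, rsid: str) -> str:
        for r, g in self.entries:
            if r == rsid:
                return g
        raise KeyError(rsid)

    def tag(self, associations: Iterable[SummaryAssociation]) -> list[str | None]:
        """Trait tag per association (None when not on the list)."""
        mine = set(self.rsids)
        return [self.trait if a.rsid in mine else None for a in associations]


DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_REQUIRED = ("rsid", "effect_allele", "other_allele", "beta", "se")


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    strict: bool = True,
) -> list[SummaryAssociation]:
    """Read per-SNP summary statistics from a delimited text file.

    Parameters
    ----------
    path : path-like
        Delimited text with a header row.
    column_map : mapping, optional
        Maps canonical names (``rsid``, ``effect_allele``, ``other_allele``,
        ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the file's header
        names. Unmapped optional columns are simply absent.
    sep : str, optional
        Field separator; sniffed when omitted.
    strict : bool
        When True, a malformed row raises :class:`ParseError` naming the
        line; when False malformed rows are skipped with a warning.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [cmap[k] for k in _REQUIRED if cmap[k] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) not found: {', '.join(missing)} "
            f"(available: {', '.join(df.columns)})"
        )

    def _get(row, key, cast=float):
        col = cmap.get(key)
        if col is None or col not in df.columns:
            return None
        raw = row[col]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "" or str(raw).upper() in ("NA", "NAN", "."):
            return None
        return cast(raw)

    out: list[SummaryAssociation] = []
    bad: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        lineno = int(i) + 2  # header is line 1
        try:
            rec = SummaryAssociation(
                rsid=str(row[cmap["rsid"]]).strip(),
                effect_allele=str(row[cmap["effect_allele"]]).strip(),
                other_allele=str(row[cmap["other_allele"]]).strip(),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                eaf=_get(row, "eaf"),
                pval=_get(row, "pval"),
                n=_get(row, "n"),
            )
        except (ValueError, TypeError) as exc:
            bad.append((lineno, str(exc)))
            continue
        out.append(rec)
    if bad:
        msg = "; ".join(f"line {ln}: {m}" for ln, m in bad)
        if strict:
            raise ParseError(f"{path}: {msg}", lines=[ln for ln, _ in bad])
        warnings.warn(f"{path}: skipped {len(bad)} malformed row(s): {msg}")
    return out


def _dedup(assocs: Sequence[SummaryAssociation], strict: bool,
           label: str) -> dict[str, SummaryAssociation]:
    table: dict[str, SummaryAssociation] = {}
    for a in assocs:
        if a.rsid in table:
            if strict:
                raise ParseError(f"duplicate rsid {a.rsid!r} in {label} panel")
            warnings.warn(f"duplicate rsid {a.rsid!r} in {label} panel; keeping first")
            continue
        table[a.rsid] = a
    return table


def harmonize(
    exposure: Sequence[SummaryAssociation],
    outcome: Sequence[SummaryAssociation],
    palindrome_policy: str = "freq-infer",
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    strict: bool = True,
) -> HarmonizedInstrumentSet:
    """Align outcome associations to the exposure's effect alleles.

    For each rsid shared by the two panels the outcome record is brought
    onto the exposure's effect-allele orientation: a swapped effect/other
    pair negates the outcome beta (and complements its eaf); alleles that
    match only after strand complementation are complemented first.
    Palindromic (A/T, C/G) SNPs are handled per ``palindrome_policy``:

    ``"drop"``
        always removed;
    ``"freq-infer"`` (default)
        orientation inferred from allele-frequency concordance; dropped
        when either eaf is missing or falls inside ``ambiguity_window``;
    ``"keep"``
        aligned on nominal alleles, trusting both panels to share strand.

    Non-reconcilable allele pairs are dropped. Every shared rsid receives
    a provenance entry.
    """
    if palindrome_policy not in ("drop", "freq-infer", "keep"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp_by = _dedup(exposure, strict, "exposure")
    out_by = _dedup(outcome, strict, "outcome")
    shared = [r for r in exp_by if r in out_by]
    if len(shared) < 2:
        raise InsufficientInstrumentsError(
            f"only {len(shared)} rsid(s) shared between exposure and outcome"
        )
    lo, hi = ambiguity_window
    records: list[tuple[SummaryAssociation, SummaryAssociation]] = []
    provenance: list[tuple[str, str]] = []
    for rsid in shared:
        exp, out = exp_by[rsid], out_by[rsid]
        ea, oa = exp.effect_allele, exp.other_allele
        if exp.is_palindromic:
            if palindrome_policy == "drop":
                provenance.append((rsid, "dropped-palindromic"))
                continue
            # nominal alignment first
            if (out.effect_allele, out.other_allele) == (ea, oa):
                aligned, action = out, "kept"
            elif (out.effect_allele, out.other_allele) == (oa, ea):
                aligned, action = out.flipped(), "flipped"
            else:
                provenance.append((rsid, "dropped-mismatch"))
                continue
            if palindrome_policy == "freq-infer":
                if exp.eaf is None or aligned.eaf is None:
                    provenance.append((rsid, "dropped-palindromic"))
                    continue
                if lo < exp.eaf < hi or lo < aligned.eaf < hi:
                    provenance.append((rsid, "dropped-palindromic"))
                    continue
                if (exp.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
                    # frequency-discordant: outcome is on the other strand,
                    # which for a palindrome means the other allele
                    aligned = aligned.flipped()
                    aligned = replace(aligned, effect_allele=ea, other_allele=oa)
                    action = "flipped" if action == "kept" else "kept"
            records.append((exp, aligned))
            provenance.append((rsid, action))
            continue
        # non-palindromic
        pair = (out.effect_allele, out.other_allele)
        if pair == (ea, oa):
            records.append((exp, out))
            provenance.append((rsid, "kept"))
        elif pair == (oa, ea):
            records.append((exp, out.flipped()))
            provenance.append((rsid, "flipped"))
        else:
            comp = out.strand_complemented()
            cpair = (comp.effect_allele, comp.other_allele)
            if cpair == (ea, oa):
                records.append((exp, comp))
                provenance.append((rsid, "kept-strand"))
            elif cpair == (oa, ea):
                records.append((exp, comp.flipped()))
                provenance.append((rsid, "flipped-strand"))
            else:
                provenance.append((rsid, "dropped-mismatch"))
    return HarmonizedInstrumentSet(
        records=tuple(records), exposure_scale=1.0, provenance=tuple(provenance)
    )


def rescale_exposure(hset: HarmonizedInstrumentSet,
                     unit: float) -> HarmonizedInstrumentSet:
    """Re-express the exposure per ``unit`` of its current reporting unit.

    Exposure betas and SEs are divided by ``unit`` so that downstream
    causal estimates (which divide by the exposure beta) come out per
    ``unit``; e.g. ``unit=0.1`` turns per-mmol/L estimates into
    per-0.1-mmol/L estimates. ``unit=1`` is the identity.
    """
    if not (unit > 0) or not math.isfinite(unit):
        raise DomainError(f"unit must be finite and > 0, got {unit}")
    if unit == 1.0:
        return hset
    new_records = tuple(
        (replace(exp, beta=exp.beta / unit, se=exp.se / unit), out)
        for exp, out in hset.records
    )
    return replace(hset, records=new_records,
                   exposure_scale=hset.exposure_scale * unit)
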