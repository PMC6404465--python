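"""Packaged instrument allow-lists and exclusion metadata.

The serum-mineral instrument panels: 6 magnesium-associated and 7
calcium-associated genome-wide-significant, independent SNPs, with the
gene label nearest each locus, plus the named sensitivity-exclusion
sets (outlier locus, atrial-fibrillation-associated loci, pleiotropic
metabolic locus).
"""

from __future__ import annotations

from .data import InstrumentAllowList
from .sensitivity import ExclusionSpec

__all__ = [
    "MAGNESIUM_INSTRUMENTS",
    "CALCIUM_INSTRUMENTS",
    "EXCLUSION_SPECS",
]

MAGNESIUM_INSTRUMENTS = InstrumentAllowList(
    trait="magnesium",
    entries=(
        ("rs4072037", "MUC1"),
        ("rs448378", "MDS1"),
        ("rs13146355", "SHROOM3"),
        ("rs11144134", "TRPM6"),
        ("rs3925584", "DCDC5"),
        ("rs7965584", "ATP2B1"),
    ),
)

CALCIUM_INSTRUMENTS = InstrumentAllowList(
    trait="calcium",
    entries=(
        ("rs1801725", "CASR"),
        ("rs1550532", "DGKD"),
        ("rs780094", "GCKR"),
        ("rs10491003", "GATA3"),
        ("rs7481584", "CARS"),
        ("rs7336933", "DGKH"),
        ("rs1570669", "CYP24A1"),
    ),
)


def _rsid(allow: InstrumentAllowList, gene: str) -> str:
    for r, g in allow.entries:
        if g == gene:
            return r
    raise KeyError(gene)


EXCLUSION_SPECS: dict[str, ExclusionSpec] = {
    "trpm6": ExclusionSpec(
        label="TRPM6 outlier",
        rsids=(_rsid(MAGNESIUM_INSTRUMENTS, "TRPM6"),),
        reason="flagged as an outlier in the cardioembolic-stroke analysis",
    ),
    "atrial-fibrillation": ExclusionSpec(
        label="atrial-fibrillation SNPs",
        rsids=(
            _rsid(MAGNESIUM_INSTRUMENTS, "MUC1"),
            _rsid(MAGNESIUM_INSTRUMENTS, "SHROOM3"),
        ),
        reason="associated with atrial fibrillation, a cardioembolic-stroke intermediate",
    ),
    "gckr": ExclusionSpec(
        label="GCKR",
        rsids=(_rsid(CALCIUM_INSTRUMENTS, "GCKR"),),
        reason="pleiotropic associations with blood lipids and type 2 diabetes",
    ),
}
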