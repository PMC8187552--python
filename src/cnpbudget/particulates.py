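"""Particulate-P composition and flow-cytometric carbon biomass.

Total particulate phosphorus (TPP) is chemically fractionated into eight
pools (orthophosphate, sugar P, nucleotide P, nucleic acid P, lipid P,
acid-soluble and acid-insoluble poly P, residual P); their proportions of
the TPP total track how microbes store freshly supplied PO4.  Carbon
biomass of the picoplankton groups is cell abundance times a fixed
per-cell carbon quota.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TPP_FRACTIONS",
    "TppComposition",
    "CellQuotaTable",
    "tpp_proportions",
    "fcm_carbon_biomass",
]

TPP_FRACTIONS = (
    "orthophosphate",
    "sugar P",
    "nucleotide P",
    "nucleic acid P",
    "lipid P",
    "acid-soluble poly P",
    "acid-insoluble poly P",
    "residual P",
)


@dataclass
class TppComposition:
    """P content of each chemical fraction (mol P m-3), optionally with
    triplicate CVs for the <= 10 % reliability QC flag."""

    fractions: dict[str, float]
    cv: dict[str, float] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(TPP_FRACTIONS)
        if unknown:
            raise ValueError(f"unknown TPP fractions: {sorted(unknown)}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fraction amounts must be non-negative")

    @property
    def tpp_total(self) -> float:
        return float(sum(self.fractions.values()))

    def reliable(self, max_cv: float = 0.10) -> bool:
        """True when every supplied triplicate CV is within ``max_cv``."""
        if not self.cv:
            return True
        return all(c <= max_cv for c in self.cv.values())


@dataclass(frozen=True)
class CellQuotaTable:
    """Cellular carbon quotas (mol C cell-1) of the picoplankton groups."""

    quota: dict[str, float] = field(
        default_factory=lambda: {
            "Prochlorococcus": 5.2e-15,
            "Synechococcus": 3.0e-14,
            "eukaryotes": 3.9e-13,
        }
    )

    def __post_init__(self) -> None:
        if any(q <= 0 for q in self.quota.values()):
            raise ValueError("carbon quotas must be positive")


def tpp_proportions(comp: TppComposition) -> dict[str, float]:
    """Each fraction's share of the TPP total (shares sum to 1)."""
    total = comp.tpp_total
    if total <= 0:
        raise ValueError("TPP total must be positive to form proportions")
    return {name: amount / total for name, amount in comp.fractions.items()}


def fcm_carbon_biomass(
    counts: dict[str, float], quotas: CellQuotaTable | None = None
) -> tuple[dict[str, float], dict[str, float] | None]:
    """Carbon biomass (mol C L-1) per group and each group's biomass share.

    ``counts`` are cell abundances (cells L-1).  With zero total biomass
    the shares are undefined and returned as ``None``.
    """
    quotas = quotas or CellQuotaTable()
    biomass: dict[str, float] = {}
    for group, count in counts.items():
        if count < 0:
            raise ValueError(f"negative cell count for {group}")
        try:
            biomass[group] = count * quotas.quota[group]
        except KeyError as exc:
            raise ValueError(f"no carbon quota for group {group!r}") from exc
    total = sum(biomass.values())
    if total <= 0 or not np.isfinite(total):
        return biomass, None
    shares = {g: b / total for g, b in biomass.items()}
    return biomass, shares
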