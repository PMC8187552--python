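"""Annual C-N-P budget closure over SST regimes.

The year is partitioned into four sea-surface-temperature regimes
(< 24, 24-26, 26-28, > 28 degC) standing in for season.  For each element
Y in {C, N, P} the annual requirement of net community production in the
0-100 m layer is closed as

    NCP-Y = Fup_Y + Fat_Y

where Fup_Y is the annual upward turbulent influx from the 100-200 m
subsurface layer (regime mean daily flux x regime days, summed) and Fat_Y
the atmospheric-side influx: air-sea CO2 flux for C, marine N2 fixation
plus atmospheric N deposition for N, atmospheric P deposition for P.
Lateral influxes and transport by vertically migrating diatoms are taken
as zero (overridable), consistent with the absence of horizontal surface
gradients and the very low migrating-diatom abundance in the study region.

From NCP-C and a microbial C:N / C:P stoichiometric range the microbial
demand MD and recycling factor RF = MD / NCP follow per element.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .uncertainty import UncertainValue, mean_with_ci, propagate, round_sig, scale

__all__ = [
    "REGIMES",
    "RegimeClimatology",
    "AtmosphericForcing",
    "StoichiometryRange",
    "ElementBudget",
    "BudgetResult",
    "classify_sst_regime",
    "regime_days",
    "annual_upward_influx",
    "annual_atmospheric_influx",
    "ncp_requirement",
    "stoichiometric_ratio",
    "microbial_demand",
    "recycling_factor",
]

log = logging.getLogger(__name__)

#: Ordered SST regime labels; bins are (-inf, 24), [24, 26), [26, 28), [28, inf).
REGIMES: tuple[str, ...] = ("SST<24", "24-26", "26-28", "SST>28")

_EDGES = (24.0, 26.0, 28.0)

DAYS_PER_YEAR = 365.0
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


def classify_sst_regime(sst: float) -> str:
    """Assign an SST (degC) to a regime; lower bin edges are inclusive."""
    if not np.isfinite(sst):
        raise ValueError(f"SST must be finite, got {sst}")
    if sst < _EDGES[0]:
        return REGIMES[0]
    if sst < _EDGES[1]:
        return REGIMES[1]
    if sst < _EDGES[2]:
        return REGIMES[2]
    return REGIMES[3]


@dataclass(frozen=True)
class RegimeClimatology:
    """Month and day counts per SST regime (months sum to 12, days to 365)."""

    months: dict[str, int]
    days: dict[str, float]

    def __post_init__(self) -> None:
        if sum(self.months.values()) != 12:
            raise ValueError("regime months must sum to 12")
        if abs(sum(self.days.values()) - DAYS_PER_YEAR) > 1e-9:
            raise ValueError("regime days must sum to 365")


def regime_days(monthly_sst) -> RegimeClimatology:
    """Count months per regime from a 12-value monthly SST series.

    Days per regime are months x 365/12 (uniform month length).
    """
    sst = np.asarray(monthly_sst, dtype=float)
    if sst.shape != (12,):
        raise ValueError(f"need exactly 12 monthly SST values, got {sst.shape}")
    months = {r: 0 for r in REGIMES}
    for t in sst:
        months[classify_sst_regime(float(t))] += 1
    days = {r: m * DAYS_PER_MONTH for r, m in months.items()}
    return RegimeClimatology(months, days)


@dataclass(frozen=True)
class AtmosphericForcing:
    """Atmosphere-side forcing rates with 95 % CIs.

    ``co2_flux_monthly`` is the mean monthly air-sea CO2 flux per SST
    regime in mol C m-2 month-1, positive into the ocean (individual
    regimes may be negative, i.e. outgassing).  Fixation/deposition rates
    are daily and must be non-negative.
    """

    co2_flux_monthly: dict[str, UncertainValue]
    n2_fixation_rate: UncertainValue  # mol N m-2 d-1
    n_deposition_rate: UncertainValue  # mol N m-2 d-1
    p_deposition_rate: UncertainValue  # mol P m-2 d-1
    lateral_flux: dict[str, float] = field(
        default_factory=lambda: {"C": 0.0, "N": 0.0, "P": 0.0}
    )

    def __post_init__(self) -> None:
        for name, rate in (
            ("n2_fixation_rate", self.n2_fixation_rate),
            ("n_deposition_rate", self.n_deposition_rate),
            ("p_deposition_rate", self.p_deposition_rate),
        ):
            if rate.m < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StoichiometryRange:
    """Molar C:N and C:P intervals of the resident microbial community."""

    cn: tuple[float, float] = (6.0, 11.0)
    cp: tuple[float, float] = (107.0, 243.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("cn", self.cn), ("cp", self.cp)):
            if not (0 < lo <= hi):
                raise ValueError(f"invalid {name} range ({lo}, {hi})")


@dataclass(frozen=True)
class ElementBudget:
    """Closed annual budget of one element (all mol m-2 y-1)."""

    element: str
    fup: UncertainValue
    fat: UncertainValue
    ncp: UncertainValue


@dataclass(frozen=True)
class BudgetResult:
    """Annual three-element budget with stoichiometry, demand and recycling."""

    elements: dict[str, ElementBudget]
    ncp_ratio: tuple[UncertainValue, UncertainValue, float]
    fup_ratio: tuple[UncertainValue, UncertainValue, float]
    md_n: tuple[float, float]
    md_p: tuple[float, float]
    rf: dict[str, tuple[float, float]]


def annual_upward_influx(
    regime_fluxes: dict[str, list[float]],
    clim: RegimeClimatology,
) -> UncertainValue:
    """Annual upward influx: sum over regimes of mean daily flux x days.

    ``regime_fluxes`` maps regime label to per-cast daily layer-mean
    fluxes (mol m-2 d-1) in the 100-200 m subsurface layer.  The CI of
    each regime term scales with its day count; terms combine in
    quadrature.  A regime with days but no flux data contributes zero and
    logs a warning.
    """
    total = UncertainValue(0.0, 0.0)
    any_data = False
    for regime in REGIMES:
        days = clim.days.get(regime, 0.0)
        samples = regime_fluxes.get(regime) or []
        if days <= 0:
            continue
        if len(samples) == 0:
            log.warning(
                "SST regime %s has %.0f days but no flux data; contributes zero",
                regime,
                days,
            )
            continue
        any_data = True
        daily = (
            mean_with_ci(samples)
            if len(samples) > 1
            else UncertainValue(float(samples[0]), 0.0, 1)
        )
        total = propagate("sum", total, scale(daily, days))
    if not any_data:
        raise ValueError("no flux data in any SST regime with nonzero days")
    return total


def annual_atmospheric_influx(
    element: str,
    forcing: AtmosphericForcing,
    clim: RegimeClimatology,
) -> UncertainValue:
    """Annual atmosphere-side influx Fat_Y (mol m-2 y-1) for Y in C, N, P."""
    if element == "C":
        total = UncertainValue(0.0, 0.0)
        for regime in REGIMES:
            months = clim.months.get(regime, 0)
            if months == 0:
                continue
            try:
                monthly = forcing.co2_flux_monthly[regime]
            except KeyError as exc:
                raise ValueError(f"no CO2 flux for regime {regime}") from exc
            total = propagate("sum", total, scale(monthly, months))
        return total
    if element == "N":
        daily = propagate("sum", forcing.n2_fixation_rate, forcing.n_deposition_rate)
        return scale(daily, DAYS_PER_YEAR)
    if element == "P":
        return scale(forcing.p_deposition_rate, DAYS_PER_YEAR)
    raise ValueError(f"unknown element {element!r}")


def ncp_requirement(fup: UncertainValue, fat: UncertainValue) -> UncertainValue:
    """NCP-Y = Fup_Y + Fat_Y with quadrature CI (exact closure identity)."""
    return propagate("sum", fup, fat)


def stoichiometric_ratio(
    c: UncertainValue, n: UncertainValue, p: UncertainValue
) -> tuple[UncertainValue, UncertainValue, float]:
    """C:N:P normalised to P = 1, with quotient CI propagation per term."""
    if p.m <= 0:
        raise ValueError("P term must be positive to normalise a ratio")
    return propagate("quotient", c, p), propagate("quotient", n, p), 1.0


def microbial_demand(
    ncp_c: UncertainValue, stoich: StoichiometryRange
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Elemental demand implied by NCP-C and the microbial C:N / C:P range.

    MD-N = [NCP-C / (C:N)_upper, NCP-C / (C:N)_lower] (mol N m-2 y-1) and
    likewise MD-P from the C:P range.  Full precision is returned; round
    with :func:`cnpbudget.uncertainty.round_sig` for reporting.
    """
    if ncp_c.m <= 0:
        raise ValueError("NCP-C must be positive")
    md_n = (ncp_c.m / stoich.cn[1], ncp_c.m / stoich.cn[0])
    md_p = (ncp_c.m / stoich.cp[1], ncp_c.m / stoich.cp[0])
    return md_n, md_p


def recycling_factor(
    md: tuple[float, float], ncp: UncertainValue
) -> tuple[float, float]:
    """RF = MD / NCP: how often the element is recycled to meet demand."""
    if ncp.m <= 0:
        raise ValueError("NCP must be positive")
    lo, hi = md
    if not lo <= hi:
        raise ValueError("demand interval must be ordered")
    return lo / ncp.m, hi / ncp.m


def format_interval(interval: tuple[float, float], sig: int = 2) -> str:
    lo, hi = (round_sig(v, sig) for v in interval)
    return f"{lo:g}~{hi:g}"
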