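"""Per-cast physical and inventory computations.

A :class:`Cast` is one station visit: bottle depths (0-200 m, positive
downward) with temperature (treated as potential temperature), practical
salinity, optionally PAR, and dissolved/particulate constituent
concentrations in mol m-3.  This module derives from each cast:

* mixed layer depth (MLD): shallowest depth where the potential temperature
  is 0.2 degC below its 10-m value, linearly interpolated;
* euphotic zone depth (EZD): depth of 1 % of surface PAR, log-linearly
  interpolated (PAR decays ~exponentially);
* potential density (EOS-80, one atmosphere) and the squared buoyancy
  frequency N^2 on a 5-m grid;
* salinity-normalised concentrations (reference salinity 34.91, removing
  evaporation/precipitation dilution);
* detection-limit substitution for nanomolar N+N and PO4;
* trapezoidal water-column inventories and their regime differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .budget import classify_sst_regime
from .uncertainty import UncertainValue, mean_with_ci, propagate

__all__ = [
    "Cast",
    "CastSummary",
    "NormalizationConfig",
    "NM_TO_MOL_M3",
    "compute_mld",
    "compute_ezd",
    "substitute_below_detection",
    "normalize_to_reference_salinity",
    "density_sigma0",
    "n_sq_from_density",
    "buoyancy_frequency_sq",
    "depth_integrate",
    "regime_inventory_difference",
]

#: 1 nmol L-1 expressed in mol m-3.
NM_TO_MOL_M3 = 1e-6

G = 9.81  # m s-2
RHO0 = 1025.0  # kg m-3 reference density

MLD_DELTA_T = 0.2  # degC below the 10-m potential temperature
EZD_FRACTION = 0.01  # 1 % of surface PAR


@dataclass
class Cast:
    """One station visit with depth-resolved hydrography and chemistry.

    ``depth`` is metres, positive downward, strictly increasing.
    ``concentrations`` maps constituent name (``DIC``, ``N+N``, ``PO4``,
    ``DOP``, ``TDP``, ``TPP``) to mol m-3 on the same depths.  ``sst`` is
    the 10-m temperature used for SST-regime classification.
    """

    station: str
    date: str
    sst: float
    depth: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    par: np.ndarray | None = None
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        if self.par is not None:
            self.par = np.asarray(self.par, dtype=float)
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        if self.depth.size < 1:
            raise ValueError("cast needs at least one depth")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.salinity <= 0):
            raise ValueError("salinity must be positive")
        for name, arr in self.concentrations.items():
            if arr.shape != self.depth.shape:
                raise ValueError(f"{name} concentrations not aligned with depths")


@dataclass(frozen=True)
class CastSummary:
    """MLD and EZD of a cast, with not-reached flags."""

    mld: float
    ezd: float | None
    mld_not_reached: bool = False
    ezd_not_reached: bool = False


@dataclass(frozen=True)
class NormalizationConfig:
    """Reference salinity and nanomolar detection handling.

    ``detection_limits`` / ``detection_substitution`` are in nM and apply
    to the constituents named; defaults follow the nanomolar analysis
    limits (combined N+N 5 nM, PO4 3 nM) with below-detection values
    replaced by 5 and 3 nM respectively.
    """

    reference_salinity: float = 34.91
    detection_limits: dict[str, float] = field(
        default_factory=lambda: {"N+N": 5.0, "PO4": 3.0}
    )
    detection_substitution: dict[str, float] = field(
        default_factory=lambda: {"N+N": 5.0, "PO4": 3.0}
    )

    def __post_init__(self) -> None:
        if self.reference_salinity <= 0:
            raise ValueError("reference salinity must be positive")


def _interp_at(depth: np.ndarray, values: np.ndarray, z: float) -> float:
    return float(np.interp(z, depth, values))


def compute_mld(cast: Cast) -> tuple[float, bool]:
    """Mixed layer depth: theta(z) = theta(10 m) - 0.2 degC, linear in z.

    Returns ``(mld_m, not_reached)``.  Scans downward from 10 m; if a
    sampled level hits the threshold exactly it is returned as-is; if the
    criterion is never met the deepest depth is returned flagged.
    """
    z, t = cast.depth, cast.temperature
    if z[-1] < 10.0:
        raise ValueError("no data at or below 10 m; cannot evaluate the MLD criterion")
    t10 = _interp_at(z, t, 10.0)
    target = t10 - MLD_DELTA_T
    below = z >= 10.0
    zs = np.concatenate(([10.0], z[below])) if 10.0 not in z[below] else z[below]
    ts = np.interp(zs, z, t)
    for i in range(1, zs.size):
        lo, hi = ts[i - 1], ts[i]
        if ts[i] == target:
            return float(zs[i]), False
        if (lo - target) * (hi - target) < 0:
            frac = (lo - target) / (lo - hi)
            return float(zs[i - 1] + frac * (zs[i] - zs[i - 1])), False
    return float(z[-1]), True


def compute_ezd(cast: Cast) -> tuple[float, bool]:
    """Euphotic zone depth: 1 % of surface PAR, log-linear interpolation."""
    if cast.par is None:
        raise ValueError("cast has no PAR profile")
    z, p = cast.depth, cast.par
    p0 = float(p[0])
    if not p0 > 0:
        raise ValueError("surface PAR must be positive")
    target = EZD_FRACTION * p0
    for i in range(z.size):
        if p[i] == target:
            return float(z[i]), False
        if p[i] < target:
            if i == 0:  # cannot happen: p[0] > target by construction
                return float(z[0]), False
            lo = max(float(p[i]), 1e-300)
            frac = (np.log(p[i - 1]) - np.log(target)) / (np.log(p[i - 1]) - np.log(lo))
            return float(z[i - 1] + frac * (z[i] - z[i - 1])), False
    return float(z[-1]), True


def substitute_below_detection(cast: Cast, config: NormalizationConfig) -> Cast:
    """Replace below-detection nanomolar values by the convention values.

    N+N below its combined detection limit becomes 5 nM and PO4 below its
    limit becomes 3 nM (configurable).  Other constituents are untouched;
    the operation is idempotent.  Returns a new cast.
    """
    new_conc = dict(cast.concentrations)
    for name, limit_nm in config.detection_limits.items():
        if name not in new_conc or name not in config.detection_substitution:
            continue
        limit = limit_nm * NM_TO_MOL_M3
        sub = config.detection_substitution[name] * NM_TO_MOL_M3
        arr = new_conc[name].copy()
        arr[arr < limit] = sub
        new_conc[name] = arr
    return replace(cast, concentrations=new_conc)


def normalize_to_reference_salinity(x, s, config: NormalizationConfig | None = None):
    """Scale concentration(s) by reference_salinity / observed salinity."""
    config = config or NormalizationConfig()
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("salinity must be positive")
    out = np.asarray(x, dtype=float) * (config.reference_salinity / s)
    return float(out) if out.ndim == 0 else out


def density_sigma0(t, s):
    """Seawater density (kg m-3) at one atmosphere, EOS-80 polynomial.

    Temperature is taken as potential temperature referenced to the
    surface (at <= 200 dbar the adiabatic correction is far below the
    0.2 degC MLD threshold), salinity is practical salinity.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    rho = rho_w + a * s + b * s**1.5 + c * s**2
    return float(rho) if rho.ndim == 0 else rho


def n_sq_from_density(depth, rho) -> np.ndarray:
    """N^2 = (g / rho0) * d(rho_theta)/dz, depth positive downward.

    Centred differences at interior points, one-sided at the ends; a
    statically stable column (density increasing downward) gives N^2 > 0.
    """
    depth = np.asarray(depth, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if depth.size < 2:
        raise ValueError("need at least two levels for N^2")
    return (G / RHO0) * np.gradient(rho, depth)


def buoyancy_frequency_sq(
    cast: Cast, dz: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """N^2 (s-2) on a ``dz``-interval grid from the cast's T and S.

    Potential density (EOS-80, surface reference) is interpolated to the
    grid and differentiated with :func:`n_sq_from_density`.
    """
    if cast.depth.size < 2:
        raise ValueError("need at least two levels for N^2")
    grid = _five_m_grid(cast.depth, dz)
    t = np.interp(grid, cast.depth, cast.temperature)
    s = np.interp(grid, cast.depth, cast.salinity)
    rho = density_sigma0(t, s)
    return grid, n_sq_from_density(grid, rho)


def _five_m_grid(depth: np.ndarray, dz: float = 5.0) -> np.ndarray:
    lo = dz * np.ceil(depth[0] / dz)
    hi = dz * np.floor(depth[-1] / dz)
    if hi < lo:
        raise ValueError("sampled range narrower than one grid interval")
    return np.arange(lo, hi + dz / 2, dz)


def depth_integrate(depth, values, z0: float, z1: float) -> float:
    """Trapezoidal water-column inventory of a profile over [z0, z1].

    The profile is treated as piecewise linear between samples; endpoint
    values at z0/z1 are linearly interpolated, with nearest-sample
    (constant) extension when they fall outside the sampled range.
    Returns mol m-2 for a mol m-3 profile.
    """
    depth = np.asarray(depth, dtype=float)
    values = np.asarray(values, dtype=float)
    if depth.size == 0:
        raise ValueError("empty profile")
    if not z0 < z1:
        raise ValueError("require z0 < z1")
    interior = depth[(depth > z0) & (depth < z1)]
    zs = np.concatenate(([z0], interior, [z1]))
    vs = np.interp(zs, depth, values)  # np.interp extends with edge values
    return float(np.trapezoid(vs, zs))


def regime_inventory_difference(
    inventories,
    ssts,
    regime_a: str,
    regime_b: str,
) -> UncertainValue:
    """Mean inventory difference regime_a - regime_b with propagated CI.

    ``inventories`` are per-cast mol m-2 values and ``ssts`` the matching
    cast SSTs; each cast is assigned to an SST regime and the two regime
    means (t-based 95 % CI) are differenced with quadrature propagation.
    """
    inventories = np.asarray(inventories, dtype=float)
    ssts = np.asarray(ssts, dtype=float)
    if inventories.shape != ssts.shape:
        raise ValueError("inventories and SSTs must align")
    labels = np.array([classify_sst_regime(t) for t in ssts])
    in_a = inventories[labels == regime_a]
    in_b = inventories[labels == regime_b]
    if in_a.size < 2 or in_b.size < 2:
        raise ValueError("need at least two casts in each regime")
    return propagate("difference", mean_with_ci(in_a), mean_with_ci(in_b))
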