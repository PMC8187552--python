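"""Turbulent diffusive fluxes of dissolved constituents.

Microstructure profilers deliver the turbulent kinetic energy dissipation
rate epsilon (W kg-1) on a 5-m grid.  With the squared buoyancy frequency
N^2 the Osborn relation gives the diapycnal diffusivity

    Kz = Gamma * epsilon / N^2,   Gamma = 0.2 (mixing efficiency)

and the vertical diffusive flux of a constituent X follows as
F_X = Kz * dX/dz, positive when concentration increases with depth, i.e.
positive flux = upward supply (depth axis positive downward).  Fluxes are
averaged over two layers: MLD-100 m (supply into the mixed layer, kept for
inspection but excluded from budgets) and 100-200 m (upward supply into
the euphotic zone, the Fup term of the annual budget).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .uncertainty import UncertainValue, mean_with_ci

__all__ = [
    "MIXING_EFFICIENCY",
    "SECONDS_PER_DAY",
    "TurbulenceProfile",
    "DiffusivityProfile",
    "FluxProfile",
    "LayerFlux",
    "osborn_diffusivity",
    "interpolate_concentration_5m",
    "vertical_gradient",
    "diffusive_flux_profile",
    "layer_mean_flux",
]

MIXING_EFFICIENCY = 0.2
SECONDS_PER_DAY = 86_400.0
GRID_DZ = 5.0


@dataclass
class TurbulenceProfile:
    """Dissipation rate and buoyancy frequency on a 5-m depth grid."""

    station: str
    date: str
    depth: np.ndarray  # m, positive downward, 5-m spacing
    epsilon: np.ndarray  # W kg-1
    n_sq: np.ndarray  # s-2

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.n_sq = np.asarray(self.n_sq, dtype=float)
        if not (self.depth.shape == self.epsilon.shape == self.n_sq.shape):
            raise ValueError("depth, epsilon and n_sq must align")
        if self.depth.size >= 2 and not np.allclose(np.diff(self.depth), GRID_DZ):
            raise ValueError("turbulence grid spacing must be 5 m")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")


@dataclass
class DiffusivityProfile:
    """Osborn diffusivity Kz (m2 s-1) with a validity mask (N^2 > 0)."""

    depth: np.ndarray
    kz: np.ndarray
    valid: np.ndarray

    @property
    def masked_fraction(self) -> float:
        return 1.0 - float(np.mean(self.valid)) if self.valid.size else 0.0


@dataclass
class FluxProfile:
    """Diffusive flux (mol m-2 d-1) and gradient (mol m-4) per depth."""

    constituent: str
    depth: np.ndarray
    flux: np.ndarray
    gradient: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class LayerFlux:
    """Mean flux over a layer, e.g. ('MLD_to_100', 'PO4')."""

    layer: str
    constituent: str
    value: UncertainValue
    n_points: int
    empty: bool = False


def osborn_diffusivity(
    turb: TurbulenceProfile, mixing_efficiency: float = MIXING_EFFICIENCY
) -> DiffusivityProfile:
    """Kz = mixing_efficiency * epsilon / N^2 where N^2 > 0, else masked."""
    valid = (turb.n_sq > 0) & np.isfinite(turb.epsilon) & np.isfinite(turb.n_sq)
    kz = np.zeros_like(turb.epsilon)
    np.divide(
        mixing_efficiency * turb.epsilon, turb.n_sq, out=kz, where=valid
    )
    return DiffusivityProfile(turb.depth.copy(), kz, valid)


def interpolate_concentration_5m(cast, constituent: str) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of a sampled constituent onto the 5-m grid.

    The grid spans only the sampled depth range (no extrapolation).
    """
    try:
        values = cast.concentrations[constituent]
    except KeyError as exc:
        raise ValueError(f"cast has no {constituent} profile") from exc
    depth = cast.depth
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError(f"need >= 2 sampled depths for {constituent}")
    depth, values = depth[finite], values[finite]
    lo = GRID_DZ * np.ceil(depth[0] / GRID_DZ)
    hi = GRID_DZ * np.floor(depth[-1] / GRID_DZ)
    grid = np.arange(lo, hi + GRID_DZ / 2, GRID_DZ)
    return grid, np.interp(grid, depth, values)


def vertical_gradient(depth: np.ndarray, values: np.ndarray) -> np.ndarray:
    """dX/dz (z positive downward): centred interior, one-sided at ends."""
    depth = np.asarray(depth, dtype=float)
    values = np.asarray(values, dtype=float)
    if depth.size < 2:
        raise ValueError("need at least two grid points for a gradient")
    return np.gradient(values, depth)


def diffusive_flux_profile(
    kz: DiffusivityProfile,
    grad_depth: np.ndarray,
    gradient: np.ndarray,
    constituent: str = "X",
) -> FluxProfile:
    """F_X = Kz * dX/dz on the common depth range, in mol m-2 d-1.

    The two profiles are intersected on depth; grid points present in only
    one input are dropped.  Flux keeps the gradient's sign: positive where
    concentration increases downward (upward supply).
    """
    grad_depth = np.asarray(grad_depth, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    common, ik, ig = np.intersect1d(kz.depth, grad_depth, return_indices=True)
    if common.size == 0:
        raise ValueError("diffusivity and gradient grids do not overlap")
    flux = kz.kz[ik] * gradient[ig] * SECONDS_PER_DAY
    valid = kz.valid[ik] & np.isfinite(gradient[ig])
    flux = np.where(valid, flux, np.nan)
    return FluxProfile(constituent, common, flux, gradient[ig], valid)


def layer_mean_flux(
    flux: FluxProfile, layer_top: float, layer_bottom: float, layer: str | None = None
) -> LayerFlux:
    """Unweighted mean flux over valid 5-m points with top < z <= bottom."""
    name = layer if layer is not None else f"{layer_top:g}_to_{layer_bottom:g}"
    sel = (flux.depth > layer_top) & (flux.depth <= layer_bottom) & flux.valid
    vals = flux.flux[sel]
    if vals.size == 0:
        return LayerFlux(name, flux.constituent, UncertainValue(float("nan"), float("nan")), 0, empty=True)
    value = mean_with_ci(vals) if vals.size > 1 else UncertainValue(float(vals[0]), float("nan"), 1)
    return LayerFlux(name, flux.constituent, value, int(vals.size))
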