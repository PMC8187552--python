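"""End-to-end orchestration: casts -> fluxes -> regimes -> annual budget.

`run_full_budget` takes a dataset (synthetic or loaded from CSV/YAML),
derives per-cast MLD/EZD, salinity-normalised inventories and diffusive
flux profiles, classifies casts into SST regimes, closes the annual
C-N-P budget and reports stoichiometric ratios, microbial demands and
recycling factors as a JSON-serialisable dictionary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import budget as bd
from . import hydrography as hyd
from . import io as pio
from . import turbulence as tb
from .stats import kruskal_wallis_with_dunn
from .synthetic import ScenarioConfig, SyntheticDataset, generate_cruise_dataset
from .uncertainty import UncertainValue, round_sig

__all__ = ["CastAnalysis", "analyze_casts", "run_full_budget", "run_from_config",
           "make_fixtures", "SCENARIOS"]

log = logging.getLogger(__name__)

#: budget element -> dissolved constituent carrying its upward flux
ELEMENT_CONSTITUENT = {"C": "DIC", "N": "N+N", "P": "PO4"}

SUBSURFACE = (100.0, 200.0)  # layer whose mean flux is the budget Fup term


@dataclass
class CastAnalysis:
    """Everything derived from one cast."""

    cast: "hyd.Cast"
    summary: hyd.CastSummary
    regime: str
    inventories_0_100: dict[str, float] = field(default_factory=dict)
    inventories_100_200: dict[str, float] = field(default_factory=dict)
    subsurface_flux: dict[str, tb.LayerFlux] = field(default_factory=dict)
    mixed_layer_flux: dict[str, tb.LayerFlux] = field(default_factory=dict)
    masked_kz_fraction: float = 0.0


def _analyze_one(
    cast: hyd.Cast,
    turb: tb.TurbulenceProfile | None,
    norm: hyd.NormalizationConfig,
    constituents: tuple[str, ...],
) -> CastAnalysis:
    cast = hyd.substitute_below_detection(cast, norm)
    mld, mld_flag = hyd.compute_mld(cast)
    if cast.par is not None:
        ezd, ezd_flag = hyd.compute_ezd(cast)
    else:
        ezd, ezd_flag = None, True
    summary = hyd.CastSummary(mld, ezd, mld_flag, ezd_flag)
    out = CastAnalysis(cast, summary, bd.classify_sst_regime(cast.sst))

    for name in ("DIC", "N+N", "PO4", "DOP", "TPP"):
        if name not in cast.concentrations:
            continue
        normed = hyd.normalize_to_reference_salinity(
            cast.concentrations[name], cast.salinity, norm
        )
        out.inventories_0_100[name] = hyd.depth_integrate(cast.depth, normed, 0.0, 100.0)
        out.inventories_100_200[name] = hyd.depth_integrate(cast.depth, normed, 100.0, 200.0)

    if turb is not None:
        kz = tb.osborn_diffusivity(turb)
        out.masked_kz_fraction = kz.masked_fraction
        for name in constituents:
            if name not in cast.concentrations:
                continue
            grid, conc = tb.interpolate_concentration_5m(cast, name)
            grad = tb.vertical_gradient(grid, conc)
            flux = tb.diffusive_flux_profile(kz, grid, grad, name)
            out.subsurface_flux[name] = tb.layer_mean_flux(flux, *SUBSURFACE, layer="100_to_200")
            out.mixed_layer_flux[name] = tb.layer_mean_flux(flux, mld, 100.0, layer="MLD_to_100")
    return out


def analyze_casts(
    casts,
    turbulence=None,
    norm: hyd.NormalizationConfig | None = None,
    constituents: tuple[str, ...] = ("DIC", "N+N", "PO4", "DOP"),
) -> list[CastAnalysis]:
    """Run the per-cast stage; turbulence profiles matched by station+date."""
    norm = norm or hyd.NormalizationConfig()
    turb_map = {}
    for t in turbulence or []:
        turb_map[(t.station, t.date)] = t
    return [
        _analyze_one(c, turb_map.get((c.station, c.date)), norm, constituents)
        for c in casts
    ]


def _uv_dict(v: UncertainValue) -> dict:
    return {"mean": v.m, "ci95": v.e, **({"n": v.n} if v.n is not None else {})}


def _regime_flux_samples(analyses, constituent) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {r: [] for r in bd.REGIMES}
    for a in analyses:
        lf = a.subsurface_flux.get(constituent)
        if lf is not None and not lf.empty and np.isfinite(lf.value.m):
            groups[a.regime].append(lf.value.m)
    return groups


def run_full_budget(
    dataset: SyntheticDataset | None = None,
    *,
    casts=None,
    turbulence=None,
    forcing=None,
    monthly_sst=None,
    stoich: bd.StoichiometryRange | None = None,
    norm: hyd.NormalizationConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Close the annual C-N-P budget and return the full report dict.

    Either pass a :class:`SyntheticDataset` or the four inputs explicitly.
    The report carries the budget closure (NCP-Y = Fup_Y + Fat_Y per
    element), stoichiometric ratios normalised to P, microbial demand and
    recycling-factor intervals, regime statistics and QC counters.
    """
    if dataset is not None:
        casts, turbulence = dataset.casts, dataset.turbulence
        forcing, monthly_sst = dataset.forcing, dataset.monthly_sst
        seed = dataset.config.seed if seed is None else seed
    if not casts:
        raise ValueError("budget stage: no casts supplied")
    if forcing is None:
        raise ValueError("budget stage: atmospheric forcing missing")
    if monthly_sst is None:
        raise ValueError("budget stage: monthly SST series missing")
    stoich = stoich or bd.StoichiometryRange()

    analyses = analyze_casts(casts, turbulence, norm)
    clim = bd.regime_days(monthly_sst)

    elements: dict[str, bd.ElementBudget] = {}
    for element, constituent in ELEMENT_CONSTITUENT.items():
        groups = _regime_flux_samples(analyses, constituent)
        fup = bd.annual_upward_influx(groups, clim)
        fat = bd.annual_atmospheric_influx(element, forcing, clim)
        lateral = forcing.lateral_flux.get(element, 0.0)
        if lateral:
            fat = bd.propagate("sum", fat, UncertainValue(lateral, 0.0))
        elements[element] = bd.ElementBudget(element, fup, fat, bd.ncp_requirement(fup, fat))

    ncp_ratio = bd.stoichiometric_ratio(
        elements["C"].ncp, elements["N"].ncp, elements["P"].ncp
    )
    fup_ratio = bd.stoichiometric_ratio(
        elements["C"].fup, elements["N"].fup, elements["P"].fup
    )
    md_n, md_p = bd.microbial_demand(elements["C"].ncp, stoich)
    rf = {
        "N": bd.recycling_factor(md_n, elements["N"].ncp),
        "P": bd.recycling_factor(md_p, elements["P"].ncp),
    }
    result = bd.BudgetResult(elements, ncp_ratio, fup_ratio, md_n, md_p, rf)

    # regime statistics on the salinity-normalised 0-100 m inventories
    inventory_stats = {}
    drawdown = {}
    ssts = np.array([a.cast.sst for a in analyses])
    for name in ("DIC", "N+N", "PO4"):
        inv = np.array([a.inventories_0_100.get(name, np.nan) for a in analyses])
        ok = np.isfinite(inv)
        if ok.sum() < 4:
            continue
        labels = [a.regime for a, keep in zip(analyses, ok) if keep]
        groups = [
            [v for v, l in zip(inv[ok], labels) if l == r]
            for r in bd.REGIMES
        ]
        present = [(r, g) for r, g in zip(bd.REGIMES, groups) if len(g) > 0]
        if len(present) >= 2:
            comp = kruskal_wallis_with_dunn([g for _, g in present], [r for r, _ in present])
            inventory_stats[name] = {
                "h": comp.h_statistic,
                "p": comp.p_value,
                "significant_pairs": sorted(map(list, comp.significant_pairs())),
            }
        try:
            diff = hyd.regime_inventory_difference(inv[ok], ssts[ok], "SST<24", "SST>28")
            drawdown[name] = _uv_dict(diff)
        except ValueError:
            log.warning("cool/warm inventory difference undefined for %s", name)

    n_sub = sum(
        1
        for a in analyses
        for nm in ("N+N", "PO4")
        if nm in a.cast.concentrations
    )
    report = {
        "n_casts": len(analyses),
        "regime_climatology": {"months": clim.months, "days": clim.days},
        "regime_cast_counts": {
            r: int(sum(a.regime == r for a in analyses)) for r in bd.REGIMES
        },
        "budget": {
            el: {"fup": _uv_dict(b.fup), "fat": _uv_dict(b.fat), "ncp": _uv_dict(b.ncp)}
            for el, b in elements.items()
        },
        "ncp_ratio_c_n_p": [_uv_dict(ncp_ratio[0]), _uv_dict(ncp_ratio[1]), 1.0],
        "fup_ratio_c_n_p": [_uv_dict(fup_ratio[0]), _uv_dict(fup_ratio[1]), 1.0],
        "microbial_demand": {
            "N": {"interval": list(md_n), "reported_2sf": [round_sig(v) for v in md_n]},
            "P": {"interval": list(md_p), "reported_2sf": [round_sig(v) for v in md_p]},
        },
        "recycling_factor": {
            el: {"interval": list(v), "reported_2sf": [round_sig(x) for x in v]}
            for el, v in rf.items()
        },
        "seasonal_drawdown_0_100": drawdown,
        "inventory_regime_tests": inventory_stats,
        "qc": {
            "mean_masked_kz_fraction": float(
                np.mean([a.masked_kz_fraction for a in analyses])
            ),
            "mld_not_reached": int(sum(a.summary.mld_not_reached for a in analyses)),
            "ezd_not_reached": int(sum(a.summary.ezd_not_reached for a in analyses)),
            "nanomolar_profiles_screened": n_sub,
        },
        "manifest": {"seed": seed, "version": _version(), "n_casts": len(analyses)},
    }
    report["_result"] = result  # stripped before serialisation
    report["_flux_rows"] = [
        {
            "station": a.cast.station, "date": a.cast.date, "regime": a.regime,
            "constituent": name, "layer": lf.layer,
            "flux_mol_m2_d": lf.value.m, "ci95": lf.value.e, "n_points": lf.n_points,
        }
        for a in analyses
        for name, lf in list(a.subsurface_flux.items()) + list(a.mixed_layer_flux.items())
        if not lf.empty
    ]
    return report


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("cnpbudget")
    except Exception:  # pragma: no cover
        return "unknown"


def report_to_json(report: dict, path=None) -> str:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    text = json.dumps(clean, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def run_from_config(config_path) -> dict:
    """Run the full pipeline from a YAML run configuration.

    The config either names a synthetic ``scenario`` (``seed`` mandatory,
    other ScenarioConfig fields optional) or an ``inputs`` mapping with
    ``casts``/``turbulence``/``forcing``/``monthly_sst`` paths.  Errors
    name the failing stage.
    """
    doc = yaml.safe_load(Path(config_path).read_text())
    base = Path(config_path).parent
    if "scenario" in doc:
        params = dict(doc["scenario"])
        if "seed" not in params:
            raise ValueError("scenario stage: 'seed' is mandatory for simulate")
        dataset = generate_cruise_dataset(ScenarioConfig(**params))
        return run_full_budget(dataset)
    if "inputs" not in doc:
        raise ValueError("config stage: need either 'scenario' or 'inputs'")
    paths = {k: base / v for k, v in doc["inputs"].items()}
    try:
        casts = pio.read_casts(paths["casts"])
    except Exception as exc:
        raise RuntimeError(f"cast-loading stage failed: {exc}") from exc
    try:
        turbulence = pio.read_turbulence(paths["turbulence"])
    except Exception as exc:
        raise RuntimeError(f"turbulence-loading stage failed: {exc}") from exc
    try:
        forcing = pio.read_forcing(paths["forcing"])
        monthly = pio.read_monthly_sst(paths["monthly_sst"])
    except Exception as exc:
        raise RuntimeError(f"forcing-loading stage failed: {exc}") from exc
    return run_full_budget(
        casts=casts, turbulence=turbulence, forcing=forcing, monthly_sst=monthly,
        seed=doc.get("seed"),
    )


def _analytic_fixture(seed: int) -> tuple[list, list, dict]:
    """One cast with an exactly linear tracer and constant epsilon/N^2.

    Closed form: layer mean flux = 0.2 (eps/N^2) * g * 86400 for every
    layer, here with eps = 2e-9 W kg-1, N^2 = 1e-4 s-2, g = 1e-3 mol m-4.
    """
    eps, n_sq, slope = 2e-9, 1e-4, 1e-3
    depths = np.array([0.0, 10, 25, 50, 75, 100, 125, 150, 200])
    cast = hyd.Cast(
        station="A1", date="2016-06-15", sst=24.95,
        depth=depths,
        temperature=25.0 - 0.05 * depths,
        salinity=np.full(depths.size, 34.91),
        par=2000.0 * np.exp(-0.046 * depths),
        concentrations={"DIC": 2.0 + slope * depths},
    )
    grid = np.arange(5.0, 200.0 + 2.5, 5.0)
    turb = tb.TurbulenceProfile(
        "A1", "2016-06-15", grid, np.full(grid.size, eps), np.full(grid.size, n_sq)
    )
    expected = 0.2 * (eps / n_sq) * slope * tb.SECONDS_PER_DAY
    return [cast], [turb], {"expected_layer_mean_flux_mol_m2_d": expected}


SCENARIOS = ("paper-defaults", "linear-gradient-analytic")


def make_fixtures(scenario: str, seed: int, outdir) -> dict[str, Path]:
    """Write the input CSVs (and an expected-output snapshot) for a scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scenario == "paper-defaults":
        dataset = generate_cruise_dataset(ScenarioConfig(seed=seed))
        paths = pio.write_dataset(dataset, outdir)
        report = run_full_budget(dataset)
        snap = outdir / "expected_report.json"
        report_to_json(report, snap)
        paths["expected"] = snap
        return paths
    if scenario == "linear-gradient-analytic":
        casts, turbs, expected = _analytic_fixture(seed)
        pio.write_casts(casts, outdir / "casts.csv")
        pio.write_turbulence(turbs, outdir / "turbulence.csv")
        snap = outdir / "expected_flux.json"
        snap.write_text(json.dumps(expected, indent=2) + "\n")
        return {"casts": outdir / "casts.csv", "turbulence": outdir / "turbulence.csv",
                "expected": snap}
    raise ValueError(f"unknown scenario {scenario!r}; available: {', '.join(SCENARIOS)}")


def config_hash(config: ScenarioConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]
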