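"""CSV / YAML interchange for casts, turbulence, forcing and SST series.

Cast files carry nutrients in nM and DIC in mol m-3 (the field's usual
reporting units); concentrations are converted to mol m-3 on load
(1 nM = 1e-6 mol m-3) and back on write, logged once.  Cast SST is the
temperature interpolated at 10 m.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .budget import AtmosphericForcing
from .hydrography import NM_TO_MOL_M3, Cast
from .turbulence import TurbulenceProfile
from .uncertainty import UncertainValue

__all__ = [
    "casts_to_dataframe", "casts_from_dataframe", "write_casts", "read_casts",
    "write_turbulence", "read_turbulence",
    "write_forcing", "read_forcing",
    "write_monthly_sst", "read_monthly_sst",
    "write_dataset",
]

log = logging.getLogger(__name__)

#: CSV column <-> internal constituent name (and unit scale to mol m-3)
_CONSTITUENT_COLUMNS = {
    "dic_mol_m3": ("DIC", 1.0),
    "nn_nM": ("N+N", NM_TO_MOL_M3),
    "po4_nM": ("PO4", NM_TO_MOL_M3),
    "dop_nM": ("DOP", NM_TO_MOL_M3),
    "tdp_nM": ("TDP", NM_TO_MOL_M3),
    "tpp_nM": ("TPP", NM_TO_MOL_M3),
}


def casts_to_dataframe(casts: list[Cast]) -> pd.DataFrame:
    rows = []
    for cast in casts:
        for i, z in enumerate(cast.depth):
            row = {
                "station": cast.station,
                "date": cast.date,
                "depth_m": z,
                "temp_C": cast.temperature[i],
                "sal": cast.salinity[i],
                "par": cast.par[i] if cast.par is not None else np.nan,
            }
            for col, (name, scale) in _CONSTITUENT_COLUMNS.items():
                arr = cast.concentrations.get(name)
                row[col] = arr[i] / scale if arr is not None else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def casts_from_dataframe(df: pd.DataFrame) -> list[Cast]:
    log.info("loading casts: converting nM columns to mol m-3 (x 1e-6)")
    casts = []
    for (station, date), grp in df.groupby(["station", "date"], sort=True):
        grp = grp.sort_values("depth_m")
        depth = grp["depth_m"].to_numpy(dtype=float)
        temp = grp["temp_C"].to_numpy(dtype=float)
        conc = {}
        for col, (name, scale) in _CONSTITUENT_COLUMNS.items():
            if col in grp and not grp[col].isna().all():
                conc[name] = grp[col].to_numpy(dtype=float) * scale
        par = grp["par"].to_numpy(dtype=float) if "par" in grp else None
        if par is not None and np.all(np.isnan(par)):
            par = None
        casts.append(
            Cast(
                station=str(station), date=str(date),
                sst=float(np.interp(10.0, depth, temp)),
                depth=depth, temperature=temp,
                salinity=grp["sal"].to_numpy(dtype=float),
                par=par, concentrations=conc,
            )
        )
    return casts


def write_casts(casts: list[Cast], path) -> None:
    casts_to_dataframe(casts).to_csv(path, index=False, float_format="%.10g")


def read_casts(path) -> list[Cast]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"cast file {path} contains no rows")
    return casts_from_dataframe(df)


def write_turbulence(profiles: list[TurbulenceProfile], path) -> None:
    rows = []
    for p in profiles:
        for i, z in enumerate(p.depth):
            rows.append(
                {"station": p.station, "date": p.date, "depth_m": z,
                 "epsilon_W_kg": p.epsilon[i], "n_sq_s2": p.n_sq[i]}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_turbulence(path) -> list[TurbulenceProfile]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"turbulence file {path} contains no rows")
    out = []
    for (station, date), grp in df.groupby(["station", "date"], sort=True):
        grp = grp.sort_values("depth_m")
        out.append(
            TurbulenceProfile(
                str(station), str(date),
                grp["depth_m"].to_numpy(dtype=float),
                grp["epsilon_W_kg"].to_numpy(dtype=float),
                grp["n_sq_s2"].to_numpy(dtype=float),
            )
        )
    return out


def _uv_to_dict(v: UncertainValue) -> dict:
    return {"mean": float(v.m), "ci95": float(v.e)}


def _uv_from_dict(d) -> UncertainValue:
    return UncertainValue(float(d["mean"]), float(d["ci95"]))


def write_forcing(forcing: AtmosphericForcing, path) -> None:
    doc = {
        "co2_flux_monthly": {r: _uv_to_dict(v) for r, v in forcing.co2_flux_monthly.items()},
        "n2_fixation": _uv_to_dict(forcing.n2_fixation_rate),
        "n_deposition": _uv_to_dict(forcing.n_deposition_rate),
        "p_deposition": _uv_to_dict(forcing.p_deposition_rate),
        "lateral_flux": dict(forcing.lateral_flux),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_forcing(path) -> AtmosphericForcing:
    doc = yaml.safe_load(Path(path).read_text())
    return AtmosphericForcing(
        co2_flux_monthly={r: _uv_from_dict(v) for r, v in doc["co2_flux_monthly"].items()},
        n2_fixation_rate=_uv_from_dict(doc["n2_fixation"]),
        n_deposition_rate=_uv_from_dict(doc["n_deposition"]),
        p_deposition_rate=_uv_from_dict(doc["p_deposition"]),
        lateral_flux=doc.get("lateral_flux", {"C": 0.0, "N": 0.0, "P": 0.0}),
    )


def write_monthly_sst(sst, path) -> None:
    pd.DataFrame({"month": np.arange(1, 13), "sst_C": np.asarray(sst, dtype=float)}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_monthly_sst(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("month")
    return df["sst_C"].to_numpy(dtype=float)


def write_dataset(dataset, outdir) -> dict[str, Path]:
    """Write a synthetic dataset as the four pipeline input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "casts": outdir / "casts.csv",
        "turbulence": outdir / "turbulence.csv",
        "forcing": outdir / "forcing.yaml",
        "monthly_sst": outdir / "monthly_sst.csv",
    }
    write_casts(dataset.casts, paths["casts"])
    write_turbulence(dataset.turbulence, paths["turbulence"])
    write_forcing(dataset.forcing, paths["forcing"])
    write_monthly_sst(dataset.monthly_sst, paths["monthly_sst"])
    return paths
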