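"""Delimited-table I/O, configuration, and pipeline orchestration.

All on-disk formats are plain CSV with documented headers:

* underway: time, lat, lon, sst, sss, pco2 (decimal day of year, degN,
  degE west-negative, degC, practical salinity, uatm).  Common synonym
  headers from community underway-pCO2 archives are accepted as aliases.
* bottles: region, period, station, layer, depth, t, s, ta, dic, no3, po4.
* forcing: day, u10_sq, ice_pct, psl, xco2 (+ sst, sss, ta_interp,
  ncp_n_daily for box-model forcing).

Rows that cannot be used (missing position/time or the core measured
variable) are skipped and counted through the module logger rather than
raising, matching how underway archives are usually ingested.

:func:`run_pipeline` wires the full analysis: simulate -> grid ->
decompose -> flux -> regional flux summary -> normalize -> NCP summary ->
box-model scenario comparison, and optionally writes every product to a
directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boxmodel as bx
from . import constants as cst
from . import synthetic as syn
from .decompose import DecompositionReference, decompose_cells
from .flux import flux_for_cells, regional_flux_table
from .gridding import grid_daily
from .ncp import regional_ncp_table
from .normalize import EndmemberSet, normalize_bottles
from .watermass import assign_region_group, classify

log = logging.getLogger("chukchi_carbon")

__all__ = ["PipelineConfig", "read_underway", "read_bottles", "read_forcing",
           "run_pipeline"]

_UNDERWAY_ALIASES = {
    "time": ("time", "doy", "day_of_year", "yday", "decimal_doy"),
    "lat": ("lat", "latitude", "latitude_dec_deg_n"),
    "lon": ("lon", "longitude", "longitude_dec_deg_e"),
    "sst": ("sst", "temp", "sst_deg_c", "temperature"),
    "sss": ("sss", "sal", "salinity"),
    "pco2": ("pco2", "pco2_sea", "pco2w", "pco2water_sst_wet_uatm",
             "pco2water_sst_wet"),
}


def _canon(name: str) -> str:
    return (name.strip().lower().replace("[", "").replace("]", "")
            .replace(".", "_").replace(" ", "_").replace("°", "deg"))


def _rename_with_aliases(df: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    mapping = {}
    canon_cols = {_canon(c): c for c in df.columns}
    for target, names in aliases.items():
        for alias in names:
            if alias in canon_cols:
                mapping[canon_cols[alias]] = target
                break
    return df.rename(columns=mapping)


def read_underway(path) -> pd.DataFrame:
    """Read an underway surface table; skips (and logs) unusable rows."""
    df = _rename_with_aliases(pd.read_csv(path), _UNDERWAY_ALIASES)
    for col in ("time", "lat", "lon", "pco2"):
        if col not in df.columns:
            raise ValueError(f"underway file {path} lacks mandatory column {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["time", "lat", "lon", "pco2"]).reset_index(drop=True)
    if len(df) < n0:
        log.warning("%s: skipped %d malformed row(s)", path, n0 - len(df))
    return df


def read_bottles(path) -> pd.DataFrame:
    """Read a discrete bottle table."""
    df = pd.read_csv(path)
    df.columns = [_canon(c) for c in df.columns]
    for col in ("t", "s", "ta", "dic", "no3", "po4"):
        if col not in df.columns:
            raise ValueError(f"bottle file {path} lacks mandatory column {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["t", "s"]).reset_index(drop=True)
    if len(df) < n0:
        log.warning("%s: skipped %d malformed row(s)", path, n0 - len(df))
    return df


def read_forcing(path) -> pd.DataFrame:
    """Read a daily forcing table."""
    df = pd.read_csv(path)
    df.columns = [_canon(c) for c in df.columns]
    for col in ("day", "u10_sq", "ice_pct", "psl", "xco2"):
        if col not in df.columns:
            raise ValueError(f"forcing file {path} lacks mandatory column {col!r}")
    return df


@dataclass
class PipelineConfig:
    """End-to-end run configuration; YAML round-trippable."""

    seed: int = 0
    outdir: str | None = None
    n_underway: int = 400
    n_stations: int = 15
    noise: float = 1.0
    mld: float = cst.MLD_DEFAULT
    s0: float = cst.S_REFERENCE
    dic_s0: float = cst.DIC_S0_INTERCEPT
    ta_s0: float = cst.TA_S0_INTERCEPT
    pco2_ini: float = cst.PCO2_INITIAL
    t_spring: float = cst.T_SPRING
    thermal_coeff: float = cst.THERMAL_COEFF
    caco3_correction: bool = True
    ncp_profile: str = "uniform"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def scenario_spec(self) -> syn.ScenarioSpec:
        return syn.ScenarioSpec(
            seed=self.seed, n_underway=self.n_underway,
            n_stations=self.n_stations, noise=self.noise, mld=self.mld,
            pco2_ini=self.pco2_ini,
            endmembers=EndmemberSet(s0=self.s0, dic_s0=self.dic_s0,
                                    ta_s0=self.ta_s0))


def _label_cells(cells: pd.DataFrame) -> pd.DataFrame:
    out = cells.copy()
    labels, regions, groups, periods = [], [], [], []
    day_to_period = {}
    for period, (lo, hi) in syn.PERIOD_DAYS.items():
        for d in range(lo, hi + 1):
            day_to_period[d] = period
    for rec in out.itertuples(index=False):
        wm = classify(rec.mean_sst, rec.mean_sss)
        rl = assign_region_group(rec.lat, wm)
        labels.append(wm.value)
        regions.append(rl.region)
        groups.append(rl.group)
        periods.append(day_to_period.get(int(rec.day), "other"))
    out["water_mass"] = labels
    out["region"] = regions
    out["group"] = groups
    out["period"] = periods
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-data analysis; returns a report bundle.

    The bundle maps stage names to DataFrames/dicts: underway, cells
    (gridded + decomposed + flux), flux_table, bottles (normalized),
    ncp_table, box trajectories and the scenario comparison per region.
    When ``config.outdir`` is set everything is also written as CSV/JSON.
    """
    spec = config.scenario_spec()
    rng = spec.rng()
    report: dict[str, object] = {"config": asdict(config)}

    log.info("stage: simulate")
    underway = syn.make_underway(spec, rng)
    bottles = syn.make_bottles(spec, rng)
    forcing = {region: syn.make_forcing(spec, region, rng,
                                        ncp_profile=config.ncp_profile)
               for region in ("southern", "northern")}

    log.info("stage: grid")
    cells = grid_daily(underway.rename(columns={"pco2": "pco2"}))

    log.info("stage: decompose")
    ref = DecompositionReference(pco2_ini=config.pco2_ini,
                                 t_spring=config.t_spring,
                                 thermal_coeff=config.thermal_coeff)
    cells = decompose_cells(cells, ref)

    log.info("stage: flux")
    cells = _label_cells(cells)
    parts = []
    for region, fc in forcing.items():
        sub = cells[cells["region"] == region]
        if len(sub):
            parts.append(flux_for_cells(sub, fc[["day", "u10_sq", "ice_pct",
                                                 "psl", "xco2"]]))
    cells = pd.concat(parts, ignore_index=True)
    flux_table = regional_flux_table(cells)

    log.info("stage: normalize + ncp")
    nb = normalize_bottles(bottles, spec.endmembers)
    ncp_table = regional_ncp_table(
        nb, syn.GROWING_SEASON, mean_flux=spec.mean_co2_flux, mld=config.mld)

    log.info("stage: boxmodel")
    box = {}
    for region in ("southern", "northern"):
        cn_flex = float(ncp_table.loc[ncp_table["region"] == region,
                                      "cn_uptake"].iloc[0])
        runs = {}
        for name, cn in (("redfield", cst.REDFIELD_CN), ("nonredfield", cn_flex)):
            scen = bx.ScenarioConfig(cn_ratio=cn, region=region, mld=config.mld)
            runs[name] = bx.run(scen, forcing[region])
        box[region] = {
            "runs": runs,
            "comparison": bx.scenario_compare(runs["nonredfield"], runs["redfield"]),
        }

    report.update(underway=underway, cells=cells, flux_table=flux_table,
                  bottles=nb, ncp_table=ncp_table, box=box, forcing=forcing)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        underway.to_csv(out / "underway.csv", index=False)
        cells.to_csv(out / "cells.csv", index=False)
        flux_table.to_csv(out / "flux_table.csv", index=False)
        nb.to_csv(out / "bottles.csv", index=False)
        ncp_table.to_csv(out / "ncp_table.csv", index=False)
        summary = {}
        for region, b in box.items():
            b["runs"]["redfield"].to_csv(out / f"box_{region}_redfield.csv", index=False)
            b["runs"]["nonredfield"].to_csv(out / f"box_{region}_nonredfield.csv", index=False)
            summary[region] = b["comparison"]
        with open(out / "scenario_comparison.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        config.to_yaml(out / "config.yaml")
    return report
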