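"""Air-sea CO2 flux with wind-speed second moment and sea-ice attenuation.

Per daily grid cell,

    F = 0.24 * Ks * k * (pCO2_sea - pCO2_air)    [mmol m-2 d-1]

where Ks is the Weiss (1974) CO2 solubility (mol L-1 atm-1), k the gas
transfer velocity (cm hr-1) from the quadratic wind parameterization

    k = 0.251 * <U10^2> * (Sc/660)^-0.5 * (1 - ice_eff/100)

with the Schmidt number from the Wanninkhof (2014) seawater polynomial, and
ice_eff = min(ice%, 90): where satellite products report more than 90% ice
cover, a 10% open-water fraction (unresolved leads) is retained.  Negative
flux means ocean uptake.  The 0.24 factor converts
(cm hr-1)(mol L-1 atm-1)(uatm) to mmol m-2 d-1.

The regional summary groups fluxes by (region, period, water-mass group)
and tests ACW against non-ACW with a Welch (unequal-variance) t-test,
flagging significance at the 0.05 / 0.01 / 0.001 tiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as cst
from .carbonate import co2_solubility, vapor_pressure

__all__ = ["ForcingDay", "FluxResult", "schmidt_number",
           "gas_transfer_velocity", "pco2_air", "co2_flux",
           "flux_for_cells", "regional_flux_table"]


@dataclass(frozen=True)
class ForcingDay:
    """One day of air-side and ice forcing."""

    day: int
    u10_sq: float   # m2 s-2, second moment of 6-hourly wind speed
    ice_pct: float  # %
    psl: float      # atm
    xco2: float     # ppm

    def __post_init__(self) -> None:
        if self.u10_sq < 0:
            raise ValueError("u10_sq must be non-negative")
        if not (0.0 <= self.ice_pct <= 100.0):
            raise ValueError("ice_pct must be within [0, 100]")


@dataclass(frozen=True)
class FluxResult:
    k: float         # cm hr-1
    ks: float        # mol L-1 atm-1
    pco2_air: float  # uatm
    dpco2: float     # uatm
    flux: float      # mmol m-2 d-1, negative = into the sea


def schmidt_number(temperature: float) -> float:
    """CO2 Schmidt number in seawater (Wanninkhof 2014 polynomial)."""
    a, b, c, d, e = cst.WANNINKHOF_2014_SC
    t = temperature
    return a + b * t + c * t * t + d * t ** 3 + e * t ** 4


def gas_transfer_velocity(u10_sq: float, temperature: float,
                          salinity: float = 35.0, ice_pct: float = 0.0) -> float:
    """Gas transfer velocity k (cm hr-1), ice-attenuated.

    ``salinity`` is accepted for interface symmetry; the Schmidt-number
    polynomial is for seawater and carries no explicit salinity dependence.
    """
    del salinity
    if u10_sq < 0:
        raise ValueError("u10_sq must be non-negative")
    if not (0.0 <= ice_pct <= 100.0):
        raise ValueError("ice_pct must be within [0, 100]")
    ice_eff = min(ice_pct, cst.ICE_CAP_PCT)
    sc = schmidt_number(temperature)
    return (cst.GAS_TRANSFER_COEFF * u10_sq
            * (sc / cst.SCHMIDT_REFERENCE) ** -0.5
            * (1.0 - ice_eff / 100.0))


def pco2_air(forcing: ForcingDay, temperature: float, salinity: float) -> float:
    """Moist-air pCO2 (uatm) from dry-air xCO2, sea-level pressure and the
    water vapor pressure at the sea surface."""
    pw = vapor_pressure(temperature, forcing.psl, salinity)
    return forcing.xco2 * (forcing.psl - pw)


def co2_flux(mean_pco2: float, mean_sst: float, mean_sss: float,
             forcing: ForcingDay) -> FluxResult:
    """Air-sea CO2 flux for one gridded cell under one day of forcing."""
    for name, v in (("mean_pco2", mean_pco2), ("mean_sst", mean_sst),
                    ("mean_sss", mean_sss)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite (got {v})")
    ks = co2_solubility(mean_sst, mean_sss)
    k = gas_transfer_velocity(forcing.u10_sq, mean_sst, mean_sss, forcing.ice_pct)
    p_air = pco2_air(forcing, mean_sst, mean_sss)
    dpco2 = mean_pco2 - p_air
    flux = cst.FLUX_UNIT_FACTOR * ks * k * dpco2
    return FluxResult(k=k, ks=ks, pco2_air=p_air, dpco2=dpco2, flux=flux)


def flux_for_cells(cells: pd.DataFrame, forcing: pd.DataFrame) -> pd.DataFrame:
    """Join gridded cells with daily forcing and append flux columns.

    ``forcing`` needs columns day, u10_sq, ice_pct, psl, xco2.  Cells whose
    day has no forcing row raise.
    """
    merged = cells.merge(forcing, on="day", how="left", validate="m:1")
    if merged["u10_sq"].isna().any():
        missing = sorted(merged.loc[merged["u10_sq"].isna(), "day"].unique())
        raise ValueError(f"no forcing for days {missing}")
    rows = []
    for rec in merged.itertuples(index=False):
        fd = ForcingDay(day=int(rec.day), u10_sq=rec.u10_sq, ice_pct=rec.ice_pct,
                        psl=rec.psl, xco2=rec.xco2)
        res = co2_flux(rec.mean_pco2, rec.mean_sst, rec.mean_sss, fd)
        rows.append((res.k, res.ks, res.pco2_air, res.dpco2, res.flux))
    merged[["k", "ks", "pco2_air", "dpco2", "flux"]] = pd.DataFrame(
        rows, index=merged.index)
    return merged


_SIG_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def regional_flux_table(fluxes: pd.DataFrame) -> pd.DataFrame:
    """Per (region, period) flux means by water-mass group with Welch t-test.

    ``fluxes`` needs columns region, period, group, flux.  Rows with group
    'excluded' are ignored.  Output: one row per (region, period) with the
    regional mean over all non-excluded groups, ACW and non-ACW means/SDs/n,
    the Welch p-value between them and a significance flag; the test is
    skipped (flag 'skipped') when either group has n < 2.
    """
    df = fluxes[fluxes["group"] != "excluded"]
    out = []
    for (region, period), sub in df.groupby(["region", "period"], sort=False):
        row: dict[str, object] = {"region": region, "period": period,
                                  "mean": sub["flux"].mean(),
                                  "sd": sub["flux"].std(ddof=1),
                                  "n": len(sub)}
        acw = sub.loc[sub["group"] == "ACW", "flux"]
        non = sub.loc[sub["group"] == "nonACW", "flux"]
        for name, g in (("acw", acw), ("nonacw", non)):
            row[f"{name}_mean"] = g.mean() if len(g) else np.nan
            row[f"{name}_sd"] = g.std(ddof=1) if len(g) > 1 else np.nan
            row[f"{name}_n"] = len(g)
        if len(acw) >= 2 and len(non) >= 2:
            t, p = stats.ttest_ind(acw, non, equal_var=False)
            row["p_value"] = p
            row["significance"] = next(
                (mark for thr, mark in _SIG_TIERS if p < thr), "ns")
        else:
            row["p_value"] = np.nan
            row["significance"] = "skipped"
        out.append(row)
    return pd.DataFrame(out)
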