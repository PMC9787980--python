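"""Cruise-like synthetic data: underway tracks, bottle stations, forcing.

The generator emulates the statistical structure of a two-region (southern /
northern of 69.5 degN) Arctic shelf survey across a melt season: per-period,
per-layer means and standard deviations of temperature, salinity, TA, DIC,
nitrate and phosphate (:data:`SEASONAL_STATS`); meltwater freshening along a
two-endmember mixing line; an under-ice spring reference state whose TA/DIC
pair is chemically consistent with a ~538 uatm pCO2; and seasonal forcing
(sigmoidal ice retreat, surface warming, quadratic-mean winds near
49 m2 s-2, ~400 ppm atmospheric CO2).

The bottle generator is the inverse of the analysis pipeline: early-summer
surface concentrations are constructed from the spring state so that, after
salinity normalization, the DIC deficit encodes a prescribed C:N uptake
ratio exactly (before noise):

    Delta(nDIC)_bio = true_cn * Delta(nNO3)    (unit-reconciled via rho)

plus a configurable air-sea CO2 addition, an excess-TA (CaCO3 dissolution)
term, and meltwater dilution applied by de-normalizing to the target summer
salinity.  Running normalize -> ncp on noise-free output therefore returns
true_cn to machine precision; with the tabulated noise levels the recovery
is statistical and is exercised by the parameter-recovery tests.

Everything random flows from one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import constants as cst
from .carbonate import CarbParams, density, pco2_from_ta_dic
from .normalize import EndmemberSet, normalize_tracer

__all__ = ["ScenarioSpec", "SEASONAL_STATS", "PERIOD_DAYS", "make_underway",
           "make_bottles", "make_forcing", "denormalize_tracer"]

#: Seasonal mean +- SD of surface ("surf") and bottom ("bot") properties by
#: period and region.  Variables: t (degC), s, ta, dic (umol kg-1),
#: no3, po4 (uM).
SEASONAL_STATS: dict[str, dict[str, dict[str, dict[str, tuple[float, float]]]]] = {
    "early_spring": {
        "southern": {
            "surf": {"t": (-1.28, 0.19), "s": (31.9, 0.4), "ta": (2205, 7),
                     "dic": (2068, 35), "no3": (9.57, 5.29), "po4": (1.33, 0.30)},
            "bot": {"t": (-1.03, 0.15), "s": (32.2, 0.3), "ta": (2212, 28),
                    "dic": (2112, 70), "no3": (10.3, 3.30), "po4": (1.41, 0.27)},
        },
        "northern": {
            "surf": {"t": (-1.71, 0.04), "s": (32.1, 0.6), "ta": (2225, 28),
                     "dic": (2173, 41), "no3": (10.54, 3.95), "po4": (1.66, 0.32)},
            "bot": {"t": (-1.74, 0.04), "s": (32.4, 0.4), "ta": (2236, 18),
                    "dic": (2191, 27), "no3": (12.18, 3.11), "po4": (1.82, 0.27)},
        },
    },
    "late_spring": {
        "northern": {
            "surf": {"t": (-1.61, 0.36), "s": (32.2, 0.5), "ta": (2229, 23),
                     "dic": (2153, 47), "no3": (10.57, 4.33), "po4": (1.59, 0.35)},
            "bot": {"t": (-1.73, 0.04), "s": (32.6, 0.2), "ta": (2243, 13),
                    "dic": (2188, 23), "no3": (13.23, 2.81), "po4": (1.89, 0.26)},
        },
    },
    "early_summer": {
        "southern": {
            "surf": {"t": (5.95, 1.80), "s": (31.4, 1.0), "ta": (2187, 40),
                     "dic": (1940, 49), "no3": (0.27, 0.20), "po4": (0.46, 0.11)},
            "bot": {"t": (3.93, 1.61), "s": (31.9, 0.6), "ta": (2204, 31),
                    "dic": (2215, 64), "no3": (3.67, 4.50), "po4": (0.84, 0.34)},
        },
        "northern": {
            "surf": {"t": (3.76, 2.79), "s": (30.7, 0.9), "ta": (2154, 37),
                     "dic": (1954, 51), "no3": (0.62, 1.51), "po4": (0.62, 0.20)},
            "bot": {"t": (-0.42, 0.99), "s": (32.1, 0.4), "ta": (2225, 25),
                    "dic": (2067, 78), "no3": (4.96, 8.29), "po4": (1.07, 0.55)},
        },
    },
    "late_summer": {
        "southern": {
            "surf": {"t": (4.46, 1.55), "s": (32.1, 0.3), "ta": (2199, 20),
                     "dic": (2012, 61), "no3": (3.95, 3.46), "po4": (0.75, 0.35)},
            "bot": {"t": (2.27, 0.27), "s": (32.5, 0.2), "ta": (2211, 12),
                    "dic": (2161, 24), "no3": (18.01, 2.53), "po4": (2.08, 0.25)},
        },
    },
    "fall": {
        "southern": {
            "surf": {"t": (5.33, 0.99), "s": (31.6, 0.2), "ta": (2180, 14),
                     "dic": (2008, 27), "no3": (2.24, 1.07), "po4": (0.62, 0.12)},
            "bot": {"t": (3.15, 0.37), "s": (32.4, 0.4), "ta": (2207, 21),
                    "dic": (2111, 45), "no3": (11.53, 4.48), "po4": (1.56, 0.35)},
        },
        "northern": {
            "surf": {"t": (3.10, 0.58), "s": (31.1, 0.2), "ta": (2249, 12),
                     "dic": (1971, 13), "no3": (0.06, 0.03), "po4": (0.45, 0.03)},
            "bot": {"t": (0.66, 1.56), "s": (32.2, 0.3), "ta": (2208, 15),
                    "dic": (2105, 59), "no3": (4.60, 2.51), "po4": (1.34, 0.41)},
        },
    },
}

#: Day-of-year windows of the survey periods.
PERIOD_DAYS = {"early_spring": (135, 151), "late_spring": (152, 172),
               "early_summer": (190, 219), "late_summer": (224, 252),
               "fall": (268, 271)}

#: Pre-bloom spring reference period per region (melt reaches the north later).
SPRING_PERIOD = {"southern": "early_spring", "northern": "late_spring"}

#: Growing-season length (d) between the spring and early-summer surveys.
GROWING_SEASON = {"southern": 73.0, "northern": 49.0}


@dataclass
class ScenarioSpec:
    """All generator parameters for one synthetic campaign.

    Defaults are the study conditions: seasonal statistics from
    :data:`SEASONAL_STATS`, under-ice reference pCO2 538 uatm, meltwater
    endmember (S=5, DIC=400, TA=460), prescribed regional C:N (C:P) uptake
    ratios of 10.9 (94) south and 12.1 (128) north, growth-window mean
    air-sea fluxes from the surveyed regional means (-9.2 south,
    -3.05 north, mmol m-2 d-1), and excess TA release chosen so the
    normalized-TA change matches the surveyed -34 / -36 umol kg-1.
    """

    seed: int = 0
    n_underway: int = 400          # records per (period, region)
    n_stations: int = 15           # bottle stations per region and period
    periods: tuple[str, ...] = ("early_spring", "early_summer")
    true_cn: dict = field(default_factory=lambda: {"southern": 10.9, "northern": 12.1})
    true_cp: dict = field(default_factory=lambda: {"southern": 94.0, "northern": 128.0})
    mean_co2_flux: dict = field(default_factory=lambda: {"southern": -9.2, "northern": -3.05})
    ta_excess: dict = field(default_factory=lambda: {"southern": 24.0, "northern": 26.0})
    pco2_ini: float = cst.PCO2_INITIAL
    mld: float = cst.MLD_DEFAULT
    noise: float = 1.0             # global multiplier on the tabulated SDs
    drawdown_scale: float = 1.0    # 0 = dilution-only (no biological uptake)
    endmembers: EndmemberSet = field(default_factory=EndmemberSet)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["endmembers"] = {"s0": self.endmembers.s0, "dic_s0": self.endmembers.dic_s0,
                           "ta_s0": self.endmembers.ta_s0}
        return d


def denormalize_tracer(n_conc, salinity, em: EndmemberSet, tracer: str):
    """Inverse of salinity normalization: concentration at ``salinity`` whose
    normalized value is ``n_conc`` (i.e. a point on the mixing line)."""
    c0 = em.intercept(tracer)
    return (np.asarray(n_conc, dtype=float) - c0) * np.asarray(salinity) / em.s0 + c0


_REGION_BAND = {"southern": (66.5, 69.4), "northern": (69.6, 73.5)}


def make_underway(spec: ScenarioSpec,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic underway surface records.

    For each requested period and each region surveyed in it, draws T and S
    around the period statistics, places TA and DIC on the meltwater mixing
    line through the period means (so freshening dilutes them consistently)
    with tabulated noise, and computes pCO2 from (TA, DIC, T, S) through the
    carbonate solver, making every record chemically self-consistent.
    """
    if rng is None:
        rng = spec.rng()
    em = spec.endmembers
    rows = []
    for period in spec.periods:
        day_lo, day_hi = PERIOD_DAYS[period]
        for region, layers in SEASONAL_STATS[period].items():
            st = layers["surf"]
            lat_lo, lat_hi = _REGION_BAND[region]
            n = spec.n_underway
            t = rng.normal(st["t"][0], st["t"][1] * spec.noise, n)
            t = np.maximum(t, -1.8)          # freezing line
            s = rng.normal(st["s"][0], st["s"][1] * spec.noise, n)
            s = np.clip(s, 6.0, 36.0)
            n_ta = normalize_tracer(st["ta"][0], st["s"][0], em, "TA")
            n_dic = normalize_tracer(st["dic"][0], st["s"][0], em, "DIC")
            ta = denormalize_tracer(n_ta, s, em, "TA") + rng.normal(0, st["ta"][1] * spec.noise * 0.3, n)
            dic = denormalize_tracer(n_dic, s, em, "DIC") + rng.normal(0, st["dic"][1] * spec.noise * 0.3, n)
            pco2 = np.array([
                pco2_from_ta_dic(ta_i, dic_i, CarbParams(t_i, s_i))
                for ta_i, dic_i, t_i, s_i in zip(ta, dic, t, s)])
            rows.append(pd.DataFrame({
                "time": rng.uniform(day_lo, day_hi + 1, n),
                "lat": rng.uniform(lat_lo, lat_hi, n),
                "lon": rng.uniform(-172.0, -162.0, n),
                "sst": t, "sss": s, "pco2": pco2,
                "period": period, "region": region,
            }))
    out = pd.concat(rows, ignore_index=True).sort_values("time", ignore_index=True)
    out.attrs["spec"] = spec.to_dict()
    return out


def _summer_surface_targets(spec: ScenarioSpec, region: str) -> dict[str, float]:
    """Noise-free normalized early-summer surface state encoding true_cn."""
    em = spec.endmembers
    spring = SEASONAL_STATS[SPRING_PERIOD[region]][region]["surf"]
    summer = SEASONAL_STATS["early_summer"][region]["surf"]
    rho_m = 0.5 * (density(spring["t"][0], spring["s"][0])
                   + density(summer["t"][0], summer["s"][0]))
    kg_per_l = rho_m / 1000.0

    n1 = {
        "ta": normalize_tracer(spring["ta"][0], spring["s"][0], em, "TA"),
        "dic": normalize_tracer(spring["dic"][0], spring["s"][0], em, "DIC"),
        "no3": normalize_tracer(spring["no3"][0], spring["s"][0], em, "NO3"),
        "po4": normalize_tracer(spring["po4"][0], spring["s"][0], em, "PO4"),
    }
    no3_target = normalize_tracer(summer["no3"][0], summer["s"][0], em, "NO3")
    d_no3 = (n1["no3"] - no3_target) * spec.drawdown_scale  # uM drawdown
    no3_target = n1["no3"] - d_no3
    cn = spec.true_cn[region]
    cp = spec.true_cp[region]
    dt = GROWING_SEASON[region]
    flux = spec.mean_co2_flux[region]
    flux_add = -flux * dt / (spec.mld * kg_per_l)      # umol kg-1 added by influx
    ta_excess = spec.ta_excess[region]                 # umol kg-1 CaCO3-dissolution TA

    n2 = {
        "no3": no3_target,
        "po4": n1["po4"] - cn * d_no3 / cp,
        "ta": n1["ta"] + d_no3 / kg_per_l + ta_excess,
        "dic": n1["dic"] - cn * d_no3 / kg_per_l + flux_add + 0.5 * ta_excess,
    }
    return {"n1": n1, "n2": n2, "rho_m": rho_m, "d_no3": d_no3}


def make_bottles(spec: ScenarioSpec,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic bottle stations for the spring and early-summer surveys.

    Surface early-summer chemistry is constructed from the spring state so
    the salinity-normalized deficits encode the prescribed C:N uptake ratio
    exactly before noise (see module docstring).  Station-level noise at the
    tabulated SDs (scaled by ``spec.noise``) represents patchiness plus
    measurement error.  Bottom samples are drawn from the bottom-layer
    statistics and only feed the depth-integrated NCP variant.
    """
    if rng is None:
        rng = spec.rng()
    em = spec.endmembers
    rows = []
    for region in ("southern", "northern"):
        targets = _summer_surface_targets(spec, region)
        spring_period = SPRING_PERIOD[region]
        for period in (spring_period, "early_summer"):
            stats = SEASONAL_STATS[period][region]
            surf = stats["surf"]
            lat_lo, lat_hi = _REGION_BAND[region]
            n_state = targets["n1"] if period == spring_period else targets["n2"]
            for i in range(spec.n_stations):
                lat = rng.uniform(lat_lo, lat_hi)
                lon = rng.uniform(-172.0, -162.0)
                s_i = max(rng.normal(surf["s"][0], surf["s"][1] * spec.noise), 6.0)
                row = {
                    "region": region, "period": period, "station": i,
                    "layer": "surf", "depth": 5.0,
                    "t": rng.normal(surf["t"][0], surf["t"][1] * spec.noise),
                    "s": s_i, "lat": lat, "lon": lon,
                    "ta": denormalize_tracer(n_state["ta"], s_i, em, "TA")
                          + rng.normal(0, surf["ta"][1] * spec.noise),
                    "dic": denormalize_tracer(n_state["dic"], s_i, em, "DIC")
                           + rng.normal(0, surf["dic"][1] * spec.noise),
                    "no3": max(denormalize_tracer(n_state["no3"], s_i, em, "NO3")
                               + rng.normal(0, surf["no3"][1] * spec.noise), 0.0),
                    "po4": max(denormalize_tracer(n_state["po4"], s_i, em, "PO4")
                               + rng.normal(0, surf["po4"][1] * spec.noise), 0.0),
                }
                rows.append(row)
                bot = stats["bot"]
                rows.append({
                    "region": region, "period": period, "station": i,
                    "layer": "bot", "depth": 40.0,
                    "t": rng.normal(bot["t"][0], bot["t"][1] * spec.noise),
                    "s": max(rng.normal(bot["s"][0], bot["s"][1] * spec.noise), 6.0),
                    "lat": lat, "lon": lon,
                    "ta": rng.normal(bot["ta"][0], bot["ta"][1] * spec.noise),
                    "dic": rng.normal(bot["dic"][0], bot["dic"][1] * spec.noise),
                    "no3": max(rng.normal(bot["no3"][0], bot["no3"][1] * spec.noise), 0.0),
                    "po4": max(rng.normal(bot["po4"][0], bot["po4"][1] * spec.noise), 0.0),
                })
    out = pd.DataFrame(rows)
    out.attrs["spec"] = spec.to_dict()
    return out


def _ramp(day, d0, d1, v0, v1):
    """Piecewise-linear ramp clamped outside [d0, d1]."""
    day = np.asarray(day, dtype=float)
    f = np.clip((day - d0) / (d1 - d0), 0.0, 1.0)
    return v0 + (v1 - v0) * f


def make_forcing(spec: ScenarioSpec, region: str = "northern",
                 rng: np.random.Generator | None = None,
                 day_lo: int = 120, day_hi: int = 270,
                 ncp_profile: str = "uniform") -> pd.DataFrame:
    """Daily forcing series for the flux calculation and the box model.

    Sea ice retreats as a deterministic sigmoid (full cover to open water,
    later in the north), SST ramps from the under-ice freezing state to the
    summer mean, winds fluctuate around <U10^2> = 49 m2 s-2, sea-level
    pressure around 1 atm, and dry-air xCO2 declines a few ppm over the
    season.  TA and SSS are interpolated linearly between the spring and
    early-summer surveyed means over the growing window, as the box model
    prescribes, and the nitrate-based NCP series distributes the regional
    nitrate drawdown inventory over the window either uniformly or as a
    triangular bloom.
    """
    if rng is None:
        rng = spec.rng()
    days = np.arange(day_lo, day_hi + 1)
    from .boxmodel import REGION_WINDOWS  # local import to avoid a cycle
    t_start, t_end = REGION_WINDOWS[region]

    spring = SEASONAL_STATS[SPRING_PERIOD[region]][region]["surf"]
    summer = SEASONAL_STATS["early_summer"][region]["surf"]

    if region == "southern":
        ice = 85.0 / (1.0 + np.exp((days - 150.0) / 5.0))
        warm = _ramp(days, 145, 205, 0.0, 1.0)
    else:
        ice = 100.0 / (1.0 + np.exp((days - 190.0) / 8.0))
        warm = _ramp(days, 170, 219, 0.0, 1.0)
    # surface warming tracks the retreating ice edge: water stays near
    # freezing under cover and warms toward the summer mean as it opens
    open_frac = 1.0 - ice / 100.0
    sst = spring["t"][0] + (summer["t"][0] - spring["t"][0]) * warm * open_frac

    sss = _ramp(days, t_start, t_end, spring["s"][0], summer["s"][0])
    ta = _ramp(days, t_start, t_end, spring["ta"][0], summer["ta"][0])

    targets = _summer_surface_targets(spec, region)
    total_n = targets["d_no3"] * spec.mld              # mmol N m-2 over the window
    in_window = (days >= t_start) & (days < t_end)
    ncp_n = np.zeros_like(days, dtype=float)
    if ncp_profile == "uniform":
        ncp_n[in_window] = total_n / (t_end - t_start)
    elif ncp_profile == "triangular":
        mid = 0.5 * (t_start + t_end)
        w = np.maximum(1.0 - np.abs(days - mid) / (0.5 * (t_end - t_start)), 0.0)
        w[~in_window] = 0.0
        ncp_n = w / w.sum() * total_n
    else:
        raise ValueError(f"unknown ncp_profile {ncp_profile!r}")

    out = pd.DataFrame({
        "day": days,
        "u10_sq": np.maximum(rng.normal(49.0, 8.0 * spec.noise, len(days)), 0.0),
        "ice_pct": np.clip(ice, 0.0, 100.0),
        "psl": rng.normal(1.0, 0.004 * spec.noise, len(days)),
        "xco2": _ramp(days, day_lo, day_hi, 402.0, 395.0),
        "sst": np.maximum(sst, -1.8),
        "sss": sss,
        "ta_interp": ta,
        "ncp_n_daily": ncp_n,
    })
    out.attrs["spec"] = spec.to_dict()
    out.attrs["region"] = region
    return out
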