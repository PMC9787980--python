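"""Equilibrium carbonate-system computations for cold shelf seawater.

The module solves the total alkalinity / dissolved inorganic carbon (TA/DIC)
equilibrium for the proton concentration and from it the seawater CO2 partial
pressure, using the carbonic-acid dissociation constants of Millero et al.
(2006) converted to the total pH scale, boric acid after Dickson (1990),
water self-ionization after Millero (1995), and total boron from salinity
after Uppstrom (1974).  Alkalinity contributions from carbonate, borate,
water, free protons, bisulfate and fluoride are included; nutrient terms are
omitted (they are < 1 umol kg-1 at the surface concentrations handled here).

The solver output is reported as pCO2 directly, without a fugacity
correction.  The fugacity factor would lower the result by roughly 0.3-0.4%
(about 2-3 uatm at 500 uatm), well below the +-18 uatm uncertainty attached
to pCO2 computed from TA and DIC measurements, but users comparing against a
solver that reports true pCO2 should be aware of the convention.

Also provided here: CO2 solubility (Weiss 1974), saturation water vapor
pressure over seawater (Buck 1981 with a linear salinity reduction), and the
EOS-80 one-atmosphere seawater density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from . import constants as cst

__all__ = [
    "CarbParams",
    "CarbState",
    "CarbonateSolverError",
    "equilibrium_constants",
    "pco2_from_ta_dic",
    "dic_from_ta_pco2",
    "co2_solubility",
    "vapor_pressure",
    "density",
]

_PH_LO, _PH_HI = 4.0, 12.0
_H_TOL = 1e-14  # relative tolerance on [H+], well below the 1e-8 contract


class CarbonateSolverError(RuntimeError):
    """Raised when the alkalinity equation cannot be solved for [H+]."""


@dataclass(frozen=True)
class CarbParams:
    """In-situ conditions for equilibrium computations.

    Parameters
    ----------
    temperature : float
        In-situ temperature, degC.  Valid range -2 to 35.
    salinity : float
        Practical salinity.  Valid range (0, 40].
    pressure : float
        Pressure in dbar; all surface work uses 0 and no pressure
        corrections are applied.
    """

    temperature: float
    salinity: float
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 35.0):
            raise ValueError(f"temperature {self.temperature} degC outside [-2, 35]")
        if not (0.0 < self.salinity <= 40.0):
            raise ValueError(f"salinity {self.salinity} outside (0, 40]")
        if self.pressure != 0.0:
            raise ValueError("only surface (0 dbar) computations are supported")


@dataclass(frozen=True)
class CarbState:
    """A solved surface carbonate-system state (umol kg-1 and uatm)."""

    ta: float
    dic: float
    pco2: float
    h_plus: float  # mol kg-1, total scale


def equilibrium_constants(temperature: float, salinity: float) -> dict[str, float]:
    """Equilibrium constants and conservative totals on the total pH scale.

    Returns a dict with K0 (mol kg-1 atm-1), K1, K2, KB, KW, KF (total
    scale), KS (free scale) and the totals TB, TS, TF (mol kg-1).
    """
    t_k = temperature + 273.15
    s = salinity
    sqrt_s = math.sqrt(s)
    ln_t = math.log(t_k)

    # conservative totals from salinity
    tb = cst.UPPSTROM_1974_BORON * s / 35.0
    ts = cst.MORRIS_RILEY_1966_SULFATE * s / 35.0
    tf = cst.RILEY_1965_FLUORIDE * s / 35.0

    # bisulfate (free scale), ionic strength formulation
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    d = cst.DICKSON_1990_KS
    ln_ks = (
        d["base"][0] + d["base"][1] / t_k + d["base"][2] * ln_t
        + math.sqrt(ion) * (d["sqrt_i"][0] + d["sqrt_i"][1] / t_k + d["sqrt_i"][2] * ln_t)
        + ion * (d["i"][0] + d["i"][1] / t_k + d["i"][2] * ln_t)
        + ion ** 1.5 * d["i15"] / t_k
        + ion ** 2 * d["i2"] / t_k
        + math.log(1.0 - 0.001005 * s)
    )
    ks = math.exp(ln_ks)

    # fluoride (total scale)
    kf = math.exp(cst.PEREZ_FRAGA_1987_KF[0] / t_k
                  + cst.PEREZ_FRAGA_1987_KF[1]
                  + cst.PEREZ_FRAGA_1987_KF[2] * sqrt_s)

    # seawater scale -> total scale conversion factor
    sws_to_tot = (1.0 + ts / ks) / (1.0 + ts / ks + tf / kf)

    # carbonic acid, Millero et al. (2006), reported on SWS
    a0, b0, c0 = cst.MILLERO_2006_PK1_0
    pk1_0 = a0 + b0 / t_k + c0 * ln_t
    a1, a2, a3, b1, b2, c1 = cst.MILLERO_2006_PK1_SAL
    pk1 = (pk1_0 + a1 * sqrt_s + a2 * s + a3 * s * s
           + (b1 * sqrt_s + b2 * s) / t_k + c1 * sqrt_s * ln_t)
    a0, b0, c0 = cst.MILLERO_2006_PK2_0
    pk2_0 = a0 + b0 / t_k + c0 * ln_t
    a1, a2, a3, b1, b2, c1 = cst.MILLERO_2006_PK2_SAL
    pk2 = (pk2_0 + a1 * sqrt_s + a2 * s + a3 * s * s
           + (b1 * sqrt_s + b2 * s) / t_k + c1 * sqrt_s * ln_t)
    k1 = 10.0 ** (-pk1) * sws_to_tot
    k2 = 10.0 ** (-pk2) * sws_to_tot

    # boric acid, Dickson (1990b), already total scale
    kb_c = cst.DICKSON_1990_KB
    ln_kb = (
        (kb_c["inv_t"][0] + kb_c["inv_t"][1] * sqrt_s + kb_c["inv_t"][2] * s
         + kb_c["inv_t"][3] * s * sqrt_s + kb_c["inv_t"][4] * s * s) / t_k
        + kb_c["const"][0] + kb_c["const"][1] * sqrt_s + kb_c["const"][2] * s
        + (kb_c["log_t"][0] + kb_c["log_t"][1] * sqrt_s + kb_c["log_t"][2] * s) * ln_t
        + kb_c["t"] * sqrt_s * t_k
    )
    kb = math.exp(ln_kb)

    # water, Millero (1995), SWS -> total
    kw_c = cst.MILLERO_1995_KW
    ln_kw = (
        kw_c["base"][0] + kw_c["base"][1] / t_k + kw_c["base"][2] * ln_t
        + sqrt_s * (kw_c["sqrt_s"][0] + kw_c["sqrt_s"][1] / t_k + kw_c["sqrt_s"][2] * ln_t)
        + kw_c["s"] * s
    )
    kw = math.exp(ln_kw) * sws_to_tot

    k0 = co2_solubility(temperature, salinity, gravimetric=True)

    return {"K0": k0, "K1": k1, "K2": k2, "KB": kb, "KW": kw,
            "KS": ks, "KF": kf, "TB": tb, "TS": ts, "TF": tf}


def _alkalinity_residual(h: float, ta_mol: float, dic_mol: float,
                         k: dict[str, float]) -> float:
    """TA(model) - TA(given), everything in mol kg-1; h on the total scale."""
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    hco3 = dic_mol * k["K1"] * h / denom
    co3 = dic_mol * k["K1"] * k["K2"] / denom
    boh4 = k["TB"] * k["KB"] / (k["KB"] + h)
    oh = k["KW"] / h
    h_free = h / (1.0 + k["TS"] / k["KS"])
    hso4 = k["TS"] * h_free / (h_free + k["KS"])
    hf = k["TF"] * h / (h + k["KF"])
    return hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf - ta_mol


def _solve_h(ta: float, dic: float, params: CarbParams) -> tuple[float, dict[str, float]]:
    if ta <= 0.0 or dic <= 0.0:
        raise ValueError(f"ta and dic must be positive (got ta={ta}, dic={dic})")
    k = equilibrium_constants(params.temperature, params.salinity)
    ta_mol, dic_mol = ta * 1e-6, dic * 1e-6
    h_hi, h_lo = 10.0 ** (-_PH_LO), 10.0 ** (-_PH_HI)
    f_lo = _alkalinity_residual(h_lo, ta_mol, dic_mol, k)
    f_hi = _alkalinity_residual(h_hi, ta_mol, dic_mol, k)
    if f_lo * f_hi > 0.0:
        raise CarbonateSolverError(
            f"no [H+] root in pH [{_PH_LO}, {_PH_HI}] for ta={ta}, dic={dic}, "
            f"T={params.temperature}, S={params.salinity}")
    try:
        h = brentq(_alkalinity_residual, h_lo, h_hi,
                   args=(ta_mol, dic_mol, k), rtol=_H_TOL, xtol=1e-30, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq convergence failure
        raise CarbonateSolverError(
            f"solver failed for ta={ta}, dic={dic}, T={params.temperature}, "
            f"S={params.salinity}: {exc}") from exc
    return h, k


def pco2_from_ta_dic(ta: float, dic: float, params: CarbParams) -> float:
    """Seawater pCO2 (uatm) from TA and DIC (umol kg-1)."""
    h, k = _solve_h(ta, dic, params)
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    co2_star = dic * 1e-6 * h * h / denom           # mol kg-1
    return co2_star / k["K0"] * 1e6                  # uatm


def solve_state(ta: float, dic: float, params: CarbParams) -> CarbState:
    """Full solved state (TA, DIC, pCO2, [H+]) for one sample."""
    h, k = _solve_h(ta, dic, params)
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    co2_star = dic * 1e-6 * h * h / denom
    return CarbState(ta=ta, dic=dic, pco2=co2_star / k["K0"] * 1e6, h_plus=h)


def dic_from_ta_pco2(ta: float, pco2: float, params: CarbParams) -> float:
    """DIC (umol kg-1) from TA (umol kg-1) and pCO2 (uatm); inverse of
    :func:`pco2_from_ta_dic` under identical constants."""
    if ta <= 0.0:
        raise ValueError(f"ta must be positive (got {ta})")
    if pco2 <= 0.0:
        raise ValueError(f"pco2 must be positive (got {pco2})")
    k = equilibrium_constants(params.temperature, params.salinity)
    ta_mol = ta * 1e-6
    co2_star = k["K0"] * pco2 * 1e-6                 # mol kg-1

    def residual(h: float) -> float:
        hco3 = co2_star * k["K1"] / h
        co3 = co2_star * k["K1"] * k["K2"] / (h * h)
        boh4 = k["TB"] * k["KB"] / (k["KB"] + h)
        oh = k["KW"] / h
        h_free = h / (1.0 + k["TS"] / k["KS"])
        hso4 = k["TS"] * h_free / (h_free + k["KS"])
        hf = k["TF"] * h / (h + k["KF"])
        return hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf - ta_mol

    h_hi, h_lo = 10.0 ** (-_PH_LO), 10.0 ** (-_PH_HI)
    if residual(h_lo) * residual(h_hi) > 0.0:
        raise CarbonateSolverError(
            f"no [H+] root for ta={ta}, pco2={pco2}, "
            f"T={params.temperature}, S={params.salinity}")
    h = brentq(residual, h_lo, h_hi, rtol=_H_TOL, xtol=1e-30, maxiter=200)
    dic_mol = co2_star * (1.0 + k["K1"] / h + k["K1"] * k["K2"] / (h * h))
    return dic_mol * 1e6


def co2_solubility(temperature: float, salinity: float,
                   gravimetric: bool = False) -> float:
    """CO2 solubility K0 after Weiss (1974).

    Volumetric units (mol L-1 atm-1) by default, as used by the flux unit
    factor; ``gravimetric=True`` returns mol kg-1 atm-1 for the equilibrium
    solver.
    """
    if not (-2.0 <= temperature <= 40.0) or not (0.0 <= salinity <= 42.0):
        raise ValueError(f"T={temperature}, S={salinity} outside Weiss (1974) range")
    t100 = (temperature + 273.15) / 100.0
    a1, a2, a3, b1, b2, b3 = (cst.WEISS_1974_GRAV if gravimetric
                              else cst.WEISS_1974_VOL)
    ln_k0 = (a1 + a2 / t100 + a3 * math.log(t100)
             + salinity * (b1 + b2 * t100 + b3 * t100 * t100))
    return math.exp(ln_k0)


def vapor_pressure(temperature: float, psl: float = 1.0,
                   salinity: float = 35.0) -> float:
    """Saturation water vapor pressure over seawater (atm).

    Buck (1981) pure-water curve with a linear salinity reduction
    (1 - 0.000537 S).  ``psl`` (atm) is used only for the physical sanity
    check that the air is not entirely water vapor.
    """
    if temperature < -2.0:
        raise ValueError(f"temperature {temperature} below -2 degC")
    e_hpa = cst.BUCK_1981_A_HPA * math.exp(
        cst.BUCK_1981_B * temperature / (cst.BUCK_1981_C + temperature))
    pw = e_hpa / cst.ATM_HPA * (1.0 - cst.VAPOR_SALINITY_REDUCTION * salinity)
    if pw >= psl:
        raise ValueError(f"vapor pressure {pw:.4f} atm >= sea-level pressure {psl}")
    return pw


def density(temperature: float, salinity: float) -> float:
    """Surface seawater density (kg m-3), EOS-80 at 0 dbar."""
    if not (-2.0 <= temperature <= 40.0) or not (0.0 <= salinity <= 42.0):
        raise ValueError(f"T={temperature}, S={salinity} outside EOS-80 range")
    t = temperature
    s = salinity
    rho_w = sum(c * t ** i for i, c in enumerate(cst.EOS80_PURE_WATER))
    a = sum(c * t ** i for i, c in enumerate(cst.EOS80_A))
    b = sum(c * t ** i for i, c in enumerate(cst.EOS80_B))
    return rho_w + a * s + b * s ** 1.5 + cst.EOS80_C * s ** 2
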