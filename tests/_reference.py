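"""Independent reference routes used as oracles by the test suite.

The package solves the alkalinity balance for [H+] with a bracketed
safeguarded root finder.  The reference implementation here takes a wholly
different numerical route: the same chemical system is written as an exact
polynomial in [H+] (the alkalinity balance multiplied through by every
denominator) whose coefficients are assembled by polynomial convolution and
whose roots are found by companion-matrix eigenvalues (``numpy.roots``).
Only the constants table is shared; if either route mis-handles the
chemistry or the numerics the two disagree.

Also here: a brute-force trapezoidal NCP calculator used to cross-check the
drawdown arithmetic, independent of the package's ncp module.
"""

from __future__ import annotations

import numpy as np

from chukchi_carbon.carbonate import equilibrium_constants


def pco2_polynomial(ta: float, dic: float, temperature: float, salinity: float) -> float:
    """pCO2 (uatm) via exact polynomial-in-[H+] formulation.

    Species identical to the package solver: carbonate, borate, water,
    free H+, bisulfate, fluoride alkalinity.
    """
    k = equilibrium_constants(temperature, salinity)
    ta_m, dic_m = ta * 1e-6, dic * 1e-6
    k1, k2, kb, kw = k["K1"], k["K2"], k["KB"], k["KW"]
    ts, ks, tf, kf, tb = k["TS"], k["KS"], k["TF"], k["KF"], k["TB"]
    s_fac = 1.0 + ts / ks           # total = free * s_fac
    ks_t = ks * s_fac               # effective KS on the total scale

    # factor polynomials in h (highest degree first)
    p_carb = np.array([1.0, k1, k1 * k2])        # h^2 + K1 h + K1K2
    p_b = np.array([1.0, kb])
    p_h = np.array([1.0, 0.0])
    p_s = np.array([1.0, ks_t])
    p_f = np.array([1.0, kf])

    m = np.polymul(np.polymul(np.polymul(np.polymul(p_carb, p_b), p_h), p_s), p_f)

    def without(*keep_out):
        poly = np.array([1.0])
        for p in (p_carb, p_b, p_h, p_s, p_f):
            if not any(p is q for q in keep_out):
                poly = np.polymul(poly, p)
        return poly

    terms = []
    # carbonate alkalinity: dic*(K1 h + 2 K1K2) * M/p_carb
    terms.append(np.polymul(dic_m * np.array([k1, 2.0 * k1 * k2]), without(p_carb)))
    # borate: TB*KB * M/p_b
    terms.append(tb * kb * without(p_b))
    # hydroxide: KW/h * M  -> KW * M/p_h
    terms.append(kw * without(p_h))
    # free proton: -(h/s_fac) * M
    terms.append(np.polymul(np.array([-1.0 / s_fac, 0.0]), m))
    # bisulfate: -TS*h/(h + KS*s_fac) * M
    terms.append(np.polymul(-ts * np.array([1.0, 0.0]), without(p_s)))
    # fluoride: -TF*h/(h + KF) * M
    terms.append(np.polymul(-tf * np.array([1.0, 0.0]), without(p_f)))
    # -TA * M
    terms.append(-ta_m * m)

    deg = max(len(t) for t in terms)
    coeffs = np.zeros(deg)
    for t in terms:
        coeffs[deg - len(t):] += t

    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-25 * np.abs(roots.real).max()].real
    phys = real[(real > 1e-12) & (real < 1e-4)]
    if len(phys) != 1:
        # fall back: pick the root closest to pH 8
        phys = np.array([real[np.argmin(np.abs(np.log10(np.abs(real)) + 8.0))]])
    h = float(phys[0])
    co2_star = dic_m * h * h / (h * h + k1 * h + k1 * k2)
    return co2_star / k["K0"] * 1e6


def ncp_brute_force(drawdown: float, mld: float, dt: float) -> float:
    """Drawdown-inventory NCP by explicit unit bookkeeping (umol/L * m / d)."""
    inventory_mmol_m2 = drawdown * 1e-3 * mld * 1e3  # umol/L -> mol/m3 -> mmol/m2
    return inventory_mmol_m2 / dt
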