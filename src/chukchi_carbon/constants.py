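"""Single versioned table of physical and empirical constants.

Every empirical coefficient used anywhere in the package lives here, so a
constant-set change is a one-file diff.  Coefficient provenance:

* ``WEISS_1974_*`` -- CO2 solubility K0, Weiss (1974), Mar. Chem. 2, 203-215.
* ``MILLERO_2006_*`` -- carbonic acid K1/K2 for seawater, Millero et al.
  (2006), Mar. Chem. 100, 80-94 (reported on the seawater pH scale).
* ``DICKSON_1990_KB`` -- boric acid, Dickson (1990), Deep-Sea Res. 37, 755
  (total scale).
* ``MILLERO_1995_KW`` -- water self-ionization, Millero (1995) (SWS scale).
* ``DICKSON_1990_KS`` -- bisulfate, Dickson (1990), J. Chem. Thermodyn. 22,
  113 (free scale).
* ``PEREZ_FRAGA_1987_KF`` -- hydrogen fluoride, Perez & Fraga (1987)
  (total scale).
* ``EOS80_*`` -- one-atmosphere International Equation of State of Seawater
  (Millero & Poisson 1981 / UNESCO 1983).
* ``WANNINKHOF_2014_SC`` -- CO2 Schmidt number in seawater, 4th-order
  polynomial in temperature, Wanninkhof (2014), Limnol. Oceanogr. Methods 12.
* ``BUCK_1981_*`` -- saturation vapor pressure over water, Buck (1981),
  with a linear salinity reduction for seawater.
"""

from __future__ import annotations

CONSTANTS_VERSION = "1.0"

# --- gas exchange -----------------------------------------------------------

#: Coefficient of the quadratic wind-speed gas-transfer parameterization
#: (cm hr-1 per (m s-1)^2), Wanninkhof (2014).
GAS_TRANSFER_COEFF = 0.251

#: Schmidt number normalization (CO2 in seawater at 20 degC).
SCHMIDT_REFERENCE = 660.0

#: Schmidt number polynomial Sc(T) = A + B*T + C*T^2 + D*T^3 + E*T^4, T in degC.
WANNINKHOF_2014_SC = (2116.8, -136.25, 4.7353, -0.092307, 0.0007555)

#: Unit conversion (cm hr-1)*(mol L-1 atm-1)*(uatm) -> mmol m-2 d-1.
#: 1 cm hr-1 = 0.24 m d-1; mol L-1 = 1e3 mol m-3; uatm = 1e-6 atm;
#: mol -> mmol = 1e3.  Product of the scale factors: 0.24.
FLUX_UNIT_FACTOR = 0.24

#: Ice concentration (percent) above which a 10% open-water fraction is
#: retained for gas exchange (leads unresolved by satellite ice products).
ICE_CAP_PCT = 90.0

# --- CO2 solubility (Weiss 1974), ln K0 = A1 + A2*(100/T) + A3*ln(T/100)
#     + S*(B1 + B2*(T/100) + B3*(T/100)^2), T in kelvin ---------------------

WEISS_1974_VOL = (-58.0931, 90.5069, 22.2940, 0.027766, -0.025888, 0.0050578)  # mol L-1 atm-1
WEISS_1974_GRAV = (-60.2409, 93.4517, 23.3585, 0.023517, -0.023656, 0.0047036)  # mol kg-1 atm-1

# --- carbonic acid dissociation, Millero et al. (2006), SWS scale ----------
# pK = pK0(T) + A(S) + B(S)/T + C(S)*ln(T)

MILLERO_2006_PK1_0 = (-126.34048, 6320.813, 19.568224)   # a + b/T + c*lnT
MILLERO_2006_PK1_SAL = (13.4191, 0.0331, -5.33e-5,       # A: sqrtS, S, S^2
                        -530.123, -6.103,                # B: sqrtS, S
                        -2.06950)                        # C: sqrtS
MILLERO_2006_PK2_0 = (-90.18333, 5143.692, 14.613358)
MILLERO_2006_PK2_SAL = (21.0894, 0.1248, -3.687e-4,
                        -772.483, -20.051,
                        -3.3336)

# --- boric acid, Dickson (1990b), total scale ------------------------------

DICKSON_1990_KB = {
    "inv_t": (-8966.90, -2890.53, -77.942, 1.728, -0.0996),  # /T: 1, sqrtS, S, S^1.5, S^2
    "const": (148.0248, 137.1942, 1.62142),                   # 1, sqrtS, S
    "log_t": (-24.4344, -25.085, -0.2474),                    # lnT: 1, sqrtS, S
    "t": 0.053105,                                            # T * sqrtS
}

# --- water self-ionization, Millero (1995), SWS scale ----------------------

MILLERO_1995_KW = {
    "base": (148.9802, -13847.26, -23.6521),       # 1, 1/T, lnT
    "sqrt_s": (-5.977, 118.67, 1.0495),            # 1, 1/T, lnT (times sqrtS)
    "s": -0.01615,
}

# --- bisulfate, Dickson (1990a), free scale, ionic strength I --------------

DICKSON_1990_KS = {
    "base": (141.328, -4276.1, -23.093),           # 1, 1/T, lnT
    "sqrt_i": (324.57, -13856.0, -47.986),
    "i": (-771.54, 35474.0, 114.723),
    "i15": -2698.0,                                 # /T only
    "i2": 1776.0,                                   # /T only
}

# --- hydrogen fluoride, Perez & Fraga (1987), total scale ------------------

PEREZ_FRAGA_1987_KF = (874.0, -9.68, 0.111)         # 1/T, const, sqrtS

# --- conservative seawater composition (mol kg-1 at S = 35) ----------------

UPPSTROM_1974_BORON = 0.0004157     # total boron * 35/S
MORRIS_RILEY_1966_SULFATE = 0.02824
RILEY_1965_FLUORIDE = 6.832e-5

# --- EOS-80 one-atmosphere density (kg m-3) --------------------------------

EOS80_PURE_WATER = (999.842594, 6.793952e-2, -9.095290e-3,
                    1.001685e-4, -1.120083e-6, 6.536332e-9)
EOS80_A = (8.24493e-1, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9)
EOS80_B = (-5.72466e-3, 1.0227e-4, -1.6546e-6)
EOS80_C = 4.8314e-4

# --- saturation vapor pressure, Buck (1981) curve e_w4 ---------------------
# e_sat(T) = a * exp(b*T/(c+T)) in hPa, T in degC; seawater reduction
# factor (1 - d*S) after Weiss & Price (1980).

BUCK_1981_A_HPA = 6.1121
BUCK_1981_B = 17.502
BUCK_1981_C = 240.97
VAPOR_SALINITY_REDUCTION = 5.37e-4
ATM_HPA = 1013.25

# --- stoichiometry ---------------------------------------------------------

#: Canonical Redfield molar C:N:P composition of marine plankton.
REDFIELD_C = 106.0
REDFIELD_N = 16.0
REDFIELD_P = 1.0
REDFIELD_CN = REDFIELD_C / REDFIELD_N   # 6.625

# --- study-frame defaults (seasonal reference state) -----------------------

#: Under-ice spring reference pCO2 (uatm) and its observed spread.
PCO2_INITIAL = 538.0
PCO2_INITIAL_SD = 68.0
#: Mean under-ice spring temperature (degC).
T_SPRING = -1.60
#: Takahashi thermal sensitivity of pCO2 (degC-1).
THERMAL_COEFF = 0.0423

#: Reference salinity for tracer normalization (under-ice spring water).
S_REFERENCE = 32.1
#: Linear mixing-line intercepts at S = 0 implied by a meltwater endmember
#: of S = 5, DIC = 400, TA = 460 umol kg-1 crossing the winter-water line.
DIC_S0_INTERCEPT = 60.0
TA_S0_INTERCEPT = 106.0
MELTWATER_ENDMEMBER = {"S": 5.0, "DIC": 400.0, "TA": 460.0}

#: Default mixed-layer depth (m).
MLD_DEFAULT = 25.0
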