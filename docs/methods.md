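# Methods

This note records the models implemented in `chukchi_carbon`, the choices
made where the formulation was genuinely open, and what the synthetic data
do and do not establish.

## Carbonate system

Surface pCO2 is solved from total alkalinity (TA) and dissolved inorganic
carbon (DIC) by finding the proton concentration that closes the alkalinity
balance

    TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]F - [HSO4-] - [HF]

with carbonic-acid constants of Millero et al. (2006) — the set recommended
for cold, brackish shelf water — converted from the seawater to the total pH
scale; boric acid after Dickson (1990), total boron from salinity after
Uppström (1974); water after Millero (1995); bisulfate after Dickson (1990)
and fluoride after Perez & Fraga (1987). Nutrient alkalinity is omitted:
at the < 2 µM surface nutrient levels involved it contributes < 1 µmol kg⁻¹,
far below the ±18 µmol-scale uncertainty of computed pCO2. The root is
bracketed over pH 4–12 and found with Brent's method at 1e-14 relative
tolerance on [H+] (contract: ≤ 1e-8); the TA/DIC ↔ TA/pCO2 round trip closes
to better than 1e-6 µmol kg⁻¹.

The solver reports [CO2*]/K0 directly as pCO2, with no fugacity correction
(a ≤ 0.4 % effect, i.e. 2–3 µatm at 500 µatm). K0 is Weiss (1974);
volumetric units (mol L⁻¹ atm⁻¹) feed the flux formula, gravimetric units
the equilibrium solver.

Verification takes two independent routes. First, the same chemical system
is written as an exact polynomial in [H+] and solved by companion-matrix
roots in the test suite; the two routes share only the constants table and
agree to ~1e-10 µatm over a 5×5×5 (TA, DIC, T) grid. Second, physical
anchors: the EOS-80 density implementation reproduces the published UNESCO
check values to 1e-4 kg m⁻³, the boric-acid constant reproduces its
published total-scale check value (pKB = 8.5975 at 25 °C, S = 35), and the
under-ice spring water type (TA 2225, DIC 2173 µmol kg⁻¹ at −1.71 °C,
S 32.1) solves to a pCO2 inside the observed under-ice band of 538 ± 68
µatm. Buffer behaviour is canonical: Revelle factor ≈ 18 for the cold
high-DIC state, thermal sensitivity ≈ 4.5 %/°C.

Vapor pressure over seawater uses the Buck (1981) pure-water curve with a
linear salinity reduction (1 − 0.000537 S); density is the EOS-80
one-atmosphere equation of state, since inputs are practical salinity.

## Water masses and regions

Classification follows the conventional T/S boxes for the Chukchi shelf
(winter waters NVWW/RWW, Alaskan Coastal Water, Bering Summer Water, early-
and late-season meltwater, river water), with strict inequalities as the
boxes are conventionally printed. Points exactly on a boundary that no box
includes are labelled OTHER and excluded from group statistics; the only
genuine overlap (T > 8, S < 30 satisfies both river water and late-season
meltwater) resolves to river water, which is grouped with the coastal
current. Atlantic Water (T > −1.0, S > 33.6) never surfaces on the shelf
and is reachable only when a below-shelf depth flag is supplied. The region
split is 69.5 °N within a 66–74 °N study domain. An exhaustive 0.1°-resolution
grid scan verifies the partition is single-valued after precedence.

## Gridding, decomposition, flux

Underway tracks are averaged into daily 0.25° × 0.25° cells (half-open bins
anchored at 0°, UTC day boundary) so dense station-keeping does not
overweight regional statistics; missing values drop per variable and the
observation count is conserved.

The seasonal pCO2 change of each cell relative to the under-ice spring
reference (538 µatm at −1.60 °C, configurable; the ±68 µatm spread is
available as a sensitivity sweep, not propagated as an error bar) is split
into a thermal part, pCO2_ini·(exp(0.0423·ΔT) − 1), and a non-thermal
remainder; additivity is exact by construction.

Flux per cell is F = 0.24·Ks·k·ΔpCO2 (mmol m⁻² d⁻¹, negative into the sea)
with k = 0.251·⟨U10²⟩·(Sc/660)^(−1/2) scaled by open-water fraction; the
Schmidt number is the Wanninkhof (2014) seawater polynomial (the source of
the 0.251 coefficient prints no Sc formula, so the same reference's
polynomial is pinned). Where reported ice cover exceeds 90 %, a 10 %
open-water fraction is retained (leads unresolved at radiometer resolution);
below 90 % the scaling is purely linear. Moist-air pCO2 is
xCO2·(Psl − Pw). The 0.24 unit factor is derived dimensionally and asserted
in tests. Group contrasts (ACW + river water vs BSW + meltwaters) use a
Welch t-test, since group variances differ visibly; groups with n < 2 skip
the test with a flag.

## Salinity normalization and NCP

Tracers are projected along conservative mixing lines to the under-ice
reference salinity S0 = 32.1 (the spring surface mean; configurable) with
non-zero S = 0 intercepts implied by a meltwater endmember of S = 5,
DIC = 400, TA = 460 µmol kg⁻¹ — i.e. DIC(S=0) = 60 and TA(S=0) = 106
µmol kg⁻¹ — and zero intercepts for nutrients. With intercepts equal to the
true mixing-line intercept the normalization removes dilution exactly; with
the fixed default intercepts the residual error for realistic melt
fractions is a few µmol kg⁻¹, small against seasonal drawdowns of ~80–95
µmol kg⁻¹.

NCP over a growing season Δt is drawdown × MLD / Δt with MLD = 25 m;
nutrient NCPs convert to carbon at 106:16:1. The DIC-based NCP additionally
removes the air–sea influx (period-mean flux, negative for uptake) and the
CaCO3 term. The CaCO3 correction is written in the nitrate-credit
convention: nitrate assimilation raises alkalinity one-for-one, so

    ΔDIC_CaCO3 = 0.5 · (ΔnTA·ρ/1000 + ΔnNO3)   [µM, Δ = spring − later]

pinned in a single function with its own tests. The printed forms of this
correction in the literature are sign-ambiguous; under this convention the
dissolution share of DIC-based NCP is exposed as a diagnostic only. Density
enters as ρ/1000 (kg L⁻¹) to convert µmol kg⁻¹ to µM, using the mean of the
two survey densities. A depth-integrated variant replaces drawdown × MLD by
trapezoidal profile inventories.

The C:N and C:P uptake ratios are NCP_DIC : NCP_N and NCP_DIC : NCP_P;
values well above the Redfield 6.625 and 106 diagnose carbon
overconsumption. An optional N2-fixation adjustment adds rate·depth/1000 to
NCP_N (at the highest reported regional rate, 3.6 nmol N L⁻¹ d⁻¹ over 25 m,
this is 0.09 mmol N m⁻² d⁻¹ — about 2 %, too small to explain the C:N
excess).

## Box model

The mixed layer is a single 25 m box stepped daily (τ = 1 d) over the
regional melt-season windows (day 136–219 south, 167–219 north). Each day
the box's pCO2 is re-solved from (TA, DIC) and the DIC changes by
(i) the air–sea flux term (uptake adds DIC, converted by MLD·ρ/1000),
(ii) biology, −NCP_N·(C:N)/(MLD·ρ/1000) with the scenario C:N ratio, and
(iii) meltwater dilution, (TA_{t+1} − TA_t)/TA_t · DIC_t, with TA prescribed
by linear interpolation between the surveyed seasonal means (assuming thin
first-year ice carries the surface TA/DIC ratio); optionally (iv) a uniform
daily DIC source for diagnosed CaCO3 dissolution. The three terms are
evaluated simultaneously from the start-of-day state; evaluating them
sequentially instead changes the final DIC by < 0.5 µmol kg⁻¹ over a season
(asserted). The budget closes to 1e-9 µmol kg⁻¹. Initial (TA, DIC) default
to the pre-bloom regional surface means (2205/2068 south, 2229/2153 north).

The daily NCP_N series distributes the regional nitrate-drawdown inventory
(Δ(nNO3)·MLD) uniformly over the window — the total, not the time course,
is observationally constrained — with a triangular bloom profile available.

Scenario comparison contrasts a Redfield run (C:N = 6.625) against a
flexible-stoichiometry run (diagnosed C:N) under identical forcing:
enhancement = (U_nr − U_r)/U_r and flexibility share = (U_nr − U_r)/U_nr of
cumulative uptake. Guaranteed (and tested) properties: flexible uptake
strictly exceeds Redfield uptake, uptake is monotone in C:N, and the
Redfield limit reduces exactly to the fixed-stoichiometry model. The
*magnitudes* of the enhancement depend on the daily forcing series: under
the synthetic forcing below, the southern pair lands near the reported
enhancement scale while the northern Redfield run is more strongly
ice-limited, so its enhancement is larger than the reported value; absolute
uptake totals are not reproducible without the original daily forcing and
are not asserted anywhere.

## Synthetic generator

The generator emulates: two-region seasonal means/SDs of T, S, TA, DIC,
NO3, PO4 for surface and bottom layers; meltwater freshening along the
two-endmember mixing line (so TA/DIC co-vary with salinity); underway pCO2
computed chemically from each record's (TA, DIC, T, S); sigmoidal ice
retreat (midpoint day ~150 south, ~190 north) with SST coupled to the
ice-open fraction — surface water stays near freezing under cover and warms
toward the summer mean as it opens, matching the observed collocation of
SST fronts with the ice edge; winds around ⟨U10²⟩ = 49 m² s⁻²; sea-level
pressure ≈ 1 atm; dry-air xCO2 declining 402 → 395 ppm over the season.

Bottle surveys are generated by inverting the analysis: the early-summer
surface state is constructed from the spring state so the normalized
deficits encode a prescribed C:N uptake ratio exactly before noise, plus a
growth-window air–sea DIC addition (−9.2 / −3.05 mmol m⁻² d⁻¹ south/north,
the means of the surveyed spring and early-summer regional fluxes), an
excess-TA term representing ikaite dissolution (24 / 26 µmol kg⁻¹, chosen so
the normalized-TA change matches the surveyed −34 / −36 µmol kg⁻¹), and
de-normalization to the summer salinity. Station noise at the tabulated SDs
represents patchiness plus measurement error. All randomness flows from one
seeded generator, and every table carries its generating spec in `attrs`.

Not emulated: spatial circulation and advection, correlated T–S–chemistry
error structure within stations, sub-daily forcing variability, river
plumes, and the real campaign's uneven station coverage. Passing tests
therefore demonstrate the correctness and self-consistency of the
estimators under the stated statistical structure — not that the estimators
are unbiased against real, spatially organized fields.

## Problem sizes and numerical defaults

Default runs use 400 underway records per period and region, 15 bottle
stations per region and survey, 151 forcing days, and 83/52 daily box-model
steps; the parameter-recovery check averages 100 seeded surveys. The full
test suite runs in a few seconds on one CPU. Tolerances: solver 1e-14
relative on [H+]; round-trip assertion 0.01 µmol kg⁻¹; solver-vs-oracle
1 µatm; box budget 1e-9 µmol kg⁻¹; recovery 10 % on the multi-seed mean.

## Known limitations

- No fugacity correction and no pressure dependence; surface (0 dbar) only.
- The C:N estimator is a ratio of noisy means: single-survey estimates
  scatter by ±2–3 units at realistic noise even though the multi-seed mean
  recovers the prescribed ratio; uncertainty on a single survey should be
  bootstrapped, which the package does not yet do.
- The CaCO3 convention reproduces only one of the two published dissolution
  shares; it is deliberately a diagnostic, not a headline number.
- The box model has no entrainment, lateral advection, or prognostic ice;
  dilution is carried entirely by the prescribed TA trajectory.
- Box-model scenario *magnitudes* (enhancement percentages, absolute
  uptake) are forcing-dependent; only their ordering and budget properties
  are asserted.
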