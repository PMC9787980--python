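# chukchi-carbon

Seasonal carbon-cycle analysis of an Arctic shelf sea (the Chukchi Sea
archetype): from underway pCO2 tracks and discrete bottle chemistry to
air–sea CO2 fluxes, net community production (NCP), and a mixed-layer box
model that quantifies how flexible phytoplankton C:N stoichiometry enhances
ocean CO2 uptake. Written for marine biogeochemists who want a tested,
scriptable version of this now-standard analysis chain, with a synthetic
cruise-data generator so every stage runs without downloading campaign data.

## What it computes

- **Carbonate equilibrium** — pCO2 from TA and DIC (and the inverse) with
  Millero (2006) K1/K2 on the total pH scale, Weiss (1974) solubility,
  Buck (1981) vapor pressure, EOS-80 density.
- **Water masses** — T/S classification into NVWW, RWW, ACW, BSW,
  meltwaters and river water; region (69.5 °N split) and flux-group
  partitioning.
- **Gridding** — daily 0.25° × 0.25° reduction of underway tracks.
- **Decomposition** — seasonal pCO2 change relative to the under-ice spring
  state (538 µatm at −1.60 °C) split into thermal
  `pCO2_ini·(exp(0.0423·ΔT) − 1)` and non-thermal parts.
- **Flux** — `F = 0.24·Ks·k·ΔpCO2` with `k = 0.251·⟨U10²⟩·(Sc/660)^−½`
  scaled by open water, a 10 % open-water floor above 90 % ice cover, and
  Welch-tested water-mass group contrasts.
- **Normalization & NCP** — salinity normalization with non-zero meltwater
  endmembers (DIC(S=0) = 60, TA(S=0) = 106 µmol kg⁻¹); `NCP = Δn·MLD/Δt`
  for NO3, PO4 and (flux- and CaCO3-corrected) DIC; C:N and C:P uptake
  ratios; N2-fixation sensitivity.
- **Box model** — daily mixed-layer DIC budget
  `DIC_{t+1} = DIC_t + ΔDIC_flux + ΔDIC_bio + ΔDIC_dilution`, with pCO2
  re-solved each day, comparing Redfield (C:N = 6.6) against flexible
  (C:N ≈ 10.9–12.1) uptake scenarios.
- **Synthetic data** — seeded generator for underway tracks, bottle
  surveys encoding a prescribed C:N uptake ratio, and seasonal forcing
  (ice retreat, warming, wind).

## Worked example

NCP from the surveyed mixed-layer drawdowns between spring and early
summer (see `examples/ncp_from_drawdown.py`):

```python
from chukchi_carbon.ncp import DrawdownInput, ncp_from_drawdown

south = DrawdownInput(d_ndic=79.0, d_nno3=10.24, d_npo4=1.19,
                      d_nta=-34.0, dt=73.0, mean_co2_flux=-9.2)
r = ncp_from_drawdown(south)
print(f"NCP_N {r.ncp_n:.2f}  NCP_P {r.ncp_p:.2f}  NCP_DIC {r.ncp_dic:.1f}  "
      f"C:N {r.cn_uptake:.1f}")
```

prints

```
NCP_N 3.51  NCP_P 0.41  NCP_DIC 41.1  C:N 11.7
```

i.e. a 10.24 µM nitrate drawdown over a 25 m mixed layer and 73 days is
3.51 mmol N m⁻² d⁻¹ of nitrogen-based NCP (23.2 mmol C m⁻² d⁻¹ at
106:16), while the DIC deficit — after crediting the air–sea influx and
CaCO3 dissolution — implies ~41 mmol C m⁻² d⁻¹. The C:N uptake ratio of
~11–12, far above the Redfield 6.6, is the signature of carbon
overconsumption that the box model then translates into extra CO2 uptake:
`examples/boxmodel_scenarios.py` runs the Redfield and flexible scenarios
under identical synthetic forcing and prints the cumulative-uptake
enhancement and the share of uptake supported by stoichiometric
flexibility.

The other scripts in `examples/` cover the carbonate solver, the
water-mass/flux pipeline, and end-to-end recovery of a prescribed C:N
ratio from noisy synthetic surveys. The full pipeline is also scriptable
from a shell:

```sh
chukchi-carbon run --seed 1 --out results/
```

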