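"""From synthetic underway tracks to a water-mass-resolved CO2 flux table.

Generates a spring + early-summer synthetic survey, reduces it to daily
quarter-degree cells, splits each cell's pCO2 change into thermal and
non-thermal parts, computes ice-modulated air-sea fluxes, and prints the
regional flux summary with the ACW vs non-ACW contrast.
"""

from chukchi_carbon.io import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1, n_underway=300, n_stations=15))

cells = report["cells"]
print(f"{len(report['underway'])} underway records -> {len(cells)} daily cells")
print("\nmean pCO2 change decomposition by period (uatm):")
print(cells.groupby("period")[["d_total", "d_thermal", "d_nonthermal"]]
      .mean().round(1).to_string())

print("\nregional flux table (mmol m-2 d-1; negative = ocean uptake):")
cols = ["region", "period", "mean", "sd", "n", "acw_mean", "nonacw_mean",
        "p_value", "significance"]
print(report["flux_table"][cols].round(2).to_string(index=False))
# a significant ACW/non-ACW contrast in summer reflects the stronger
# biological drawdown in nutrient-rich non-coastal water.
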