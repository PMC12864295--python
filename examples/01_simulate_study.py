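"""Generate a synthetic 17-colony egg-monitoring study and look at its shape.

The generator reproduces the sampling structure of the Canadian herring
gull programs (regions, alternate-year chemistry, 1-5 pools per
colony-year) with known ground-truth trends, so every downstream stage can
be checked against truth.
"""

from hfrtrends.simulate import default_design, default_scenarios, simulate_study

design = default_design()
scenarios = default_scenarios(design)
measurements, covariates, truth = simulate_study(design, scenarios, seed=1)

print(f"measurement rows:        {len(measurements)}")
print(f"censored (non-detect):   {(~measurements['detected']).sum()}")
print(f"colonies:                {measurements['colony_id'].nunique()}")
print(f"years:                   {measurements['year'].min()}-"
      f"{measurements['year'].max()}")
print("\nDetection fraction by analyte (lowest five):")
print(measurements.groupby("analyte")["detected"].mean()
      .sort_values().head(5).round(3).to_string())
print("\nEach row is one pooled-egg homogenate x analyte with its own "
      "detection limit; the truth record keeps every generating parameter.")
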