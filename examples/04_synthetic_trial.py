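"""Simulate a full factorial trial and recover its designed effects.

Generates the 3-pattern x 4-rate x 3-replicate two-year experiment with
8% measurement noise, runs the chamber->flux->emission and plant
pipelines, and checks that the replicate means recover the designed
pattern ordering (PM > JM > FP) and the 160 kg/ha plant-response peak.
"""

from nbudget import (SyntheticDesign, emission_table, flux_table, generate,
                     recover_effects, summary_table)

design = SyntheticDesign(seed=42, cv=0.08)
data = generate(design)
print(f"generated: {len(data.soil)} soil rows, {len(data.plant)} plant rows, "
      f"{len(data.chamber)} chamber rows")

plant = summary_table(data.plant)
means = (plant.groupby(["pattern", "n_rate"])["plant_n_kg_ha"]
         .mean().unstack("pattern").round(1))
print("\nreplicate-mean plant N accumulation (kg/ha):")
print(means.to_string())

emissions = emission_table(flux_table(data.chamber, w_ridge=0.5))
by_trt = (emissions.groupby(["year", "pattern"])["n2o_emission_kg_ha"]
          .mean().round(2))
print("\nmean seasonal N2O emission (kg/ha):")
print(by_trt.to_string())

report = recover_effects(data, design)
print(f"\npattern ordering PM>JM>FP recovered: {report.pattern_order_ok}")
print(f"plant-N peak rate: {report.peak_rate:.0f} kg/ha "
      f"(designed {design.plant_peak_rate:.0f})")
print(f"max emission error vs noise-free truth: "
      f"{report.emission_max_rel_error:.1%}")
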