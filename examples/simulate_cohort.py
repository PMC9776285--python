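"""Generate a synthetic perfusion cohort and inspect one kidney.

Builds the study-sized cohort (4 nonfunctional / 10 limited / 12 functional
kidneys) with the full measurement schedule and prints the manifest plus the
derived marker table of one functional kidney.
"""

import pandas as pd

from renalnmp import GeneratorConfig, derive_marker_table, simulate_cohort

# 1 s hemodynamic sampling keeps the example quick; the analysis windowing
# is sampling-rate agnostic
cfg = GeneratorConfig(dt_s=1.0)
cohort = simulate_cohort((4, 10, 12), seed=1, params=cfg)

manifest = pd.DataFrame({
    "kidney": [r.kidney_id for r in cohort],
    "class": [r.function_class for r in cohort],
    "weight_g": [round(r.weight_g) for r in cohort],
    "wit_min": [round(r.wit_min) for r in cohort],
    "cit_min": [round(r.cit_min) for r in cohort],
    "split": [r.split for r in cohort],
})
print(manifest.groupby(["class", "split"]).size().unstack(fill_value=0))

functional = next(r for r in cohort if r.function_class == 3)
table = derive_marker_table(functional)
print(f"\nmarkers of {functional.kidney_id} "
      f"({functional.weight_g:.0f} g, functional):")
print(table.frame[["do2", "vo2", "ero2", "rbf", "ap", "t_kidney"]].round(2))

# A functional kidney holds flow well above the 23 mL/min/100 g critical
# value at the 100-110 mmHg pressure setpoint, so oxygen delivery stays in
# the supply-adequate regime for the whole four hours.
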