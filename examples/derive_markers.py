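"""Derive the eleven function/injury markers for one kidney.

Simulates a single limited-function kidney at the full measurement schedule
and prints the complete marker table, including the filtration markers on
their coarser 60-min grid.
"""

from renalnmp import derive_marker_table, simulate_kidney

kidney = simulate_kidney(2, seed=42, kidney_id="demo")
table = derive_marker_table(kidney)

print(f"kidney {table.kidney_id}: class {table.function_class}, "
      f"{table.weight_g:.0f} g, WIT {kidney.wit_min:.0f} min, "
      f"CIT {kidney.cit_min:.0f} min")
print(table.frame.round(2).to_string())

# Blood-gas markers (DO2, VO2, ERO2, CO2P) exist wherever a panel pair was
# measured; NaN marks a dropped panel.  rel_urea and rel_gst start from
# 100% at baseline; urine_rate is the hourly output per 100 g.  A limited
# kidney starts supply-adequate and slides toward the critical flow as its
# vascular resistance climbs.
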