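"""Simulate the three-group serum cohort and inspect its structure.

Generates the default study cohort (50 healthy, 46 localized, 50
metastatic) over the 7-protease panel and prints per-group mean
activities.  Healthy serum shows the highest activity for most proteases;
ADAM15 is elevated in metastatic relative to localized disease; ADAM17 is
flat by construction.
"""

import protpanel as pp

config = pp.CohortConfig(seed=1)
table = pp.generate_cohort(config)

print(f"cohort: {len(table)} samples")
print(table["group"].value_counts().to_string())
print("\nper-group mean activity (a.u.):")
print(table.groupby("group")[pp.default_panel().columns].mean().round(1).to_string())
print("\nEach row is a serum sample; each activity column is the net "
      "fluorescence a protease releases from its nanobiosensor.")
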