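"""From raw plate wells to a feature table.

Simulates triplicate 96-well readouts (sample control, assay control and
assay solutions) for a small cohort, then reduces them back to one net
activity per sample and protease: mean(assay) - mean(assay control),
floored at zero, with coefficient-of-variation QC flags.
"""

import protpanel as pp

table = pp.generate_cohort(
    pp.CohortConfig(seed=2, n_healthy=4, n_localized=4, n_metastatic=4)
)
plates = pp.generate_plates(table, plate_noise_sd=5.0, seed=2)
print(f"plate records: {len(plates)} wells "
      f"({len(table)} samples x 7 proteases x 3 solutions x 3 replicates)")
print(plates.head(6).to_string(index=False))

features, qc = pp.summarize_wells(
    plates, groups=table.set_index("sample_id")["group"]
)
print("\nrecovered activities (a.u.):")
print(features.head(4).round(1).to_string(index=False))
print(f"\nQC flags raised: {len(qc)}")
print("Recovered values differ from the simulated truth only by plate "
      "noise (sd 5 a.u. per well, ~4 a.u. after triplicate averaging).")
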