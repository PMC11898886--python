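"""Exact Shapley attributions for individual predictions.

Explains which panel proteases drive the hierarchical model's class
probability for a held-out sample: phi_i is protease i's additive
contribution (in probability units) relative to the background average,
computed exactly over all 2^7 feature coalitions.  base_value + sum(phi)
equals the model output (efficiency axiom).
"""

import numpy as np

import protpanel as pp
from protpanel.explain import cap_background

panel = pp.default_panel()
table = pp.generate_cohort(pp.CohortConfig(seed=1))
result = pp.run_al(table, config=pp.ALConfig(), seed=1)
model = result.state.model

indexed = table.set_index("sample_id", drop=False)
labeled = indexed.loc[result.state.labeled_ids]
background = cap_background(labeled[panel.columns].to_numpy(float))

explanations = []
for _, row in indexed.loc[result.state.test_ids].query(
    "group == 'healthy'"
).head(8).iterrows():
    x = row[panel.columns].to_numpy(float)
    predicted = model.predict(x).predicted_class
    fn = pp.class_predict_fn(model, pp.GROUPS.index(predicted))
    explanations.append(
        pp.shapley_exact(fn, x, background, sample_id=row["sample_id"],
                         explained_class=predicted)
    )

ex = explanations[0]
print(f"sample {ex.sample_id}, explained class {ex.explained_class!r}:")
print(f"  base value (background mean probability): {ex.base_value:.3f}")
for protease, phi in zip(panel.proteases, ex.phi):
    print(f"  {protease:<10s} phi = {phi:+.3f}")
total = ex.base_value + ex.phi.sum()
print(f"  base + sum(phi) = {total:.3f} = model output (efficiency)")

ranking, top3 = pp.top_features(explanations, "healthy", panel=panel)
print(f"\nhealthy-class aggregate ranking (mean |phi| over "
      f"{len(explanations)} samples): {', '.join(ranking)}")
print(f"top-3: {', '.join(top3)}")
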