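"""The composite NQE predictor and its Shapley attribution.

A random forest learns the reduced temperature T_vm = Δ_vm/α_P from the
two intrinsic descriptors (average atomic mass m_w, hydrogen density n_H);
the prediction Δ̂_vm = T̂_vm·α_P composes it with the classical expansivity.
Leave-one-out R² measures out-of-sample recovery; exact Shapley values
attribute each prediction to the three inputs.
"""

import numpy as np

from nqeliq.ml_pipeline import (
    composite_prediction_function,
    exact_shapley,
    fit_composite,
    loo_evaluate,
    stability_groups,
)
from nqeliq.synthetic_data import FeatureGenSpec, make_feature_dataset

table, latent = make_feature_dataset(FeatureGenSpec(seed=0))
res = loo_evaluate(table, n_seed_iterations=5)
print(f"LOO R^2 over 92 molecules, 5 forest seeds: "
      f"{res['r2_mean']:.3f} +- {res['r2_sem']:.3f}")

model = fit_composite(table, seed=0)
f = composite_prediction_function(model)
bg = table[["m_w", "n_H", "alpha_P"]].to_numpy()
i = int(np.argmax(table["delta_vm"]))
phi = exact_shapley(f, bg[i], bg)
print(f"\nmost quantum molecule: {table['name'][i]} "
      f"(Delta_vm = {100 * table['delta_vm'][i]:.2f} %)")
for name, p in zip(("m_w", "n_H", "alpha_P"), phi):
    print(f"  phi_{name:8s} = {100 * p:+7.3f} % of molar volume")
print(f"  sum(phi) = f(x) - E[f] = "
      f"{100 * (f(bg[i][None])[0] - f(bg).mean()):+7.3f} %  (efficiency)")

groups = stability_groups(table, k=4, seed=0)
print("\nn_H group centers (A^-3):",
      ", ".join(f"{c:.4f}" for c in groups.centers))
print("High n_H and high alpha_P both push Delta_vm up; the groups "
      "disentangle the two effects.")
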