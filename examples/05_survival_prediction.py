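"""Predicting overall survival from discriminative connections via LOOCV SVR.

Simulates a patient cohort whose survival is coupled to five planted
connections, runs leave-one-out support-vector regression with per-fold
deconfounding and feature selection, and assesses the observed-vs-predicted
correlation by permutation.
"""

import numpy as np

from klsnet import (
    SimulationConfig,
    loocv_predict,
    permutation_test,
    simulate_connectivity_direct,
    summarize_weights,
)

cfg = SimulationConfig(
    n_patients=78, n_controls=60, n_regions=10,
    planted_edges=[(1, 2, 1.5), (3, 4, 1.5), (5, 6, 1.5), (7, 8, 1.5), (9, 10, 1.5)],
    outcome_betas={(1, 2): 40, (3, 4): -30, (5, 6): 25, (7, 8): 35, (9, 10): -20},
    survival_noise_sd=3.0, seed=1,
)
cohort = simulate_connectivity_direct(cfg)

result = loocv_predict(cohort.patient_records(), cohort.controls_table())
p = permutation_test(result, n_perm=9999, seed=0)
print(f"{len(result.predicted)} LOOCV folds "
      f"(mean {np.mean(result.n_selected_per_fold):.1f} connections selected per fold)")
print(f"observed-vs-predicted Pearson r = {result.pearson_r:.3f}, permutation p = {p:.4f}")

lobe_map = {r: "anterior" if r <= 5 else "posterior" for r in range(1, 11)}
lobes = summarize_weights(result.mean_weights, lobe_map)
print("aggregate |weight| by region group:")
for lobe, w in sorted(lobes.items(), key=lambda kv: -kv[1]):
    print(f"  {lobe:10s} {w:.2f}")

# A significant permutation p means the survival signal carried by the
# selected connections generalizes across left-out patients; the group
# weights show which part of the network drives the prediction.
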