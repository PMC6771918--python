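"""Score new samples with a trained model and compare against the truth.

Trains on one synthetic cohort, then predicts fetal fractions for 10 fresh
pregnancies drawn from the same world (different sampling seed) and prints
the three per-sample estimates next to the simulated ground truth.
"""

import numpy as np

from fetalfrac.predictor import TrainConfig
from fetalfrac.simulate import SimulationParams, simulate_cohort
from fetalfrac.workflows import default_reference, predict_table, train_pipeline

params = SimulationParams(n_samples=300, seed=7)
cohort = simulate_cohort(params)
model = train_pipeline(cohort.profiles, default_reference(params),
                       TrainConfig(n_components=30, regressor="OLM", seed=1))

fresh = simulate_cohort(SimulationParams(n_samples=10, seed=99, world_seed=7))
table = predict_table(model, fresh.profiles)
truth = fresh.truth.set_index("sample_id")

print(f"{'sample':8} {'sex':8} {'true FF':>8} {'FF_pred':>8} "
      f"{'FFY':>8} {'FFX':>8}")
for _, row in table.iterrows():
    t = truth.loc[row["sample_id"]]
    print(f"{row['sample_id']:8} {t['sex']:8} {t['true_ff']:8.3f} "
          f"{row['ff_pred']:8.3f} {row['ffy']:8.3f} {row['ffx']:8.3f}")

err = table.set_index("sample_id")["ff_pred"] - truth["true_ff"]
print(f"\nmean absolute error vs truth: {np.abs(err).mean():.4f}")
print()
print("FF_pred comes from the autosomal PCA+regressor model and works for")
print("any fetal sex; FFY (chrY read counts) and FFX (chrX dosage) are only")
print("informative for male fetuses - for females both sit near zero while")
print("FF_pred still recovers the true fetal fraction.")
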