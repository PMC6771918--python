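"""Classify twin-pregnancy fetal sexes from the FFY / FF ratio.

In a twin pregnancy chromosome-Y reads reflect only the male fetus(es),
while the autosomal predictor sees the total fetal fraction, so FFY/FF is
~1 for two males, ~0 for two females and ~0.5 for a mixed pair.  A
three-component Gaussian mixture over the observed ratios yields cutoffs at
the local minima of the fitted density.
"""

import numpy as np

from fetalfrac.predictor import TrainConfig
from fetalfrac.screening import classify_twin_gender, fit_gmm_1d, gmm_cutoffs
from fetalfrac.simulate import SimulationParams, simulate_cohort
from fetalfrac.workflows import default_reference, predict_table, train_pipeline

params = SimulationParams(n_samples=300, seed=7)
cohort = simulate_cohort(params)
model = train_pipeline(cohort.profiles, default_reference(params),
                       TrainConfig(n_components=30, regressor="OLM", seed=1))

twins = simulate_cohort(SimulationParams(
    n_samples=240, seed=21, world_seed=7, ff_low=0.08, ff_high=0.20,
    twin_fraction=1.0, trisomy_rates={}, maternal_cnv_rate=0.0))
table = predict_table(model, twins.profiles)
ratio = (table["ffy"] / table["ff_pred"]).to_numpy()

mixture = fit_gmm_1d(ratio, k=3, seed=0)
cutoffs = gmm_cutoffs(mixture)
print("mixture component means:", np.round(mixture.means, 3))
print("density-minimum cutoffs:", np.round(cutoffs, 3))

label_of = {"XX/XX": "female_female", "XY/XX": "mixed", "XX/XY": "mixed",
            "XY/XY": "male_male"}
truth = twins.truth.set_index("sample_id")["karyotype"].map(label_of)
calls = [classify_twin_gender(r, cutoffs) for r in ratio]
acc = np.mean([c == t for c, t in zip(calls, truth)])
print(f"classification accuracy vs simulated truth: {acc:.1%} "
      f"(n = {len(ratio)})")
print()
print("The three mixture peaks sit near the theoretical ratios 0, 0.5 and 1;")
print("cutoffs near 1/4 and 3/4 separate the classes. Accuracy is high at")
print("FF >= 8% and degrades toward low fetal fractions, where the male-male")
print("and mixed clouds overlap.")
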