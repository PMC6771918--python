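# fetalfrac

Fetal fraction estimation from shallow whole-genome sequencing in
noninvasive prenatal testing (NIPT), for bioinformaticians running or
developing cfDNA screening pipelines.

In maternal plasma, cell-free DNA is a mixture of maternal and fetal
(placental) fragments; the *fetal fraction* (FF) governs the amplitude of
every fetal copy-number signal and therefore the reliability of an NIPT
call. `fetalfrac` implements a fetal-sex-independent FF predictor that
works from the binned copy-number profiles (100-kb log2 ratios of
observed/expected read counts) an sWGS pipeline already produces, trained
semi-supervised so that unlabeled female-fetus samples also contribute.

## The models

**FFY (chromosome Y).** For a male fetus, FF is proportional to the
read-depth-normalized chrY read abundance. A prior anchors each sample
between the median of male liquid biopsies (pure male genome, FFY = 1) and
the female NIPT background (FFY = 0):

    FFY_prior,male = (Y_NIPT - median(Y_NIPT,female)) / (median(Y_LB,male) - median(Y_NIPT,female))
    FFY_prior,female = 0

Because 5-kb chrY windows differ in male specificity (pseudoautosomal
sequence, mappability), a lasso-regularized linear model (λ = 1e-4) over
the per-bin counts refines this into the final FFY = β₀ + Σₖ βₖ yₖ,
down-weighting hypervariable, FF-unrelated bins. Final FFY values for
training samples are produced out-of-fold.

**The core predictor.** Autosomal bins (excluding chromosomes 13, 18 and
21, so fetal trisomies cannot pose as FF signal) feed a mean-centered PCA
fitted on *all* samples, labeled or not; the leading 50 components capture
the nonrandom, FF-linked variance. A regressor — by default a small
two-hidden-layer feed-forward network trained with Rprop+ (resilient
backpropagation with weight backtracking) under a sum-of-squared-errors
loss, or alternatively an ordinary linear model (OLM) — maps standardized
PC scores of labeled males to FFY, followed by an affine de-slanting
correction. Ten-fold cross-validation (refitting the entire pipeline per
fold) reports Pearson r and MAE, with the MAE of low-FF samples (< 10%)
shown separately.

**FFX (chromosome X).** A robust (Huber IRLS) line between the overall
chrX dosage ratio and FFY on males — robust so that (mosaic) maternal X
rearrangements cannot drag the fit — is inverted to score any sample:
at fetal fraction FF a male fetus depresses the chrX ratio to 1 − FF/2.

**Screens.** Downstream, the three estimates support: twin-gender
classification from FFY/FF (≈1 male–male, ≈0 female–female, ≈0.5 mixed)
with cutoffs at the local minima of a 3-component Gaussian mixture;
sex-aneuploidy screening via density1 = (FFY+FFX)/(2·FF) and
density2 = FFY−FFX with a 3-SD outlier rule after removing |FFX| > 40%
maternal excursions; and aberration-source checks comparing an observed
trisomy amplitude with its expectation log2(1 + FF/2).

A seed-deterministic synthetic-cohort generator (`fetalfrac.simulate`)
emulates the whole data model — Poisson read counts, an FF-proportional
autosomal signature, gonosomal dosage, twins, trisomies, sex aneuploidies,
maternal CNVs — so every stage is testable without clinical data.

## Worked example

```python
from fetalfrac.predictor import TrainConfig
from fetalfrac.simulate import SimulationParams, simulate_cohort
from fetalfrac.workflows import default_reference, predict_table, train_pipeline

params = SimulationParams(n_samples=300, seed=7)
cohort = simulate_cohort(params)
model = train_pipeline(cohort.profiles, default_reference(params),
                       TrainConfig(n_components=30, regressor="OLM", seed=1))
fresh = simulate_cohort(SimulationParams(n_samples=10, seed=99, world_seed=7))
print(predict_table(model, fresh.profiles))
```

which prints (abridged; `examples/predict_fetal_fraction.py` adds the truth
columns):

```
sample   sex       true FF  FF_pred      FFY      FFX
S00      male        0.086    0.104    0.088    0.091
S02      female      0.238    0.196   -0.002    0.011
S03      female      0.051    0.059   -0.003   -0.001
S05      male        0.212    0.189    0.211    0.215

mean absolute error vs truth: 0.0247
```

For male fetuses all three estimates agree; for females FFY and FFX sit at
their ~0 background while `FF_pred`, driven by the autosomal signature
alone, still recovers the simulated fetal fraction. The `examples/`
directory holds one short script per capability (training + CV, prediction,
twin-gender calling, sex-aneuploidy screening, aberration source).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
trains the pipeline on a synthetic cohort (800 samples; OLM regressor, the
configuration recommended for cohorts of this size) and scores three fresh
200-sample twin cohorts — male–male, female–female and mixed-sex with equal
fetal contributions — writing the mean per-sample FFY/FF ratio of each
class to the JSON file. Theoretical expectations for the three classes are
1, 0 and 0.5.
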