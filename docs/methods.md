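# Methods

This note records the statistical model behind `fetalfrac`, the defaults
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Problem setting

Shallow WGS of maternal plasma cfDNA (~0.1–1×) yields, per sample, binned
read counts normalized into log2 ratios of observed/expected reads at
100-kb resolution, plus raw read counts over 5-kb chromosome-Y windows.
The fetal fraction (FF) is the share of fragments of fetal (placental)
origin. The package provides three FF estimates and downstream screens:

* **FFY** — chrY read abundance, informative for male fetuses only;
* **FF_pred** — a fetal-sex-independent estimate from the autosomal
  profile, trained semi-supervised against FFY;
* **FFX** — the depressed chrX dosage of male-fetus pregnancies,
  calibrated against FFY.

## FFY

The prior interpolates a sample's mean normalized chrY abundance between
two anchors: the median over male liquid biopsies (a 100%-male-genome
reference, FFY = 1) and the median over female-fetus NIPT samples
(mismapping background, FFY = 0). Female priors are identically zero. The
final FFY is a lasso-regularized linear model over the per-bin counts with
the prior as response, fitted on both sexes — the females anchor the zero
class, which is what lets the fit discount bin-level background variation
that the prior itself absorbs.

Numerical conventions:

* the objective is ‖t − β₀ − Yβ‖² + λΣ|βₖ| with the intercept unpenalized,
  predictors standardized internally (λ acts on the standardized scale,
  default λ = 1e-4), and betas reported back on the count scale;
* λ = 0 falls back to an exact least-squares solve;
* constant predictor columns receive β = 0;
* final FFY is **unclipped**: slightly negative female values are
  calibration information, and downstream consumers decide;
* training samples receive **out-of-fold** final FFY values (10 fold
  models), so no sample is scored by a model that saw it. This matters:
  the prior is an exact linear function of the predictors, so an in-sample
  fit reproduces the prior's noise verbatim, while out-of-fold scoring
  suppresses the contribution of hypervariable uninformative bins. The
  held-out correlation of the final FFY with the true FF exceeds the
  prior's whenever such bins are present.
* "read-depth-normalized number of reads" is taken as reads-in-bin over
  total aligned reads.

## Core predictor

* **Features**: autosomal 100-kb bins excluding chromosomes 13, 18, 21
  (fetal trisomies would otherwise correlate with FF) and the gonosomes
  (they encode fetal sex, not FF). Bins missing in more than
  `max_bin_missing_rate` (default 5%) of training samples are dropped;
  remaining gaps are imputed with the bin's training mean, and those means
  are stored for predict-time imputation (an all-imputed chromosome
  therefore predicts identically to one set at the bin means).
* **Unsupervised phase**: mean-centered PCA over *all* samples, default 50
  components, features centered but not scaled (bins share the log2-ratio
  unit; per-bin variance is signal). Adding unlabeled samples can only
  increase the pooled variance captured by the leading components.
* **Supervised phase**: PC scores are z-standardized (training mean/SD,
  stored in the model), then regressed on FFY over labeled males. The
  default regressor is a feed-forward network with two logistic hidden
  layers (16, 8) and a linear output, trained full-batch by Rprop+ with
  weight backtracking (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δmax = 50,
  Δmin = 1e-6), SSE loss, stopping at max|∂SSE/∂w| < 1e-5 or 20 000
  epochs. A non-finite loss or weight counts as convergence failure,
  triggering up to 3 reseeded retries and then an OLM fallback with a
  prominent warning; exhausting the epoch budget with finite loss is
  treated as usable (the gradient tolerance is strict, and discarding such
  networks would make the fallback the de-facto default).
* **Bias correction**: an OLS line of FFY on the raw predictions de-slants
  the output; refitting on corrected predictions gives slope 1/intercept 0
  by construction.
* **Cross-validation**: labeled males are shuffled (seeded) into 10 folds;
  the *entire* pipeline — bin statistics, PCA (females plus non-held-out
  males), regressor, bias correction — is refit per fold. Reported: pooled
  Pearson r, MAE in percentage points, and the MAE over FFY < 10%.
  Undersized folds merge into a neighbor; a constant prediction vector
  reports r = NaN with a flag, never silently 0.
* **Persistence**: a zip archive holding a JSON config echo plus all
  arrays; loading verifies a grid checksum and rejects newer format
  versions. Training is bit-deterministic under (config, seed, inputs).

### NN versus OLM

On this package's synthetic cohorts the network *interpolates* its
training males (~1 000 weights against a few hundred samples) while the
OLM cannot, and which of the two generalizes better flips with cohort
size: at ~400 labeled males the OLM's held-out error (≈1.2 pp MAE against
truth) beats the NN's (≈2 pp), while at ≤100 labeled males the OLM is
variance-starved on 20–50 mostly-noise PCs and the NN wins in almost every
seeded replicate. Reports that linear models are the reliable choice on
small real cohorts likely reflect optimizer fragility in other toolchains
rather than a property this implementation reproduces. Consequence: the
NN remains the package default, but the acceptance script and the
twin-ratio analyses train with `regressor="OLM"`, the better-calibrated
configuration at the cohort sizes used there — the FFY/FF ratio has a
noisy denominator, and regressor noise inflates its per-sample mean.

## FFX

The overall chrX ratio is the unweighted mean of per-bin linear dosages
2^(log2 ratio) over non-missing chrX bins (the alternative — exponentiating
a mean log2 — differs only at second order; the linear mean matches the
"observed/expected reads" reading). A Huber M-estimator line (tuning
constant 1.345, MAD scale re-estimated each iteration, tolerance 1e-10,
≤50 iterations) of FFY on the chrX ratio over males resists maternal X
events in either variable's tail; note that, like any Huber regression,
it does *not* resist a high-leverage outlier backed by only a handful of
inliers. FFX = intercept + slope·ratio is unclipped, because maternal X
events legitimately push it far outside [0, 1] and that excursion is the
downstream screening signal.

## Screens

* **Twin gender**: FFY/FF ratios (undefined below an FF floor of 0.01) are
  modeled by a 3-component 1-D Gaussian mixture (EM, tolerance 1e-8,
  ≤1 000 iterations, quantile initialization with seeded jitter, best of 5
  restarts, components sorted by mean; an sd below 1e-6 forces a restart).
  Class cutoffs are the local minima of the fitted density between
  adjacent means, found by bracketed scalar minimization; overlapping
  components fall back to the midpoint with a warning.
* **Sex aneuploidy**: per sample, density1 = (FFY+FFX)/(2·FF) and
  density2 = FFY−FFX (the cumulative-sum notation of the source material
  is read as defining the per-sample statistics whose empirical density is
  modeled). Samples with |FFX| > 0.40 are flagged and excluded from model
  fitting but retained in the output. A 3-component mixture on density1
  yields female-like / mixed / male-like bands; a single Gaussian on
  density2 defines gonosomal-trend outliers at 3 SD (mean and SD from the
  fitted Gaussian, not raw moments). Outputs are screening annotations,
  deliberately not karyotype calls. The screen refuses cohorts under 30
  samples (mixtures are unstable below that).
* **Aberration source**: a nonmosaic fetal trisomy shifts the affected
  chromosome's mean log2 ratio by log2(1 + FF/2); the inverse map
  2·(2^r − 1) turns an observed shift into an implied FF. Concordance
  within a tolerance (default 2 FF percentage points) suggests a fetal
  nonmosaic event; an implied FF below the prediction suggests confined
  placental mosaicism; a negative shift is incompatible with a duplication
  outright.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes:

* per-bin reads are Poisson around a length-proportional expectation
  (mean 3M ± 0.3M reads/sample), giving the Gaussian-limit log2-ratio
  noise of binomial counting (~0.047 at the default depth);
* a fixed, zero-mean latent *fetal signature* s perturbs autosomal
  dosages by FF·sᵢ. Its scale (0.05) was set by a design-time power
  calculation: the toy genome has ~3 000 autosomal bins versus ~26 000 in
  a real profile, and 0.05 restores a realistic end-to-end recovery
  (held-out MAE ≈ 1.2–1.5 pp, r ≈ 0.97);
* chrX dosage follows karyotype (1 − FF/2 per male fetus, etc.); chrY
  5-kb bins split into 30% informative windows with per-bin male-
  specificity weights (unit 8e-5 normalized counts at FF = 1) and
  uninformative windows at a 5e-7 background with lognormal (σ = 0.8)
  heavy tails. The Y background was calibrated once so female final FFY
  behaves like the real assay's (~95% of female samples within ±0.5%);
* optional trisomies 13/18/21 (+FF/2 dosage), twins (component FFs summing
  to the total, equal split by default), sex aneuploidies, and
  FF-independent maternal CNVs (±0.5 dosage over 10–50-bin segments);
* the latent structure is seeded by `world_seed` separately from the
  sampling seed, so cohorts drawn in the same "world" are scoreable by one
  trained model.

Not emulated: fragment-length or methylation signal, GC waves, sequencing
error, within-sample normalization artifacts, and any spatial correlation
of the fetal signature. A green end-to-end test therefore establishes that
the pipeline recovers FF when the nonuniform-coverage premise holds and
noise is counting-dominated — not that it survives every real-world
normalization artifact.

## Known limitations

* The Huber FFX fit has the usual zero leverage-breakdown of M-estimators
  (documented above and in the tests).
* The packaged GRCh38 chrY 5-kb grid has 11 446 bins
  (= ceil(57 227 415 / 5 000)); published bin counts for equivalent
  tilings differ by one depending on masking conventions. The grid is
  fully configurable.
* With ~200 Y bins in the toy world the λ = 1e-4 lasso penalty binds only
  weakly (per-bin contributions are ~50× larger than in an 11 446-bin
  genome), so FFY sparsity on toy cohorts is near zero; sparsity increases
  monotonically with λ as expected.
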