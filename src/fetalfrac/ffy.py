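"""Chromosome-Y fetal fraction (FFY).

For a male fetus the fetal fraction is linearly proportional to the
read-depth-normalized abundance of chrY reads.  A *prior* FFY places a
sample's mean chrY abundance between two anchors: the median of male
liquid-biopsy samples (pure male genome, FFY = 1) and the median of female
NIPT samples (background mismapping, FFY = 0)::

    prior_male = (y_mean - median_female) / (median_LB_male - median_female)
    prior_female = 0

Not all 5-kb chrY windows are equally male-specific (pseudoautosomal
sequence, repeats, mappability), so the *final* FFY refines the prior with a
lasso-regularized linear model over the per-bin normalized counts::

    final = beta0 + sum_k beta_k * y_k

The lasso down-weights hypervariable, FF-unrelated bins; only a sparse set of
informative bins receives nonzero weight.  FF values are fractions in [0, 1]
throughout the API and are deliberately left unclipped: slightly negative
female values carry calibration information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .errors import ModelError

DEFAULT_LAMBDA = 1e-4


@dataclass
class FFYReference:
    """Anchor medians for the FFY prior.

    ``lb_male_median`` is the median mean-chrY abundance over male liquid
    biopsies (fully male cfDNA, FFY = 1); ``nipt_female_median`` is the same
    statistic over female-fetus NIPT samples (FFY = 0).
    """

    lb_male_median: float
    nipt_female_median: float

    def __post_init__(self) -> None:
        if self.nipt_female_median < 0:
            raise ModelError("female background median must be non-negative")
        if self.lb_male_median <= self.nipt_female_median:
            raise ModelError(
                "degenerate FFY reference: liquid-biopsy male median must exceed "
                "the female background median"
            )


@dataclass
class FFYModel:
    """Fitted lasso model mapping per-bin chrY counts to a final FFY."""

    intercept: float
    betas: np.ndarray
    lam: float
    reference: FFYReference | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.betas.shape[0]

    @property
    def sparsity(self) -> float:
        """Fraction of bins with beta exactly zero."""
        return float(np.mean(self.betas == 0.0))


def mean_y_abundance(y_counts: np.ndarray) -> float:
    """Mean normalized read abundance over all chrY bins."""
    return float(np.mean(np.asarray(y_counts, dtype=float)))


def build_reference(
    lb_male_means: np.ndarray, nipt_female_means: np.ndarray
) -> FFYReference:
    """Build an :class:`FFYReference` from per-sample mean chrY abundances."""
    return FFYReference(
        lb_male_median=float(np.median(lb_male_means)),
        nipt_female_median=float(np.median(nipt_female_means)),
    )


def ffy_prior(mean_y: float, ref: FFYReference, sex: str) -> float:
    """Prior FFY for a sample: linear interpolation for males, 0 for females."""
    if sex not in {"male", "female"}:
        raise ModelError(f"ffy_prior needs a known fetal sex, got {sex!r}")
    if sex == "female":
        return 0.0
    return (mean_y - ref.nipt_female_median) / (
        ref.lb_male_median - ref.nipt_female_median
    )


def fit_ffy_model(
    y_matrix: np.ndarray,
    priors: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    reference: FFYReference | None = None,
    tol: float = 1e-8,
    max_iter: int = 50_000,
) -> FFYModel:
    """Fit the final-FFY lasso on per-bin normalized chrY counts.

    Minimizes ``||prior - beta0 - Y beta||^2 + lam * sum|beta|`` with the
    intercept unpenalized; predictors are standardized internally (lam acts on
    the standardized scale) and betas are returned on the original count
    scale.  Constant columns receive beta = 0.
    """
    Y = np.asarray(y_matrix, dtype=float)
    t = np.asarray(priors, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != t.shape[0]:
        raise ModelError("y_matrix and priors are not aligned")
    n, p = Y.shape
    if n < 2:
        raise ModelError(f"need at least 2 training samples, got {n}")
    if lam < 0:
        raise ModelError("lambda must be non-negative")
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    live = sd > 0
    betas = np.zeros(p)
    if not live.any():
        return FFYModel(float(t.mean()), betas, lam, reference)
    Ys = (Y[:, live] - mu[live]) / sd[live]
    if lam == 0.0:
        X1 = np.column_stack([np.ones(n), Ys])
        coef, *_ = np.linalg.lstsq(X1, t, rcond=None)
        b0s, bs = coef[0], coef[1:]
    else:
        # sklearn objective is (1/2n)||r||^2 + alpha*|b|; rescale to match ours
        model = Lasso(alpha=lam / (2 * n), fit_intercept=True, tol=tol,
                      max_iter=max_iter)
        with warnings.catch_warnings():
            # near-zero penalties leave a duality gap ~1e-9 past sklearn's
            # strict target; coefficients are converged far beyond need
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Ys, t)
        b0s, bs = float(model.intercept_), model.coef_
    betas[live] = bs / sd[live]
    intercept = float(b0s - np.sum(bs * mu[live] / sd[live]))
    return FFYModel(intercept, betas, lam, reference)


def ffy_final(model: FFYModel, y_vector: np.ndarray) -> float:
    """Final FFY ``beta0 + sum_k beta_k y_k`` (unclipped)."""
    y = np.asarray(y_vector, dtype=float)
    if y.shape != (model.n_bins,):
        raise ModelError(
            f"y vector length {y.shape} does not match model ({model.n_bins} bins)"
        )
    return float(model.intercept + model.betas @ y)


def fit_ffy_model_cv(
    y_matrix: np.ndarray,
    priors: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    k: int = 10,
    seed: int = 0,
    reference: FFYReference | None = None,
) -> tuple[FFYModel, np.ndarray]:
    """Fit the FFY lasso and produce out-of-fold final FFY values.

    Training several fold models ensures no sample's final FFY comes from a
    model that saw it.  Returns the full-data model (for scoring new samples)
    and the per-sample out-of-fold predictions.
    """
    Y = np.asarray(y_matrix, dtype=float)
    t = np.asarray(priors, dtype=float)
    n = Y.shape[0]
    if n < 2 * k:
        raise ModelError(f"{n} samples is too few for {k}-fold FFY CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    oof = np.empty(n)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        sub = fit_ffy_model(Y[train_mask], t[train_mask], lam)
        oof[test_idx] = sub.intercept + Y[test_idx] @ sub.betas
    return fit_ffy_model(Y, t, lam, reference), oof
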