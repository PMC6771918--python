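"""Downstream screens built on the three FF estimates (FFY, FFX, predicted FF).

Three independent FF readouts carry information beyond the fetal fraction
itself:

* **Twin gender** — in a twin pregnancy FFY reflects only the male
  fetus(es), while the autosomal predictor sees the total FF.  The ratio
  FFY / FF is therefore ~1 for male-male twins, ~0 for female-female twins
  and ~0.5 for mixed pairs with balanced contributions.  A three-component
  1-D Gaussian mixture over the observed ratios supplies data-driven
  cutoffs at the local minima of the fitted density.
* **Sex-aneuploidy trend** — per sample, ``density1 = (FFY + FFX) / (2 FF)``
  sharpens the gender separation, and ``density2 = FFY - FFX`` is ~0 for any
  euploid karyotype but shifts for X0/XXX/XXY/XYY-like dosages.  A single
  Gaussian fitted to density2 flags samples more than 3 SD from its mean as
  gonosomal-trend outliers.  Samples with |FFX| > 40% (maternal X events)
  are excluded from the fits but kept, flagged, in the output.
* **Aberration source** — a nonmosaic fetal trisomy shifts the affected
  chromosome's mean log2 ratio by ``log2(1 + FF/2)``; comparing the FF
  implied by an observed shift against the predicted FF suggests whether an
  aberration is fetal or rather (placental-)mosaic/maternal.

Flags here are screening annotations, not karyotype calls; experimental
confirmation is always warranted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import ModelError

FFX_PREFILTER = 0.40
OUTLIER_SD = 3.0
FF_FLOOR = 0.01


# ---------------------------------------------------------------------------
# 1-D Gaussian mixtures

@dataclass
class GaussianMixture1D:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.weights * norm.pdf(x[..., None], self.means, self.sds), axis=-1
        )


def fit_gmm_1d(
    values: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    sd_floor: float = 1e-6,
) -> GaussianMixture1D:
    """EM fit of a k-component 1-D Gaussian mixture.

    Components are initialized at the data quantiles with seeded jitter; the
    best of ``n_restarts`` runs (by log-likelihood) is kept, components are
    returned sorted by mean, and a component collapsing below ``sd_floor``
    forces a restart (persistent collapse is an error).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5 * k:
        raise ModelError(f"need >= {5 * k} values to fit a {k}-component mixture")
    rng = np.random.default_rng(seed)
    jitter_sd = 0.05 * (np.std(x) if np.std(x) > 0 else 1.0)
    best: GaussianMixture1D | None = None
    for restart in range(n_restarts):
        q = np.quantile(x, (np.arange(k) + 0.5) / k)
        means_init = (q + rng.normal(0.0, jitter_sd, size=k))[:, None]
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", tol=tol, max_iter=max_iter,
            means_init=means_init, reg_covar=1e-12,
            random_state=int(rng.integers(2**31)), n_init=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x[:, None])
        sds = np.sqrt(gm.covariances_.ravel())
        if np.min(sds) < sd_floor:
            continue  # collapsed component; try again with new jitter
        cand = GaussianMixture1D(
            weights=gm.weights_.ravel(), means=gm.means_.ravel(), sds=sds,
            loglik=float(gm.score(x[:, None]) * x.size),
        )
        if best is None or cand.loglik > best.loglik:
            best = cand
    if best is None:
        raise ModelError("Gaussian mixture fit collapsed in every restart")
    order = np.argsort(best.means)
    return GaussianMixture1D(best.weights[order], best.means[order],
                             best.sds[order], best.loglik)


def gmm_cutoffs(mixture: GaussianMixture1D) -> np.ndarray:
    """Cutoffs between adjacent components: local minima of the mixture pdf.

    Between each pair of adjacent component means the density is minimized by
    bracketed 1-D search; when no interior minimum exists (heavily
    overlapping components) the midpoint of the means is used with a warning.
    """
    if mixture.k < 2:
        raise ModelError("cutoffs need at least 2 components")
    cuts = []
    for lo, hi in zip(mixture.means[:-1], mixture.means[1:]):
        if hi - lo <= 0:
            cuts.append(float(lo))
            continue
        res = minimize_scalar(lambda v: float(mixture.pdf(np.array(v))),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        span = hi - lo
        x = float(res.x)
        if x - lo < 1e-6 * span or hi - x < 1e-6 * span:
            warnings.warn("no interior density minimum; using midpoint of means")
            x = float((lo + hi) / 2)
        cuts.append(x)
    return np.array(cuts)


# ---------------------------------------------------------------------------
# twin gender

def twin_ratio(ffy: float, ff_pred: float, floor: float = FF_FLOOR) -> float:
    """FFY over predicted total FF; NaN (undefined) when FF is at/below floor."""
    if ff_pred <= floor:
        return float("nan")
    return float(ffy / ff_pred)


def classify_twin_gender(ratio: float, cutoffs: np.ndarray) -> str:
    """Map a FFY/FF ratio to {female_female, mixed, male_male} via 2 cutoffs."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.shape != (2,) or cutoffs[0] >= cutoffs[1]:
        raise ModelError("need two ascending cutoffs")
    if np.isnan(ratio):
        return "undetermined"
    if ratio < cutoffs[0]:
        return "female_female"
    if ratio < cutoffs[1]:
        return "mixed"
    return "male_male"


# ---------------------------------------------------------------------------
# sex-aneuploidy screen

@dataclass
class ScreenResult:
    """Cohort screen output: per-sample table plus the fitted density models."""

    table: pd.DataFrame
    density1_mixture: GaussianMixture1D
    density1_cutoffs: np.ndarray
    density2_mean: float
    density2_sd: float


def sex_aneuploidy_screen(
    stats: pd.DataFrame,
    seed: int = 0,
    prefilter: float = FFX_PREFILTER,
    sd_mult: float = OUTLIER_SD,
    min_samples: int = 30,
) -> ScreenResult:
    """Annotate a cohort with gender classes and gonosomal-trend outliers.

    ``stats`` needs columns ``sample_id``, ``ffy``, ``ffx``, ``ff_pred``
    (fractions).  Samples with |FFX| above ``prefilter`` are excluded from
    model fitting but flagged and retained.  density1 drives a 3-component
    mixture (female / mixed-twin / male bands); density2 drives a single
    Gaussian whose ``sd_mult``-SD band defines outliers.
    """
    required = {"sample_id", "ffy", "ffx", "ff_pred"}
    if not required.issubset(stats.columns):
        raise ModelError(f"screen input needs columns {sorted(required)}")
    if len(stats) < min_samples:
        raise ModelError(
            f"sex-aneuploidy screen needs >= {min_samples} samples "
            f"(mixture fits are unstable below that), got {len(stats)}"
        )
    df = stats.copy().reset_index(drop=True)
    ffy = df["ffy"].to_numpy(dtype=float)
    ffx = df["ffx"].to_numpy(dtype=float)
    ff = df["ff_pred"].to_numpy(dtype=float)
    df["twin_ratio"] = [twin_ratio(a, b) for a, b in zip(ffy, ff)]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["density1"] = np.where(np.abs(ff) > 0, (ffy + ffx) / (2 * ff), np.nan)
    df["density2"] = ffy - ffx
    df["prefilter_flag"] = np.abs(ffx) > prefilter
    fit_mask = (~df["prefilter_flag"]) & np.isfinite(df["density1"])
    mixture = fit_gmm_1d(df.loc[fit_mask, "density1"].to_numpy(), k=3, seed=seed)
    cutoffs = gmm_cutoffs(mixture)
    d2 = df.loc[~df["prefilter_flag"], "density2"].to_numpy()
    g1 = fit_gmm_1d(d2, k=1, seed=seed)
    d2_mean, d2_sd = float(g1.means[0]), float(g1.sds[0])
    labels = ("female_like", "mixed", "male_like")
    df["gender_class"] = [
        "undetermined" if not np.isfinite(v)
        else labels[int(np.searchsorted(cutoffs, v))]
        for v in df["density1"]
    ]
    df["outlier_flag"] = np.abs(df["density2"] - d2_mean) > sd_mult * d2_sd
    return ScreenResult(df, mixture, cutoffs, d2_mean, d2_sd)


# ---------------------------------------------------------------------------
# aberration source

@dataclass
class AberrationCheck:
    chrom: str
    observed_mean_log2: float
    expected_log2: float
    expected_ff_from_event: float
    concordant: bool
    reason: str = ""


def expected_log2_for_trisomy(ff: float) -> float:
    """Mean log2 shift of a nonmosaic fetal trisomy at fetal fraction ff."""
    if not 0.0 <= ff <= 1.0:
        raise ModelError(f"fetal fraction out of range: {ff}")
    return float(np.log2(1.0 + ff / 2.0))


def expected_ff_from_log2(r: float) -> float:
    """Inverse of :func:`expected_log2_for_trisomy`: ``2*(2**r - 1)``."""
    dosage = 2.0 ** r
    if dosage <= 0.5:  # would imply a negative maternal background
        raise ModelError(f"log2 shift {r} is outside the trisomy dosage model")
    return float(2.0 * (dosage - 1.0))


def aberration_source_check(
    chrom: str,
    observed_mean_log2: float,
    ff_pred: float,
    tolerance: float = 0.02,
) -> AberrationCheck:
    """Compare the FF implied by an observed duplication with the predicted FF.

    Concordance (|implied FF - predicted FF| <= tolerance, on the FF scale)
    supports a fetal, nonmosaic event; an implied FF well below the predicted
    FF is the signature of a (confined placental) mosaic; a negative shift is
    incompatible with a duplication outright.
    """
    if tolerance <= 0:
        raise ModelError("tolerance must be positive")
    expected = expected_log2_for_trisomy(min(max(ff_pred, 0.0), 1.0))
    if observed_mean_log2 < 0:
        return AberrationCheck(chrom, observed_mean_log2, expected, 0.0,
                               concordant=False, reason="negative_shift")
    implied = expected_ff_from_log2(observed_mean_log2)
    ok = abs(implied - ff_pred) <= tolerance
    reason = "" if ok else (
        "mosaicism_like" if implied < ff_pred else "amplitude_above_ff"
    )
    return AberrationCheck(chrom, observed_mean_log2, expected, implied,
                           concordant=ok, reason=reason)
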