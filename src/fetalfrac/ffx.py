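"""Chromosome-X fetal fraction (FFX).

A male fetus carries a single X, so its cfDNA depresses the overall chrX
dosage of the maternal plasma sample: at fetal fraction FF the expected
observed/expected chrX ratio is 1 - FF/2.  Fitting a line between the chrX
ratio and FFY across male-fetus samples therefore yields a second,
X-chromosome-based FF estimate for any sample.

The fit must shrug off (mosaic) (sub)chromosomal maternal X rearrangements,
which shift the chrX ratio by amounts unrelated to FF, so a robust
M-estimator (Huber IRLS, MAD scale) is used instead of ordinary least
squares.  FFX is left unclipped: maternal X events can push it far outside
[0, 1], and that excursion is itself the downstream screening signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError
from .profiles import CopyNumberProfile

HUBER_T = 1.345  # 95% Gaussian efficiency tuning constant
MAD_NORMAL = 0.6744897501960817  # Phi^-1(3/4)


@dataclass
class FFXModel:
    """Robust line ffy ~ intercept + slope * chrX_ratio fitted on males."""

    slope: float
    intercept: float
    robust_scale: float
    n_train: int


def chrx_overall_ratio(profile: CopyNumberProfile) -> float:
    """Overall chrX observed/expected ratio: mean per-bin linear dosage.

    Each non-missing chrX bin contributes ``2**log2_ratio``; missing bins are
    excluded.
    """
    mask = profile.grid.chrom_mask({"X"}) & ~profile.missing
    if not mask.any():
        raise ModelError(f"profile {profile.sample_id!r}: all chrX bins missing")
    return float(np.mean(2.0 ** profile.log2_ratio[mask]))


def huber_irls(
    x: np.ndarray,
    y: np.ndarray,
    t: float = HUBER_T,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Huber M-estimation of ``y ~ a + b x`` by IRLS.

    The scale is the MAD of the residuals (about zero, normal-consistent),
    re-estimated at every iteration; weights are ``min(1, t*scale/|r|)``.
    Returns (intercept, slope, final scale).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale = 0.0
    for _ in range(max_iter):
        resid = y - X @ coef
        scale = float(np.median(np.abs(resid)) / MAD_NORMAL)
        if scale <= 0:
            break  # exact fit
        w = np.minimum(1.0, t * scale / np.maximum(np.abs(resid), 1e-300))
        sw = np.sqrt(w)
        new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(new - coef)) < tol:
            coef = new
            break
        coef = new
    return float(coef[0]), float(coef[1]), scale


def fit_ffx(x_ratios: np.ndarray, ffy: np.ndarray, min_samples: int = 10) -> FFXModel:
    """Fit the robust FFX line on male samples.

    Parameters
    ----------
    x_ratios
        Per-sample overall chrX ratios (males only).
    ffy
        Matching final FFY values.
    """
    x = np.asarray(x_ratios, dtype=float)
    y = np.asarray(ffy, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ModelError("x_ratios and ffy are not aligned 1-D arrays")
    if x.shape[0] < min_samples:
        raise ModelError(
            f"robust FFX fit needs >= {min_samples} male samples, got {x.shape[0]}"
        )
    if np.ptp(x) == 0:
        raise ModelError("degenerate FFX fit: constant chrX ratios")
    intercept, slope, scale = huber_irls(x, y)
    return FFXModel(slope=slope, intercept=intercept, robust_scale=scale,
                    n_train=int(x.shape[0]))


def ffx(model: FFXModel, x_ratio: float) -> float:
    """Evaluate the fitted line at a chrX ratio (unclipped)."""
    return float(model.intercept + model.slope * x_ratio)
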