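"""High-level entry points: train / predict / screen / simulate.

These functions are the package's operational surface (there is no shell
CLI): each one composes the lower-level modules into the standard run —
train a model from a cohort, score profiles into a table, screen a scored
cohort, or materialize a synthetic cohort as files.  TSV outputs report FF
values in percent with 4 decimals; the API itself stays fractional.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .errors import ModelError
from .ffy import (DEFAULT_LAMBDA, FFYReference, build_reference, ffy_final,
                  ffy_prior, fit_ffy_model, fit_ffy_model_cv, mean_y_abundance)
from .predictor import (CVReport, FetalFractionModel, TrainConfig,
                        cross_validate, fit_ff_model, predict_ff, save_model)
from .profiles import (CohortManifest, CopyNumberProfile, read_profile,
                       read_y_counts, write_manifest, write_profile,
                       write_y_counts)
from .screening import ScreenResult, sex_aneuploidy_screen
from .simulate import (SimulatedCohort, SimulationParams, simulate_cohort,
                       simulate_reference_sets)

__all__ = [
    "train_pipeline", "predict_table", "screen_cohort", "simulate_to_dir",
    "load_cohort", "write_percent_tsv",
]


def compute_ffy_targets(
    profiles: list[CopyNumberProfile],
    reference: FFYReference,
    lam: float = DEFAULT_LAMBDA,
    cv_folds: int | None = 10,
    seed: int = 0,
):
    """Fit the FFY lasso on all sex-labeled samples and score everyone.

    Returns ``(ffy_model, finals)`` where ``finals`` maps sample_id to the
    final FFY for every profile that carries Y counts.  Both sexes enter the
    fit (females anchor the zero class); unknown-sex profiles are scored but
    not fitted on.  With ``cv_folds`` set, the labeled samples' own final
    FFY values come from out-of-fold models (no sample is scored by a model
    that saw it); new/unlabeled samples always use the full-data model.
    """
    labeled = [p for p in profiles
               if p.sex_label in {"male", "female"} and p.y_counts is not None]
    if sum(p.sex_label == "male" for p in labeled) < 2 or \
       sum(p.sex_label == "female" for p in labeled) < 2:
        raise ModelError("FFY fitting needs >= 2 samples of each sex")
    y_matrix = np.vstack([p.y_counts for p in labeled])
    priors = np.array([
        ffy_prior(mean_y_abundance(p.y_counts), reference, p.sex_label)
        for p in labeled
    ])
    if cv_folds is not None and len(labeled) >= 2 * cv_folds:
        model, oof = fit_ffy_model_cv(y_matrix, priors, lam, k=cv_folds,
                                      seed=seed, reference=reference)
        finals = {p.sample_id: float(v) for p, v in zip(labeled, oof)}
    else:
        model = fit_ffy_model(y_matrix, priors, lam, reference=reference)
        finals = {}
    for p in profiles:
        if p.y_counts is not None and p.sample_id not in finals:
            finals[p.sample_id] = ffy_final(model, p.y_counts)
    return model, finals


def train_pipeline(
    profiles: list[CopyNumberProfile],
    reference: FFYReference,
    config: TrainConfig | None = None,
    lam: float = DEFAULT_LAMBDA,
    with_cv: bool = False,
) -> FetalFractionModel:
    """Train the full stack: FFY lasso -> PCA + regressor -> FFX line.

    Male-fetus samples supply the supervised targets (their final FFY);
    female and unknown-sex samples join the unsupervised phase.  With
    ``with_cv`` a K-fold cross-validation report is attached to the model.
    """
    config = config or TrainConfig()
    ffy_model, finals = compute_ffy_targets(profiles, reference, lam,
                                            seed=config.seed)
    targets = {p.sample_id: finals[p.sample_id]
               for p in profiles
               if p.sex_label == "male" and p.sample_id in finals}
    if not targets:
        raise ModelError("no male samples with Y counts to train on")
    y_grid = next(p.y_grid for p in profiles if p.y_counts is not None)
    model = fit_ff_model(profiles, targets, config,
                         ffy_model=ffy_model, y_grid=y_grid)
    if with_cv:
        model.cv_report = cross_validate(profiles, targets, config)
    return model


def predict_table(
    model: FetalFractionModel, profiles: list[CopyNumberProfile]
) -> pd.DataFrame:
    """Score profiles into one row each (fractions; order preserved)."""
    rows = []
    for p in profiles:
        res = predict_ff(model, p)
        rows.append({
            "sample_id": p.sample_id, "ff_pred": res.ff, "ffx": res.ffx,
            "ffy": res.ffy, "n_imputed": res.n_imputed,
            "missing_fraction": res.missing_fraction,
            "low_quality": res.low_quality,
        })
    return pd.DataFrame(rows)


def write_percent_tsv(table: pd.DataFrame, path) -> None:
    """Write a prediction/screen table with FF columns rendered as percent."""
    out = table.copy()
    for col in ("ff_pred", "ffx", "ffy", "density2"):
        if col in out.columns:
            out[col] = (out[col].astype(float) * 100).map(
                lambda v: f"{v:.4f}" if np.isfinite(v) else "NaN")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def screen_cohort(
    model: FetalFractionModel,
    profiles: list[CopyNumberProfile],
    seed: int = 0,
) -> ScreenResult:
    """Predict FF/FFX/FFY for a cohort and run the sex-aneuploidy screen."""
    table = predict_table(model, profiles)
    if table["ffy"].isna().any():
        raise ModelError("screening needs Y counts (FFY) for every sample")
    stats = table.rename(columns={})[["sample_id", "ffy", "ffx", "ff_pred"]]
    return sex_aneuploidy_screen(stats, seed=seed)


def load_cohort(manifest: CohortManifest, grid, y_grid=None,
                base_dir: str | None = None) -> list[CopyNumberProfile]:
    """Read every manifest record into a profile (plus Y counts if listed)."""
    profiles = []
    for rec in manifest.records:
        path = rec.path if base_dir is None else os.path.join(base_dir, rec.path)
        prof = read_profile(path, grid, sample_id=rec.sample_id)
        prof.sex_label = rec.sex
        if rec.y_path:
            ypath = (rec.y_path if base_dir is None
                     else os.path.join(base_dir, rec.y_path))
            if y_grid is None:
                raise ModelError("manifest lists Y counts but no y_grid was given")
            prof.y_counts = read_y_counts(ypath, y_grid)
            prof.y_grid = y_grid
        profiles.append(prof)
    return profiles


def simulate_to_dir(params: SimulationParams, outdir) -> SimulatedCohort:
    """Materialize a synthetic cohort as the on-disk formats the pipeline reads.

    Writes per-sample profile and Y-count TSVs, ``manifest.csv``,
    ``truth.tsv`` and a ``params.json`` echo into ``outdir``.
    """
    cohort = simulate_cohort(params)
    os.makedirs(outdir, exist_ok=True)
    ppaths, ypaths = {}, {}
    for s in cohort.samples:
        ppath = os.path.join(outdir, f"{s.sample_id}.profile.tsv")
        ypath = os.path.join(outdir, f"{s.sample_id}.ycounts.tsv")
        write_profile(s.profile, ppath)
        write_y_counts(s.profile.y_counts, s.profile.y_grid, ypath)
        ppaths[s.sample_id] = ppath
        ypaths[s.sample_id] = ypath
    write_manifest(cohort.manifest(ppaths, ypaths),
                   os.path.join(outdir, "manifest.csv"))
    cohort.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False,
                        lineterminator="\n")
    echo = asdict(params)
    echo["grid"] = None if params.grid is None else "custom"
    echo["y_grid"] = None if params.y_grid is None else "custom"
    with open(os.path.join(outdir, "params.json"), "w") as fh:
        json.dump(echo, fh, indent=1)
    return cohort


def default_reference(
    params: SimulationParams, n_lb_males: int = 20, n_females: int = 50,
    seed: int | None = None,
) -> FFYReference:
    """FFY reference from simulated liquid-biopsy males + NIPT females."""
    lb, fem = simulate_reference_sets(params, n_lb_males, n_females, seed=seed)
    return build_reference(lb, fem)
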