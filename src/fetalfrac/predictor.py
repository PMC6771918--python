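"""Semi-supervised fetal-fraction prediction from autosomal copy-number bins.

The core model exploits the fact that fetal (placental) and maternal cfDNA
fragments are not uniformly distributed over the genome: small, reproducible
differences in local bin-wise read depth scale with the fetal fraction.  The
pipeline is semi-supervised:

1. *Unsupervised phase* — all samples, including unlabeled female-fetus
   samples, contribute to a PCA over autosomal bin log2 ratios.  The leading
   components capture the non-random (FF-linked) variance; trailing ones are
   dominated by the Gaussian noise that binomial read counting induces.
   Bins on chromosomes 13, 18 and 21 are excluded so that fetal trisomies
   cannot masquerade as FF signal; gonosomes are excluded because their
   dosage separates the sexes rather than the fetal fraction.
2. *Supervised phase* — samples with a known FFY (male fetuses) train a
   regressor from standardized PC scores to FFY: by default a small
   two-hidden-layer network fitted with Rprop+ and an SSE loss, with an
   ordinary linear model (OLM) as alternative/fallback.  A final affine
   correction undoes the slight slant between predictions and FFY that
   least-squares-style training leaves behind.

Model quality is reported through K-fold cross-validation in which held-out
males are excluded from *every* stage (bin statistics, PCA, regressor, bias
correction) of their fold's refit.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.decomposition import PCA

from .errors import ModelError
from .ffx import FFXModel, chrx_overall_ratio, ffx as ffx_eval, fit_ffx
from .ffy import FFYModel, FFYReference, ffy_final
from .grids import BinGrid
from .nn import FitResult, RpropConfig, RpropNetwork
from .profiles import CopyNumberProfile

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Tunable knobs of the training pipeline (defaults follow the method)."""

    n_components: int = 50
    regressor: str = "NN"  # or "OLM"
    hidden_sizes: tuple[int, int] = (16, 8)
    cv_folds: int = 10
    excluded_chromosomes: tuple[str, ...] = ("13", "18", "21", "X", "Y")
    max_bin_missing_rate: float = 0.05
    seed: int = 0
    nn_retries: int = 3
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_max: float = 50.0
    grad_tol: float = 1e-5
    max_epochs: int = 20_000
    use_unlabeled_in_pca: bool = True
    max_missing_fraction: float = 0.2  # predict-time QC ceiling

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ModelError("n_components must be >= 1")
        if self.cv_folds < 2:
            raise ModelError("cv_folds must be >= 2")
        if self.regressor not in {"NN", "OLM"}:
            raise ModelError(f"unknown regressor {self.regressor!r}")
        self.hidden_sizes = tuple(self.hidden_sizes)
        self.excluded_chromosomes = tuple(self.excluded_chromosomes)

    def rprop(self) -> RpropConfig:
        return RpropConfig(
            eta_plus=self.eta_plus, eta_minus=self.eta_minus, delta0=self.delta0,
            delta_max=self.delta_max, grad_tol=self.grad_tol,
            max_epochs=self.max_epochs,
        )


@dataclass
class RegressorState:
    """Fitted regressor: NN weight arrays or OLM coefficients."""

    kind: str  # "NN" or "OLM"
    hidden_sizes: tuple[int, int] | None = None
    arrays: dict[str, np.ndarray] = field(default_factory=dict)
    fell_back: bool = False

    def predict(self, scores: np.ndarray) -> np.ndarray:
        S = np.atleast_2d(np.asarray(scores, dtype=float))
        if self.kind == "OLM":
            coef = self.arrays["coef"]
            return coef[0] + S @ coef[1:]
        net = RpropNetwork.from_state(S.shape[1], self.hidden_sizes, self.arrays)
        return net.forward(S)


@dataclass
class CVReport:
    pearson_r: float
    mae: float  # percentage points
    mae_low_ff: float  # percentage points, samples with FFY < 10%
    folds: list[dict] = field(default_factory=list)
    constant_prediction: bool = False


@dataclass
class FetalFractionModel:
    """Serialized pipeline state sufficient to score new profiles."""

    grid: BinGrid
    feature_bins: np.ndarray  # grid indices of retained autosomal bins
    bin_means: np.ndarray  # per-feature training means (imputation values)
    rotations: np.ndarray  # features x n_components, orthonormal
    explained_variance: np.ndarray
    pc_center: np.ndarray
    pc_scale: np.ndarray
    regressor_state: RegressorState
    correction: tuple[float, float]  # (a, b): corrected = a + b * raw
    config: TrainConfig
    ffy_model: FFYModel | None = None
    y_grid: BinGrid | None = None
    ffx_model: FFXModel | None = None
    cv_report: CVReport | None = None
    version: int = MODEL_FORMAT_VERSION


@dataclass
class PredictionResult:
    ff: float
    ffx: float | None
    ffy: float | None
    n_imputed: int
    missing_fraction: float
    low_quality: bool


# ---------------------------------------------------------------------------
# feature assembly and PCA

def assemble_features(
    profiles: list[CopyNumberProfile], config: TrainConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the training feature matrix from a cohort of profiles.

    Returns ``(X, feature_bins, bin_means)``: columns are autosomal grid bins
    off the excluded chromosomes whose cohort missing-rate is at most
    ``config.max_bin_missing_rate``; remaining missing cells are imputed with
    the bin's mean over observed samples, and those means are recorded for
    predict-time imputation.
    """
    if not profiles:
        raise ModelError("no profiles given")
    grid = profiles[0].grid
    ref_sum = grid.checksum()
    for p in profiles[1:]:
        if p.grid.checksum() != ref_sum:
            raise ModelError(f"profile {p.sample_id!r} is on a different grid")
    raw = np.vstack([p.log2_ratio for p in profiles])
    keep = ~grid.chrom_mask(set(config.excluded_chromosomes))
    missing_rate = np.mean(np.isnan(raw), axis=0)
    keep &= missing_rate <= config.max_bin_missing_rate
    feature_bins = np.flatnonzero(keep)
    if feature_bins.size == 0:
        raise ModelError("no bins survive the feature filters")
    X = raw[:, feature_bins]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bin_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = bin_means[nan_c]
    return X, feature_bins, bin_means


def fit_pca(X: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA.  Returns (rotations [p x k], explained variances)."""
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ModelError(
            f"n_components={n_components} exceeds min(n_samples, n_features)="
            f"{min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return pca.components_.T.copy(), pca.explained_variance_.copy()


def project(model: FetalFractionModel, feature_vector: np.ndarray) -> np.ndarray:
    """Standardized PC scores of an (already imputed) feature vector."""
    x = np.asarray(feature_vector, dtype=float)
    if x.shape[-1] != model.bin_means.shape[0]:
        raise ModelError("feature vector does not match the model's feature index")
    raw = (x - model.bin_means) @ model.rotations
    return (raw - model.pc_center) / model.pc_scale


# ---------------------------------------------------------------------------
# supervised phase

def _fit_olm(scores: np.ndarray, ffy: np.ndarray) -> RegressorState:
    n, k = scores.shape
    if n < k + 2:
        raise ModelError(f"OLM needs >= n_components+2 samples ({k + 2}), got {n}")
    X1 = np.column_stack([np.ones(n), scores])
    coef, *_ = np.linalg.lstsq(X1, ffy, rcond=None)
    return RegressorState(kind="OLM", arrays={"coef": coef})


def train_regressor(
    scores: np.ndarray, ffy: np.ndarray, config: TrainConfig
) -> RegressorState:
    """Fit the supervised regressor on standardized PC scores.

    For the NN, a non-finite loss counts as a convergence failure; the fit is
    retried with an incremented seed up to ``config.nn_retries`` times and
    then falls back to the OLM with a prominent warning.
    """
    scores = np.asarray(scores, dtype=float)
    ffy = np.asarray(ffy, dtype=float)
    if config.regressor == "OLM":
        return _fit_olm(scores, ffy)
    if scores.shape[0] < 10:
        raise ModelError("NN training needs at least 10 labeled samples")
    result: FitResult | None = None
    for attempt in range(config.nn_retries + 1):
        net = RpropNetwork(scores.shape[1], config.hidden_sizes,
                           seed=config.seed + attempt)
        result = net.fit(scores, ffy, config.rprop())
        if not result.failed:
            return RegressorState(kind="NN", hidden_sizes=config.hidden_sizes,
                                  arrays=net.state())
    warnings.warn(
        "NN training failed to converge after "
        f"{config.nn_retries + 1} attempts; falling back to the OLM regressor"
    )
    state = _fit_olm(scores, ffy)
    state.fell_back = True
    return state


def fit_bias_correction(
    predictions: np.ndarray, ffy: np.ndarray
) -> tuple[float, float]:
    """Affine de-slanting: least-squares line ffy ~ a + b*pred.

    The corrected prediction is ``a + b*pred``; refitting ffy on corrected
    predictions then gives slope 1 / intercept 0 by construction.
    """
    pred = np.asarray(predictions, dtype=float)
    t = np.asarray(ffy, dtype=float)
    if pred.size < 3:
        raise ModelError("bias correction needs at least 3 points")
    if np.ptp(pred) == 0:
        warnings.warn("constant predictions; bias correction is the identity")
        return 0.0, 1.0
    X1 = np.column_stack([np.ones(pred.size), pred])
    (a, b), *_ = np.linalg.lstsq(X1, t, rcond=None)
    return float(a), float(b)


# ---------------------------------------------------------------------------
# full pipeline

def fit_ff_model(
    profiles: list[CopyNumberProfile],
    ffy_targets: dict[str, float],
    config: TrainConfig | None = None,
    ffy_model: FFYModel | None = None,
    y_grid: BinGrid | None = None,
    fit_ffx_submodel: bool = True,
) -> FetalFractionModel:
    """Train the full pipeline.

    ``ffy_targets`` maps sample ids (labeled, male-fetus samples) to their
    final FFY; every other profile participates only in the unsupervised
    phase (unless ``config.use_unlabeled_in_pca`` is off, in which case the
    unlabeled profiles are ignored entirely).
    """
    config = config or TrainConfig()
    labeled = [p for p in profiles if p.sample_id in ffy_targets]
    if len(labeled) < 2:
        raise ModelError(f"need >= 2 labeled samples, got {len(labeled)}")
    pool = profiles if config.use_unlabeled_in_pca else labeled
    X, feature_bins, bin_means = assemble_features(pool, config)
    rotations, evar = fit_pca(X, config.n_components)
    raw_scores = (X - bin_means) @ rotations
    pc_center = raw_scores.mean(axis=0)
    pc_scale = raw_scores.std(axis=0)
    pc_scale[pc_scale == 0] = 1.0
    model = FetalFractionModel(
        grid=labeled[0].grid, feature_bins=feature_bins, bin_means=bin_means,
        rotations=rotations, explained_variance=evar, pc_center=pc_center,
        pc_scale=pc_scale,
        regressor_state=RegressorState(kind="OLM"),  # placeholder
        correction=(0.0, 1.0), config=config, ffy_model=ffy_model, y_grid=y_grid,
    )
    idx = {p.sample_id: i for i, p in enumerate(pool)}
    lab_rows = np.array([idx[p.sample_id] for p in labeled])
    lab_scores = ((X[lab_rows] - bin_means) @ rotations - pc_center) / pc_scale
    ffy_vals = np.array([ffy_targets[p.sample_id] for p in labeled])
    model.regressor_state = train_regressor(lab_scores, ffy_vals, config)
    raw_pred = model.regressor_state.predict(lab_scores)
    model.correction = fit_bias_correction(raw_pred, ffy_vals)
    if fit_ffx_submodel:
        x_ratios = np.array([chrx_overall_ratio(p) for p in labeled])
        model.ffx_model = fit_ffx(x_ratios, ffy_vals)
    return model


def _impute_vector(model: FetalFractionModel, profile: CopyNumberProfile):
    x = profile.log2_ratio[model.feature_bins]
    miss = np.isnan(x)
    x = np.where(miss, model.bin_means, x)
    return x, int(miss.sum())


def predict_ff(model: FetalFractionModel, profile: CopyNumberProfile) -> PredictionResult:
    """Score one profile: impute, project, regress, bias-correct; plus FFX/FFY."""
    if profile.grid.checksum() != model.grid.checksum():
        raise ModelError(
            f"profile {profile.sample_id!r} is not on the model's grid"
        )
    x, n_imputed = _impute_vector(model, profile)
    scores = project(model, x)
    raw = float(np.atleast_1d(model.regressor_state.predict(scores[None, :]))[0])
    a, b = model.correction
    ff = a + b * raw
    ffx_val = None
    if model.ffx_model is not None:
        try:
            ffx_val = ffx_eval(model.ffx_model, chrx_overall_ratio(profile))
        except ModelError:
            ffx_val = None
    ffy_val = None
    if model.ffy_model is not None and profile.y_counts is not None:
        ffy_val = ffy_final(model.ffy_model, profile.y_counts)
    missing_fraction = profile.missing_fraction
    return PredictionResult(
        ff=ff, ffx=ffx_val, ffy=ffy_val, n_imputed=n_imputed,
        missing_fraction=missing_fraction,
        low_quality=missing_fraction > model.config.max_missing_fraction,
    )


# ---------------------------------------------------------------------------
# cross-validation

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def make_cv_folds(sample_ids: list[str], n_folds: int, seed: int) -> list[list[str]]:
    """Seeded shuffle of labeled ids into folds; folds of <2 merge rightward."""
    rng = np.random.default_rng(seed)
    order = [sample_ids[i] for i in rng.permutation(len(sample_ids))]
    folds = [list(chunk) for chunk in np.array_split(np.array(order, dtype=object),
                                                     n_folds)]
    merged: list[list[str]] = []
    for fold in folds:
        if merged and len(fold) < 2:
            warnings.warn("merging an undersized CV fold into its neighbor")
            merged[-1].extend(fold)
        else:
            merged.append(fold)
    if len(merged) > 1 and len(merged[0]) < 2:
        warnings.warn("merging an undersized CV fold into its neighbor")
        merged[1] = merged[0] + merged[1]
        merged = merged[1:]
    return merged


def cross_validate(
    profiles: list[CopyNumberProfile],
    ffy_targets: dict[str, float],
    config: TrainConfig | None = None,
    fit_fn=None,
    predict_fn=None,
) -> CVReport:
    """K-fold CV over labeled males; the full pipeline is refit per fold.

    Unlabeled profiles take part in every fold's unsupervised phase.  The
    pooled held-out predictions yield the Pearson r and the MAE (percentage
    points), with the MAE over low-FF samples (FFY < 10%) reported separately.

    ``fit_fn(profiles, targets, config)`` and ``predict_fn(model, profile)``
    default to the real pipeline; they are injectable for validation.
    """
    config = config or TrainConfig()
    if fit_fn is None:
        fit_fn = lambda ps, ts, cfg: fit_ff_model(ps, ts, cfg,  # noqa: E731
                                                  fit_ffx_submodel=False)
    if predict_fn is None:
        predict_fn = lambda m, p: predict_ff(m, p).ff  # noqa: E731
    labeled_ids = [p.sample_id for p in profiles if p.sample_id in ffy_targets]
    if len(labeled_ids) < config.cv_folds:
        raise ModelError(
            f"{len(labeled_ids)} labeled samples cannot fill {config.cv_folds} folds"
        )
    folds = make_cv_folds(labeled_ids, config.cv_folds, config.seed)
    by_id = {p.sample_id: p for p in profiles}
    pooled_pred: list[float] = []
    pooled_ffy: list[float] = []
    fold_records = []
    for fold_no, test_ids in enumerate(folds):
        test_set = set(test_ids)
        train_profiles = [p for p in profiles if p.sample_id not in test_set]
        train_targets = {k: v for k, v in ffy_targets.items() if k not in test_set}
        sub = fit_fn(train_profiles, train_targets, config)
        preds = [float(predict_fn(sub, by_id[s])) for s in test_ids]
        truth = [ffy_targets[s] for s in test_ids]
        pooled_pred.extend(preds)
        pooled_ffy.extend(truth)
        fold_records.append({
            "fold": fold_no, "n_test": len(test_ids),
            "r": _pearson(np.array(preds), np.array(truth)),
            "mae": float(np.mean(np.abs(np.array(preds) - np.array(truth)))) * 100,
        })
    pred = np.array(pooled_pred)
    truth = np.array(pooled_ffy)
    err = np.abs(pred - truth)
    low = truth < 0.10
    constant = bool(np.ptp(pred) == 0)
    return CVReport(
        pearson_r=_pearson(pred, truth),
        mae=float(np.mean(err)) * 100,
        mae_low_ff=float(np.mean(err[low])) * 100 if low.any() else float("nan"),
        folds=fold_records,
        constant_prediction=constant,
    )


# ---------------------------------------------------------------------------
# serialization

def _grid_arrays(grid: BinGrid, prefix: str) -> dict[str, np.ndarray]:
    chroms = np.array([c for c, _, _ in grid.bins])
    starts = np.array([s for _, s, _ in grid.bins], dtype=np.int64)
    ends = np.array([e for _, _, e in grid.bins], dtype=np.int64)
    return {f"{prefix}_chroms": chroms, f"{prefix}_starts": starts,
            f"{prefix}_ends": ends}


def _grid_from_arrays(data, prefix: str, resolution: int, label: str) -> BinGrid:
    bins = tuple(
        (str(c), int(s), int(e))
        for c, s, e in zip(data[f"{prefix}_chroms"], data[f"{prefix}_starts"],
                           data[f"{prefix}_ends"])
    )
    return BinGrid(bins, resolution, label)


def save_model(model: FetalFractionModel, path) -> None:
    """Write the model as a zip archive: ``meta.json`` + ``arrays.npz``."""
    arrays: dict[str, np.ndarray] = {
        "feature_bins": model.feature_bins.astype(np.int64),
        "bin_means": model.bin_means,
        "rotations": model.rotations,
        "explained_variance": model.explained_variance,
        "pc_center": model.pc_center,
        "pc_scale": model.pc_scale,
    }
    arrays.update(_grid_arrays(model.grid, "grid"))
    for name, arr in model.regressor_state.arrays.items():
        arrays[f"reg_{name}"] = arr
    meta = {
        "format_version": model.version,
        "grid_checksum": model.grid.checksum(),
        "grid_resolution": model.grid.resolution,
        "grid_assembly": model.grid.assembly_label,
        "config": asdict(model.config),
        "correction": list(model.correction),
        "regressor": {
            "kind": model.regressor_state.kind,
            "hidden_sizes": model.regressor_state.hidden_sizes,
            "fell_back": model.regressor_state.fell_back,
            "array_names": sorted(model.regressor_state.arrays),
        },
    }
    if model.ffy_model is not None:
        m = model.ffy_model
        arrays["ffy_betas"] = m.betas
        meta["ffy"] = {
            "intercept": m.intercept, "lambda": m.lam,
            "reference": None if m.reference is None else
            [m.reference.lb_male_median, m.reference.nipt_female_median],
        }
        if model.y_grid is not None:
            arrays.update(_grid_arrays(model.y_grid, "ygrid"))
            meta["y_grid"] = {"resolution": model.y_grid.resolution,
                              "assembly": model.y_grid.assembly_label}
    if model.ffx_model is not None:
        meta["ffx"] = asdict(model.ffx_model)
    if model.cv_report is not None:
        meta["cv_report"] = asdict(model.cv_report)
    import io

    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("arrays.npz", buf.getvalue())


def load_model(path) -> FetalFractionModel:
    """Load a model archive; checks version and grid checksum integrity."""
    import io

    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            for member in ("meta.json", "arrays.npz"):
                if member not in names:
                    raise ModelError(f"corrupt model archive: missing {member}")
            meta = json.loads(zf.read("meta.json"))
            data = np.load(io.BytesIO(zf.read("arrays.npz")))
    except zipfile.BadZipFile as exc:
        raise ModelError(f"corrupt model archive {path}: {exc}") from exc
    version = int(meta["format_version"])
    if version > MODEL_FORMAT_VERSION:
        raise ModelError(
            f"model archive format v{version} is newer than supported "
            f"v{MODEL_FORMAT_VERSION}"
        )
    grid = _grid_from_arrays(data, "grid", int(meta["grid_resolution"]),
                             meta["grid_assembly"])
    if grid.checksum() != meta["grid_checksum"]:
        raise ModelError("model archive grid checksum mismatch")
    cfg_dict = dict(meta["config"])
    config = TrainConfig(**cfg_dict)
    reg_meta = meta["regressor"]
    reg = RegressorState(
        kind=reg_meta["kind"],
        hidden_sizes=None if reg_meta["hidden_sizes"] is None
        else tuple(reg_meta["hidden_sizes"]),
        arrays={name: data[f"reg_{name}"] for name in reg_meta["array_names"]},
        fell_back=bool(reg_meta["fell_back"]),
    )
    ffy_model = None
    y_grid = None
    if "ffy" in meta:
        ref = meta["ffy"]["reference"]
        ffy_model = FFYModel(
            intercept=float(meta["ffy"]["intercept"]), betas=data["ffy_betas"],
            lam=float(meta["ffy"]["lambda"]),
            reference=None if ref is None else FFYReference(*ref),
        )
        if "y_grid" in meta:
            y_grid = _grid_from_arrays(data, "ygrid",
                                       int(meta["y_grid"]["resolution"]),
                                       meta["y_grid"]["assembly"])
    ffx_model = FFXModel(**meta["ffx"]) if "ffx" in meta else None
    cv_report = CVReport(**meta["cv_report"]) if "cv_report" in meta else None
    return FetalFractionModel(
        grid=grid, feature_bins=data["feature_bins"], bin_means=data["bin_means"],
        rotations=data["rotations"], explained_variance=data["explained_variance"],
        pc_center=data["pc_center"], pc_scale=data["pc_scale"],
        regressor_state=reg, correction=tuple(meta["correction"]), config=config,
        ffy_model=ffy_model, y_grid=y_grid, ffx_model=ffx_model,
        cv_report=cv_report, version=version,
    )
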