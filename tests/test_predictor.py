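"""Semi-supervised predictor core: features, PCA, regressors, persistence."""

import warnings

import numpy as np
import pytest

from fetalfrac.errors import ModelError
from fetalfrac.predictor import (TrainConfig, assemble_features,
                                 cross_validate, fit_bias_correction,
                                 fit_ff_model, fit_pca, load_model,
                                 make_cv_folds, predict_ff, project,
                                 save_model, train_regressor)
from fetalfrac.profiles import CopyNumberProfile


def make_profiles(grid, matrix, sexes=None):
    sexes = sexes or ["male"] * len(matrix)
    return [CopyNumberProfile(f"s{i}", grid, row, sex_label=sx)
            for i, (row, sx) in enumerate(zip(matrix, sexes))]


# -- feature assembly --------------------------------------------------------

def test_feature_filters_and_imputation(small_grid):
    cfg = TrainConfig(n_components=2, excluded_chromosomes=("X", "Y"),
                      max_bin_missing_rate=0.4)
    n = 5
    rng = np.random.default_rng(0)
    M = rng.normal(size=(n, small_grid.n_bins))
    M[:, 0] = np.nan            # missing everywhere -> dropped
    M[0, 1] = np.nan            # missing once -> imputed
    profiles = make_profiles(small_grid, M)
    X, feature_bins, bin_means = assemble_features(profiles, cfg)
    auto = ~small_grid.chrom_mask({"X", "Y"})
    assert 0 not in feature_bins
    assert set(feature_bins) == set(np.flatnonzero(auto)) - {0}
    col = np.flatnonzero(feature_bins == 1)[0]
    assert X[0, col] == pytest.approx(np.mean(M[1:, 1]))
    assert bin_means[col] == pytest.approx(np.mean(M[1:, 1]))


def test_no_missing_keeps_all_autosomal_bins(small_grid):
    cfg = TrainConfig(n_components=2)
    M = np.zeros((4, small_grid.n_bins))
    X, feature_bins, _ = assemble_features(make_profiles(small_grid, M), cfg)
    expected = ~small_grid.chrom_mask({"13", "18", "21", "X", "Y"})
    assert set(feature_bins) == set(np.flatnonzero(expected))


def test_excluded_chromosomes_absent(mini_cohort):
    cfg = TrainConfig()
    _, feature_bins, _ = assemble_features(mini_cohort.profiles, cfg)
    grid = mini_cohort.profiles[0].grid
    banned = grid.chrom_mask({"13", "18", "21", "X", "Y"})
    assert not banned[feature_bins].any()


def test_all_bins_filtered_is_error(small_grid):
    cfg = TrainConfig(max_bin_missing_rate=0.0)
    M = np.full((3, small_grid.n_bins), np.nan)
    with pytest.raises(ModelError):
        assemble_features(make_profiles(small_grid, M), cfg)


# -- PCA ---------------------------------------------------------------------

def test_pca_exact_line():
    t = np.linspace(-1, 1, 10)
    X = np.column_stack([t, t])  # exactly on y = x
    rot, evar = fit_pca(X, 2)
    assert np.allclose(np.abs(rot[:, 0]), np.sqrt(0.5), atol=1e-12)
    assert evar[1] == pytest.approx(0.0, abs=1e-20)


def test_pca_matches_svd_oracle():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 8))
    rot, evar = fit_pca(X, 8)
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(8):
        sign = np.sign(vt[k] @ rot[:, k])
        assert np.max(np.abs(rot[:, k] - sign * vt[k])) <= 1e-8
    assert np.max(np.abs(evar - s**2 / (30 - 1))) <= 1e-8


def test_pca_orthonormal_and_variance_ranked():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 12)) * np.linspace(1, 5, 12)
    rot, evar = fit_pca(X, 6)
    assert np.max(np.abs(rot.T @ rot - np.eye(6))) <= 1e-8
    assert (np.diff(evar) <= 1e-12).all()
    with pytest.raises(ModelError):
        fit_pca(X, 41)


def test_unlabeled_samples_never_reduce_explained_variance():
    """PCA fitted on the pooled cohort captures at least as much pooled
    variance in its leading components as PCA fitted on the labeled subset."""
    rng = np.random.default_rng(8)
    latent = rng.normal(size=(80, 3))
    load = rng.normal(size=(3, 30))
    pooled = latent @ load + 0.3 * rng.normal(size=(80, 30))
    males = pooled[:40]
    k = 3

    def captured(rot):
        Xc = pooled - pooled.mean(axis=0)
        return float(np.sum((Xc @ rot) ** 2))

    rot_pool, _ = fit_pca(pooled, k)
    rot_males, _ = fit_pca(males, k)
    assert captured(rot_pool) >= captured(rot_males) - 1e-9


# -- projection --------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_model(request):
    """A small trained model on a simulated cohort (OLM for speed)."""
    from fetalfrac.simulate import SimulationParams, simulate_cohort

    cohort = simulate_cohort(SimulationParams(n_samples=80, seed=13))
    truth = cohort.truth
    targets = {s: f for s, f, sex in zip(truth.sample_id, truth.true_ff,
                                         truth.sex) if sex == "male"}
    cfg = TrainConfig(n_components=10, regressor="OLM", seed=2, cv_folds=4)
    model = fit_ff_model(cohort.profiles, targets, cfg)
    return model, cohort, targets, cfg


def test_project_center_and_unit_directions(tiny_model):
    model, *_ = tiny_model
    raw0 = (model.bin_means - model.bin_means) @ model.rotations
    assert (raw0 == 0).all()
    x = model.bin_means + model.rotations[:, 0]
    raw = (x - model.bin_means) @ model.rotations
    expected = np.zeros(model.rotations.shape[1])
    expected[0] = 1.0
    assert np.allclose(raw, expected, atol=1e-10)


def test_project_is_linear(tiny_model):
    model, *_ = tiny_model
    rng = np.random.default_rng(0)
    a = rng.normal(size=model.bin_means.size)
    b = rng.normal(size=model.bin_means.size)
    lhs = project(model, a) + project(model, b)
    rhs = project(model, a + b) + project(model, np.zeros_like(a))
    assert np.allclose(lhs, rhs, atol=1e-8)


# -- regressors --------------------------------------------------------------

def test_olm_exact_on_linear_targets():
    rng = np.random.default_rng(1)
    S = rng.normal(size=(40, 6))
    y = 0.1 + S @ rng.normal(size=6) * 0.01
    state = train_regressor(S, y, TrainConfig(n_components=6, regressor="OLM"))
    assert np.max(np.abs(state.predict(S) - y)) <= 1e-8


def test_nn_fits_linear_targets():
    rng = np.random.default_rng(1)
    S = rng.normal(size=(60, 5))
    y = 0.1 + S @ (0.02 * rng.normal(size=5))
    cfg = TrainConfig(n_components=5, regressor="NN", seed=3, max_epochs=20_000)
    state = train_regressor(S, y, cfg)
    assert state.kind == "NN" and not state.fell_back
    sse = float(np.sum((state.predict(S) - y) ** 2))
    assert sse < 1e-4


def test_nn_falls_back_to_olm_on_nan():
    rng = np.random.default_rng(0)
    S = rng.normal(size=(30, 4))
    y = np.full(30, np.nan)
    y[:15] = 0.1  # NaN loss -> failure path
    cfg = TrainConfig(n_components=4, regressor="NN", nn_retries=1, max_epochs=50)
    with pytest.warns(UserWarning, match="falling back"):
        state = train_regressor(S, y, cfg)
    assert state.kind == "OLM" and state.fell_back


# -- bias correction ---------------------------------------------------------

def test_bias_correction_inverts_affine_map():
    rng = np.random.default_rng(5)
    ffy = rng.uniform(0.02, 0.25, size=50)
    pred = 0.5 * ffy + 0.01
    a, b = fit_bias_correction(pred, ffy)
    assert b == pytest.approx(2.0, abs=1e-10)
    assert a == pytest.approx(-0.02, abs=1e-10)
    assert np.allclose(a + b * pred, ffy, atol=1e-10)


def test_bias_correction_identity_when_unbiased():
    ffy = np.linspace(0.02, 0.2, 20)
    a, b = fit_bias_correction(ffy, ffy)
    assert a == pytest.approx(0.0, abs=1e-12) and b == pytest.approx(1.0, abs=1e-12)


def test_bias_correction_is_idempotent_in_refit():
    rng = np.random.default_rng(6)
    ffy = rng.uniform(0.02, 0.25, size=80)
    pred = 0.8 * ffy + 0.02 + 0.01 * rng.normal(size=80)
    a, b = fit_bias_correction(pred, ffy)
    corrected = a + b * pred
    a2, b2 = fit_bias_correction(corrected, ffy)
    assert a2 == pytest.approx(0.0, abs=1e-8) and b2 == pytest.approx(1.0, abs=1e-8)


def test_bias_correction_constant_predictions_warns():
    with pytest.warns(UserWarning, match="constant"):
        a, b = fit_bias_correction(np.full(10, 0.1), np.linspace(0, 1, 10))
    assert (a, b) == (0.0, 1.0)


# -- prediction --------------------------------------------------------------

def test_imputation_equivalence_and_diagnostics(tiny_model):
    model, cohort, _, _ = tiny_model
    grid = cohort.profiles[0].grid
    base = CopyNumberProfile("t", grid, np.zeros(grid.n_bins))
    base.log2_ratio[model.feature_bins] = model.bin_means
    full = predict_ff(model, base)
    # blank out chr22 entirely: imputation must restore the same prediction
    masked = CopyNumberProfile("t2", grid, base.log2_ratio.copy())
    masked.log2_ratio[grid.chrom_mask({"22"})] = np.nan
    out = predict_ff(model, masked)
    assert out.ff == pytest.approx(full.ff, abs=1e-12)
    assert out.n_imputed > 0 and out.missing_fraction > 0


def test_low_quality_flag(tiny_model):
    model, cohort, _, _ = tiny_model
    grid = cohort.profiles[0].grid
    vals = np.zeros(grid.n_bins)
    vals[: int(grid.n_bins * 0.5)] = np.nan
    res = predict_ff(model, CopyNumberProfile("q", grid, vals))
    assert res.low_quality and np.isfinite(res.ff)


def test_predict_rejects_wrong_grid(tiny_model, small_grid):
    model, *_ = tiny_model
    prof = CopyNumberProfile("w", small_grid, np.zeros(small_grid.n_bins))
    with pytest.raises(ModelError):
        predict_ff(model, prof)


# -- persistence and determinism --------------------------------------------

def test_save_load_roundtrip_bit_exact(tiny_model, tmp_path):
    model, cohort, _, _ = tiny_model
    path = tmp_path / "model.zip"
    save_model(model, path)
    back = load_model(path)
    assert (back.rotations == model.rotations).all()
    assert (back.bin_means == model.bin_means).all()
    assert (back.pc_center == model.pc_center).all()
    assert back.correction == model.correction
    for name, arr in model.regressor_state.arrays.items():
        assert (back.regressor_state.arrays[name] == arr).all()
    res_a = predict_ff(model, cohort.profiles[0])
    res_b = predict_ff(back, cohort.profiles[0])
    assert res_a.ff == res_b.ff and res_a.ffx == res_b.ffx


def test_truncated_archive_errors(tiny_model, tmp_path):
    model, *_ = tiny_model
    path = tmp_path / "model.zip"
    save_model(model, path)
    data = path.read_bytes()
    path.write_bytes(data[: len(data) // 2])
    with pytest.raises(ModelError):
        load_model(path)


def test_newer_version_rejected(tiny_model, tmp_path):
    import json
    import zipfile

    model, *_ = tiny_model
    path = tmp_path / "model.zip"
    save_model(model, path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = zf.read("arrays.npz")
    meta["format_version"] = 99
    path2 = tmp_path / "model2.zip"
    with zipfile.ZipFile(path2, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("arrays.npz", arrays)
    with pytest.raises(ModelError, match="newer"):
        load_model(path2)


def test_training_is_deterministic(mini_cohort):
    truth = mini_cohort.truth
    targets = {s: f for s, f, sex in zip(truth.sample_id, truth.true_ff,
                                         truth.sex) if sex == "male"}
    cfg = TrainConfig(n_components=8, regressor="NN", seed=4, max_epochs=300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = fit_ff_model(mini_cohort.profiles, targets, cfg)
        b = fit_ff_model(mini_cohort.profiles, targets, cfg)
    assert (a.rotations == b.rotations).all()
    assert a.correction == b.correction
    for name, arr in a.regressor_state.arrays.items():
        assert (b.regressor_state.arrays[name] == arr).all()


# -- cross-validation --------------------------------------------------------

def test_cv_folds_partition_and_merge():
    ids = [f"s{i}" for i in range(23)]
    folds = make_cv_folds(ids, 10, seed=1)
    flat = [s for fold in folds for s in fold]
    assert sorted(flat) == sorted(ids)
    assert all(len(f) >= 2 for f in folds)
    with pytest.warns(UserWarning, match="merging"):
        folds = make_cv_folds([f"s{i}" for i in range(11)], 10, seed=0)
    assert all(len(f) >= 2 for f in folds)


def test_cv_with_truth_oracle_is_perfect(mini_cohort):
    truth = mini_cohort.truth
    targets = {s: f for s, f, sex in zip(truth.sample_id, truth.true_ff,
                                         truth.sex) if sex == "male"}
    lookup = dict(targets)
    report = cross_validate(
        mini_cohort.profiles, targets, TrainConfig(cv_folds=5, seed=0),
        fit_fn=lambda ps, ts, cfg: None,
        predict_fn=lambda m, p: lookup[p.sample_id],
    )
    assert report.pearson_r == pytest.approx(1.0, abs=1e-12)
    assert report.mae == pytest.approx(0.0, abs=1e-12)


def test_cv_constant_predictor_flags_undefined_r(mini_cohort):
    truth = mini_cohort.truth
    targets = {s: f for s, f, sex in zip(truth.sample_id, truth.true_ff,
                                         truth.sex) if sex == "male"}
    c = 0.07
    report = cross_validate(
        mini_cohort.profiles, targets, TrainConfig(cv_folds=5, seed=0),
        fit_fn=lambda ps, ts, cfg: None,
        predict_fn=lambda m, p: c,
    )
    vals = np.array(list(targets.values()))
    assert report.constant_prediction
    assert np.isnan(report.pearson_r)
    assert report.mae == pytest.approx(np.mean(np.abs(vals - c)) * 100, abs=1e-9)
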