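"""Twin-gender classification, density screens, aberration source."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from fetalfrac.errors import ModelError
from fetalfrac.screening import (GaussianMixture1D, aberration_source_check,
                                 classify_twin_gender, expected_ff_from_log2,
                                 expected_log2_for_trisomy, fit_gmm_1d,
                                 gmm_cutoffs, sex_aneuploidy_screen, twin_ratio)


# -- twin ratio --------------------------------------------------------------

@pytest.mark.parametrize("ffy,ff,expected", [
    (0.10, 0.10, 1.0), (0.0, 0.10, 0.0), (0.05, 0.10, 0.5),
])
def test_twin_ratio_values(ffy, ff, expected):
    assert twin_ratio(ffy, ff) == pytest.approx(expected)


def test_twin_ratio_floor_gives_nan():
    assert np.isnan(twin_ratio(0.05, 0.005))
    assert np.isnan(twin_ratio(0.05, 0.01))


# -- 1-D GMM -----------------------------------------------------------------

def test_gmm_recovers_three_separated_components():
    rng = np.random.default_rng(0)
    x = np.concatenate([
        rng.normal(0.0, 0.03, 300),
        rng.normal(0.5, 0.03, 250),
        rng.normal(1.0, 0.03, 350),
    ])
    gm = fit_gmm_1d(x, k=3, seed=1)
    assert np.allclose(gm.means, [0.0, 0.5, 1.0], atol=0.02)
    assert (np.diff(gm.means) > 0).all()
    assert abs(gm.weights.sum() - 1.0) < 1e-9


def test_gmm_k1_is_sample_mle():
    rng = np.random.default_rng(1)
    x = rng.normal(0.3, 0.05, 400)
    gm = fit_gmm_1d(x, k=1, seed=0)
    assert gm.means[0] == pytest.approx(x.mean(), abs=1e-6)
    assert gm.sds[0] == pytest.approx(x.std(), rel=1e-3)


def test_gmm_degenerate_input_errors():
    # identical values: either a collapse error or an sd-floor fit
    try:
        gm = fit_gmm_1d(np.zeros(50), k=1, seed=0)
        assert gm.sds[0] <= 1e-6
        assert gm.means[0] == pytest.approx(0.0, abs=1e-12)
    except ModelError:
        pass
    with pytest.raises(ModelError):
        fit_gmm_1d(np.arange(4.0), k=1, seed=0)  # too few values


# -- cutoffs -----------------------------------------------------------------

def test_cutoff_symmetric_two_components():
    gm = GaussianMixture1D([0.5, 0.5], [0.0, 1.0], [0.1, 0.1], 0.0)
    cuts = gmm_cutoffs(gm)
    assert cuts[0] == pytest.approx(0.5, abs=1e-6)


def test_cutoffs_three_equal_components():
    gm = GaussianMixture1D([1 / 3] * 3, [0.0, 0.5, 1.0], [0.1] * 3, 0.0)
    cuts = gmm_cutoffs(gm)
    # verify against a brute-force scan of the stated mixture density
    for (lo, hi), cut in zip([(0.0, 0.5), (0.5, 1.0)], cuts):
        grid = np.linspace(lo, hi, 200_001)
        brute = grid[np.argmin(gm.pdf(grid))]
        assert cut == pytest.approx(brute, abs=1e-4)
    assert np.allclose(cuts, [0.25, 0.75], atol=0.01)


def test_unequal_weights_shift_cutoff_toward_lighter_component():
    heavy_left = GaussianMixture1D([0.8, 0.2], [0.0, 1.0], [0.15, 0.15], 0.0)
    cut = gmm_cutoffs(heavy_left)[0]
    assert cut > 0.5  # shifted toward the lighter (right) component


def test_overlapping_components_fall_back_to_midpoint():
    gm = GaussianMixture1D([0.5, 0.5], [0.0, 0.05], [1.0, 1.0], 0.0)
    with pytest.warns(UserWarning, match="midpoint"):
        cut = gmm_cutoffs(gm)[0]
    assert cut == pytest.approx(0.025, abs=1e-12)


# -- classification ----------------------------------------------------------

@pytest.mark.parametrize("ratio,expected", [
    (0.05, "female_female"), (0.5, "mixed"), (1.02, "male_male"),
    (float("nan"), "undetermined"),
])
def test_classify_twin_gender(ratio, expected):
    assert classify_twin_gender(ratio, np.array([0.25, 0.75])) == expected


def test_classify_needs_ascending_cutoffs():
    with pytest.raises(ModelError):
        classify_twin_gender(0.5, np.array([0.75, 0.25]))


# -- density screen ----------------------------------------------------------

def synthetic_stats(seed=0, n=500, n_xxy=4):
    """Euploid FFY/FFX/FF triples from the dosage model + XXY-like rows
    (FFY tracks FF, FFX collapses to ~0)."""
    rng = np.random.default_rng(seed)
    ff = rng.uniform(0.08, 0.20, size=n)
    male = rng.uniform(size=n) < 0.5
    ffy = np.where(male, ff, 0.0) + 0.004 * rng.normal(size=n)
    ffx = np.where(male, ff, 0.0) + 0.006 * rng.normal(size=n)
    for i in range(n_xxy):
        ffx[i] = 0.006 * rng.normal()
        ffy[i] = ff[i] + 0.004 * rng.normal()
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "ffy": ffy, "ffx": ffx, "ff_pred": ff,
    })
    return df, np.arange(n_xxy)


def test_density_arithmetic_and_antisymmetry():
    df = pd.DataFrame({
        "sample_id": ["m", "f"],
        "ffy": [0.10, 0.0], "ffx": [0.10, 0.0], "ff_pred": [0.10, 0.10],
    })
    big, _ = synthetic_stats(seed=3)
    merged = pd.concat([df, big], ignore_index=True)
    res = sex_aneuploidy_screen(merged, seed=0)
    row_m = res.table.set_index("sample_id").loc["m"]
    row_f = res.table.set_index("sample_id").loc["f"]
    assert row_m["density1"] == pytest.approx(1.0)
    assert row_m["density2"] == pytest.approx(0.0)
    assert not row_m["outlier_flag"]
    assert row_f["density1"] == pytest.approx(0.0)
    assert row_f["density2"] == pytest.approx(0.0)
    # antisymmetry of density2 under ffy <-> ffx
    d2 = res.table["ffy"] - res.table["ffx"]
    swapped = res.table["ffx"] - res.table["ffy"]
    assert np.allclose(d2, -swapped)


def test_screen_flags_xxy_like_outliers():
    df, xxy_idx = synthetic_stats(seed=1)
    res = sex_aneuploidy_screen(df, seed=0)
    flags = res.table["outlier_flag"].to_numpy()
    assert flags[xxy_idx].all()
    euploid_rate = flags[len(xxy_idx):].mean()
    assert euploid_rate <= 0.015


def test_prefilter_excludes_extreme_ffx_but_keeps_rows():
    df, _ = synthetic_stats(seed=2, n_xxy=0)
    df.loc[:2, "ffx"] = [0.6, -0.9, 1.4]  # maternal-X-like excursions
    res = sex_aneuploidy_screen(df, seed=0)
    assert res.table["prefilter_flag"][:3].all()
    assert len(res.table) == len(df)
    # the density2 Gaussian is fitted without them
    kept = res.table.loc[~res.table["prefilter_flag"], "density2"]
    assert abs(res.density2_mean - kept.mean()) < 0.01


def test_screen_refuses_small_cohorts():
    df, _ = synthetic_stats(n=20, n_xxy=0)
    with pytest.raises(ModelError, match="30"):
        sex_aneuploidy_screen(df, seed=0)


def test_gender_classes_partition_by_density1():
    df, _ = synthetic_stats(seed=4, n_xxy=0)
    res = sex_aneuploidy_screen(df, seed=0)
    tab = res.table
    lo, hi = res.density1_cutoffs
    assert (tab.loc[tab["density1"] < lo, "gender_class"] == "female_like").all()
    assert (tab.loc[tab["density1"] >= hi, "gender_class"] == "male_like").all()


# -- trisomy amplitude -------------------------------------------------------

def test_trisomy_amplitude_closed_form():
    assert expected_log2_for_trisomy(0.0) == 0.0
    assert expected_log2_for_trisomy(1.0) == pytest.approx(np.log2(1.5))
    assert expected_log2_for_trisomy(1.0) == pytest.approx(0.58496, abs=1e-5)
    with pytest.raises(ModelError):
        expected_log2_for_trisomy(1.2)


def test_trisomy_roundtrip_identity():
    for x in np.arange(0.01, 0.51, 0.01):
        back = expected_ff_from_log2(expected_log2_for_trisomy(x))
        assert abs(back - x) <= 1e-12


@pytest.mark.parametrize(
    "observed,ff,expect_ok,reason",
    [
        (expected_log2_for_trisomy(0.12), 0.12, True, ""),
        (expected_log2_for_trisomy(0.03), 0.15, False, "mosaicism_like"),
        (0.0, 0.10, False, "mosaicism_like"),
        (-0.05, 0.10, False, "negative_shift"),
    ],
)
def test_aberration_source_check(observed, ff, expect_ok, reason):
    chk = aberration_source_check("21", observed, ff, tolerance=0.02)
    assert chk.concordant is expect_ok
    assert chk.reason == reason


def test_gmm_pdf_matches_scipy():
    gm = GaussianMixture1D([0.3, 0.7], [0.0, 1.0], [0.2, 0.1], 0.0)
    x = np.linspace(-0.5, 1.5, 11)
    manual = 0.3 * norm.pdf(x, 0.0, 0.2) + 0.7 * norm.pdf(x, 1.0, 0.1)
    assert np.allclose(gm.pdf(x), manual, atol=1e-12)
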