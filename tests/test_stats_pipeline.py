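"""Spearman matrices, LASSO selection, and the quartic normalization."""

import numpy as np
import pandas as pd
import pytest

from asrkit.metadata_report import AnnotationMetadata, SpeciesRecord
from asrkit.stats_pipeline import (
    PolynomialFit,
    build_normalization,
    evaluate_normalization,
    expected_asr,
    fit_polynomial,
    lasso_select,
    normalize_asr,
    spearman_matrix,
)
from asrkit.synthetic_data import DEFAULT_BETA, SpeciesSimParams, quartic, simulate_species_table


def brute_force_spearman(x, y):
    """Oracle: average ranks by explicit sorting, then the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_invariance():
    x = np.linspace(0.1, 5, 50)
    df = pd.DataFrame({"x": x, "y": x**3, "z": -x})
    cm = spearman_matrix(df, ["x", "y", "z"])
    assert cm.rho.loc["x", "y"] == pytest.approx(1.0, abs=1e-12)
    assert cm.rho.loc["x", "z"] == pytest.approx(-1.0, abs=1e-12)


def test_spearman_matches_rank_oracle_on_small_tables():
    rng = np.random.default_rng(99)
    for n in (4, 5, 6, 8):
        for _ in range(25):
            x = rng.integers(0, 5, n).astype(float)  # ties likely
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            cm = spearman_matrix(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
            assert cm.rho.loc["x", "y"] == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_spearman_matrix_shape_and_stars():
    rng = np.random.default_rng(4)
    n = 200
    x = rng.normal(size=n)
    df = pd.DataFrame({"x": x, "y": x + rng.normal(0, 0.3, n), "z": rng.normal(size=n)})
    cm = spearman_matrix(df, ["x", "y", "z"])
    assert np.allclose(np.diag(cm.rho), 1.0)
    assert cm.rho.equals(cm.rho.T)
    assert cm.stars.loc["x", "y"] == "**"  # strong association, P < .001
    assert cm.stars.loc["x", "z"] in ("", "*")
    p = cm.pvalues.loc["x", "y"]
    assert (cm.stars.loc["x", "y"] == "**") == (p < 0.001)


def test_spearman_constant_variable_reported_missing():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
    with pytest.warns(UserWarning, match="constant"):
        cm = spearman_matrix(df, ["x", "c"])
    assert np.isnan(cm.rho.loc["x", "c"])


# ---------------------------------------------------------------------------
# LASSO


def _design(seed, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(670, 8))
    names = [f"p{i}" for i in range(8)]
    if signal:
        y = 2 * X[:, 0] + 1.2 * X[:, 1] - 0.8 * X[:, 2] + rng.normal(0, 1, 670)
    else:
        y = 2 * X[:, 0]
    df = pd.DataFrame(X, columns=names)
    df["asr"] = y
    return df, names


def test_lasso_all_slopes_zero_at_lambda_max():
    df, names = _design(7)
    fit = lasso_select(df, names, seed=11)
    assert np.all(fit.coefficient_path[:, 0] == 0.0)
    assert np.all(np.diff(fit.lambda_grid) < 0)


def test_lasso_noiseless_single_signal_selected():
    df, names = _design(7, signal=False)
    fit = lasso_select(df, names, seed=5)
    assert fit.selected == ["p0"]
    assert fit.test_r2 > 0.99


def test_lasso_planted_three_signal_recovery():
    """3 signal + 5 noise predictors: the signals carry the largest coefficients."""
    df, names = _design(7)
    fit = lasso_select(df, names, seed=11)
    top3 = fit.final_coefficients.abs().sort_values(ascending=False).index[:3]
    assert set(top3) == {"p0", "p1", "p2"}
    assert all(fit.final_coefficients[p] != 0 for p in ("p0", "p1", "p2"))
    assert fit.cv_folds == 10 and fit.n_train == 536 and fit.n_test == 134


def test_lasso_errors_on_tiny_tables():
    df, names = _design(7)
    with pytest.raises(ValueError):
        lasso_select(df.head(5), names, seed=0, folds=10)


# ---------------------------------------------------------------------------
# polynomial fit and normalization


def test_quartic_recovered_from_noiseless_data():
    rng = np.random.default_rng(21)
    x = rng.uniform(0, 1, 200)
    y = quartic(x, DEFAULT_BETA)
    fit = fit_polynomial(x, y)
    assert fit.beta == pytest.approx(np.asarray(DEFAULT_BETA), rel=1e-6)
    assert fit.r2 == pytest.approx(1.0)


def test_constant_response_gives_flat_fit_and_zero_r2():
    x = np.linspace(0, 1, 50)
    fit = fit_polynomial(x, np.full(50, 2.5))
    assert fit.beta[0] == pytest.approx(2.5, abs=1e-9)
    assert np.allclose(fit.beta[1:], 0, atol=1e-8)
    assert fit.r2 == 0.0


def test_underdetermined_fit_is_an_error():
    with pytest.raises(ValueError):
        fit_polynomial(np.linspace(0, 1, 4), np.ones(4))
    with pytest.raises(ValueError, match="constant"):
        fit_polynomial(np.full(10, 0.5), np.arange(10.0))


def test_expected_asr_raw_basis_evaluation():
    fit = PolynomialFit(
        beta=np.array([0.0, 1, 0, 0, 0]), r2=1.0, residuals=np.array([]),
        n=0, x=np.array([]), scaled_coef=np.array([]), domain=(0, 1),
    )
    assert expected_asr(fit, 0.5) == 0.5
    fit.beta = np.array([3.0, 0, 0, 0, 0])
    assert expected_asr(fit, np.array([0.1, 0.9])) == pytest.approx([3.0, 3.0])


def test_expected_asr_consistent_with_training_predictions():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, 100)
    y = quartic(x, DEFAULT_BETA) + rng.normal(0, 0.3, 100)
    fit = fit_polynomial(x, y)
    assert expected_asr(fit, x) == pytest.approx(y - fit.residuals, abs=1e-9)


def _tiny_table(residuals, fit):
    """Species whose ASR sits at given offsets from a flat expectation."""
    recs = []
    for i, r in enumerate(residuals):
        meta = AnnotationMetadata(cds_fully_supported_pct=50.0, cds_total=1000)
        recs.append(
            SpeciesRecord(
                species_name=f"s{i}", asr=float(fit.beta[0] + r), metadata=meta
            )
        )
    from asrkit.metadata_report import SpeciesTable

    return SpeciesTable(records=recs)


def _flat_fit(c):
    return PolynomialFit(
        beta=np.array([c, 0.0, 0, 0, 0]), r2=0.0, residuals=np.array([]),
        n=3, x=np.array([]), scaled_coef=np.array([]), domain=(0, 1),
    )


def test_sigma_min_arithmetic():
    fit = _flat_fit(2.0)
    model = build_normalization(fit, _tiny_table([-0.5, 0.0, 0.5], fit))
    assert model.sigma_min == pytest.approx(1.5)
    stars = sorted(
        normalize_asr(model, r).asr_star for r in _tiny_table([-0.5, 0.0, 0.5], fit).records
    )
    assert stars == pytest.approx([1.0, 1.5, 2.0])


def test_sigma_min_degenerate_cases():
    fit = _flat_fit(2.0)
    assert build_normalization(fit, _tiny_table([0.0, 0.0], fit)).sigma_min == pytest.approx(1.0)
    single = build_normalization(fit, _tiny_table([0.7], fit))
    star = normalize_asr(single, _tiny_table([0.7], fit).records[0]).asr_star
    assert star == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="empty"):
        build_normalization(fit, _tiny_table([], fit))


def test_training_minimum_is_exactly_one(species_panel):
    df = species_panel.complete_frame(["asr", "cds_fully_supported_pct"])
    fit = fit_polynomial(
        df["cds_fully_supported_pct"].to_numpy() / 100.0, df["asr"].to_numpy()
    )
    model = build_normalization(fit, species_panel)
    stars = [normalize_asr(model, r).asr_star for r in species_panel.records]
    assert min(stars) == pytest.approx(1.0, abs=1e-12)
    assert not any(
        normalize_asr(model, r).below_training_min for r in species_panel.records
    )


def test_new_species_below_training_minimum_is_flagged():
    fit = _flat_fit(2.0)
    model = build_normalization(fit, _tiny_table([0.0, 0.5], fit))
    outsider = _tiny_table([-1.0], fit).records[0]
    outsider.species_name = "outsider"
    nz = normalize_asr(model, outsider)
    assert nz.asr_star < 1.0 and nz.below_training_min


def test_missing_support_percentage_is_an_error():
    fit = _flat_fit(2.0)
    model = build_normalization(fit, _tiny_table([0.0], fit))
    rec = SpeciesRecord(species_name="x", asr=2.0, metadata=AnnotationMetadata())
    with pytest.raises(ValueError, match="cds_fully_supported_pct"):
        normalize_asr(model, rec)


def test_normalization_preserves_ranking_at_fixed_x():
    """Within a fixed-x stratum, ASR* differences equal ASR differences."""
    fit = _flat_fit(2.0)
    table = _tiny_table([-0.3, 0.1, 0.8], fit)
    model = build_normalization(fit, table)
    stars = [normalize_asr(model, r).asr_star for r in table.records]
    asrs = [r.asr for r in table.records]
    diffs_star = np.diff(sorted(stars))
    diffs_asr = np.diff(sorted(asrs))
    assert diffs_star == pytest.approx(diffs_asr, abs=1e-12)


def test_decorrelation_on_quartic_panel(species_panel):
    df = species_panel.complete_frame(["asr", "cds_fully_supported_pct"])
    fit = fit_polynomial(
        df["cds_fully_supported_pct"].to_numpy() / 100.0, df["asr"].to_numpy()
    )
    model = build_normalization(fit, species_panel)
    report = evaluate_normalization(model, species_panel)
    assert report["rho_asr_x"] > 0.5
    assert abs(report["rho_asr_star_x"]) < 0.05
    assert report["min_asr_star"] == pytest.approx(1.0, abs=1e-12)


def test_noiseless_panel_reports_undefined_decorrelation():
    table = simulate_species_table(SpeciesSimParams(n_species=100, noise_sd=0.0, seed=8))
    df = table.complete_frame(["asr", "cds_fully_supported_pct"])
    fit = fit_polynomial(
        df["cds_fully_supported_pct"].to_numpy() / 100.0, df["asr"].to_numpy()
    )
    model = build_normalization(fit, table)
    report = evaluate_normalization(model, table)
    # residuals are (numerically) constant: rank correlation is meaningless
    assert report["fit_r2"] == pytest.approx(1.0)
    assert np.isnan(report["rho_asr_star_x"])


def test_fitted_r2_tracks_population_r2_across_seeds():
    """Noise calibrated to population R^2 = 0.6 yields fitted r2 in [0.5, 0.7]."""
    r2s = []
    for seed in range(1, 21):
        table = simulate_species_table(SpeciesSimParams(seed=seed))
        df = table.complete_frame(["asr", "cds_fully_supported_pct"])
        fit = fit_polynomial(
            df["cds_fully_supported_pct"].to_numpy() / 100.0, df["asr"].to_numpy()
        )
        r2s.append(fit.r2)
    assert all(0.5 <= r <= 0.7 for r in r2s)
    assert abs(np.mean(r2s) - 0.6) < 0.1
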