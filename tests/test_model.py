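"""Indicator encoding, scoring, recentering, rescaling, and fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from refree import (
    CoefficientTable,
    Complex,
    ERE,
    SRE,
    FitConfig,
    Genotype,
    InputError,
    TermKey,
    build_indicator_row,
    calibrate_ddg,
    check_proportional_odds,
    check_zero_sum,
    class_probabilities,
    fit,
    genetic_score,
    predict_class,
    recenter,
    reffree_coefficients_from_scores,
    rescale_scores,
    weighted_misclassification,
)
from refree.model import (
    predict_landscape_classes,
    score_landscape,
)
from refree.synthetic import (
    SyntheticSpec,
    generate_coefficients,
    sample_classes,
)
from refree.variance import variance_partition

from conftest import random_table


# ---------------------------------------------------------------------------
# indicator rows
# ---------------------------------------------------------------------------


def test_full_model_row_has_30_nonzeros():
    row = build_indicator_row(
        Complex(Genotype.from_string("EGKA"), ERE), max_order=3
    )
    assert len(row) == 30
    values = dict(row.entries)
    assert all(v == 1 for k, v in values.items() if k.effect_type == "beta")
    assert all(v == 1 for k, v in values.items() if k.effect_type == "sigma")


def test_sre_row_negates_specificity_entries():
    g = Genotype.from_string("EGKA")
    ere_row = dict(build_indicator_row(Complex(g, ERE)).entries)
    sre_row = dict(build_indicator_row(Complex(g, SRE)).entries)
    for key in ere_row:
        if key.effect_type == "beta":
            assert sre_row[key] == ere_row[key]
        else:
            assert sre_row[key] == -ere_row[key]


def test_toy_second_order_row_has_8_nonzeros():
    row = build_indicator_row(
        Complex(Genotype.from_string("AC"), ERE), max_order=2
    )
    assert len(row) == 8  # beta0, sigma0, 2+1 beta, 2+1 sigma


# ---------------------------------------------------------------------------
# genetic score
# ---------------------------------------------------------------------------


def test_intercept_only_score():
    table = CoefficientTable.zeros(tuple("ACDE"), 2, 2)
    table.tables[("beta", ())] = np.asarray(5.0)
    for re in (ERE, SRE):
        assert genetic_score(
            Complex(Genotype.from_string("AC"), re), table
        ) == pytest.approx(5.0)


def test_specificity_terms_cancel_in_re_sum(tiny_space):
    table = random_table(tiny_space.alphabet, 2, 2, seed=1)
    y_ere, y_sre = score_landscape(table, tiny_space)
    codes = tiny_space.codes()
    from refree.model import _component_scores

    beta_part = _component_scores(table, "beta", codes)
    np.testing.assert_allclose(y_ere + y_sre, 2 * beta_part)


def test_hand_built_score():
    table = CoefficientTable.zeros(tuple("AC"), 2, 2)
    table.tables[("beta", ())] = np.asarray(0.5)
    table.tables[("sigma", ())] = np.asarray(0.25)
    table.set(TermKey("beta", (1,), ("A",)), 1.0)
    table.set(TermKey("beta", (2,), ("C",)), -0.5)
    table.set(TermKey("beta", (1, 2), ("A", "C")), 0.75)
    table.set(TermKey("sigma", (1,), ("A",)), 0.3)
    g = Genotype.from_string("AC")
    expected_beta = 0.5 + 1.0 - 0.5 + 0.75
    expected_sigma = 0.25 + 0.3
    assert genetic_score(Complex(g, ERE), table) == pytest.approx(
        expected_beta + expected_sigma
    )
    assert genetic_score(Complex(g, SRE), table) == pytest.approx(
        expected_beta - expected_sigma
    )


def test_score_equals_indicator_dot_product(small_truth):
    space = small_truth.space
    y_ere, _ = score_landscape(small_truth, space)
    for idx in (0, 17, 101):
        g = space.decode(idx)
        row = build_indicator_row(Complex(g, ERE), small_truth.max_order)
        dot = sum(small_truth.get(k) * v for k, v in row.entries)
        assert dot == pytest.approx(y_ere[idx], abs=1e-12)


# ---------------------------------------------------------------------------
# class probabilities and prediction
# ---------------------------------------------------------------------------


def test_probabilities_normalize_and_order():
    for score in (-5.0, 0.0, 0.7, 3.3, 40.0):
        p = class_probabilities(score, 0.0, 1.5)
        assert sum(p) == pytest.approx(1.0)
        assert all(0 <= x <= 1 for x in p)


def test_probability_half_at_strong_threshold():
    p_null, p_weak, p_strong = class_probabilities(1.5, 0.0, 1.5)
    assert p_null + p_weak == pytest.approx(0.5)
    assert p_strong == pytest.approx(0.5)


def test_extreme_scores_saturate():
    _, _, p_strong = class_probabilities(1e3, 0.0, 1.5)
    assert p_strong == pytest.approx(1.0)
    p_null, _, _ = class_probabilities(-1e3, 0.0, 1.5)
    assert p_null == pytest.approx(1.0)


def test_predict_class_regions():
    table = CoefficientTable.zeros(tuple("AC"), 1, 1, theta_nw=-4.0,
                                   theta_ws=4.0)
    table.tables[("beta", ())] = np.asarray(10.0)
    assert predict_class(Complex(Genotype.from_string("A"), ERE), table) == (
        "Strong"
    )
    table.tables[("beta", ())] = np.asarray(0.0)
    assert predict_class(Complex(Genotype.from_string("A"), ERE), table) == (
        "Weak"
    )


# ---------------------------------------------------------------------------
# recentering and the averaging oracle
# ---------------------------------------------------------------------------


def test_recenter_zero_sums_and_score_preservation():
    raw = random_table(tuple("ACDE"), 3, 3, seed=11)
    centered = recenter(raw)
    assert check_zero_sum(centered) < 1e-9
    y0 = np.concatenate(score_landscape(raw))
    y1 = np.concatenate(score_landscape(centered))
    np.testing.assert_allclose(y0, y1, atol=1e-9)


def test_recenter_idempotent():
    centered = random_table(tuple("ACDE"), 3, 3, seed=3, centered=True)
    again = recenter(centered)
    for key in centered.tables:
        np.testing.assert_allclose(
            again.tables[key], centered.tables[key], atol=1e-12
        )


def test_recenter_agrees_with_averaging_oracle():
    raw = random_table(tuple("ACDEF"), 3, 3, seed=5)
    centered = recenter(raw)
    y_ere, y_sre = score_landscape(raw)
    oracle = reffree_coefficients_from_scores(y_ere, y_sre, raw.space, 3)
    for key in centered.tables:
        np.testing.assert_allclose(
            centered.tables[key], oracle.tables[key], atol=1e-10
        )


def test_from_scores_constant():
    space = CoefficientTable.zeros(tuple("ACD"), 2, 2).space
    y = np.full(space.size, 3.25)
    table = reffree_coefficients_from_scores(y, y, space, 2)
    assert float(table.tables[("beta", ())]) == pytest.approx(3.25)
    for (etype, sites), arr in table.tables.items():
        if sites or etype == "sigma":
            np.testing.assert_allclose(arr, 0.0, atol=1e-12)


def test_from_scores_roundtrip_exact():
    truth = random_table(tuple("ACDE"), 3, 3, seed=9, centered=True)
    y_ere, y_sre = score_landscape(truth)
    rec = reffree_coefficients_from_scores(y_ere, y_sre, truth.space, 3)
    for key in truth.tables:
        np.testing.assert_allclose(
            rec.tables[key], truth.tables[key], atol=1e-10
        )


def test_sigma0_is_half_mean_re_difference():
    table = random_table(tuple("ACD"), 2, 2, seed=21)
    y_ere, y_sre = score_landscape(table)
    rec = reffree_coefficients_from_scores(y_ere, y_sre, table.space, 2)
    assert float(rec.tables[("sigma", ())]) == pytest.approx(
        (y_ere.mean() - y_sre.mean()) / 2
    )


def test_from_scores_requires_complete_coverage():
    space = CoefficientTable.zeros(tuple("ACD"), 2, 2).space
    with pytest.raises(InputError):
        reffree_coefficients_from_scores(
            np.zeros(space.size - 1), np.zeros(space.size - 1), space, 2
        )


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------


def test_rescale_targets_and_idempotence(small_truth):
    rescaled = rescale_scores(small_truth)
    y = np.concatenate(score_landscape(rescaled))
    assert y.mean() == pytest.approx(0.0, abs=1e-9)
    assert rescaled.theta_ws == pytest.approx(1.0)
    twice = rescale_scores(rescaled)
    assert twice.theta_nw == pytest.approx(rescaled.theta_nw)
    np.testing.assert_allclose(
        np.concatenate(score_landscape(twice)), y, atol=1e-9
    )


def test_rescale_preserves_class_probabilities(small_truth):
    rescaled = rescale_scores(small_truth)
    y0_e, y0_s = score_landscape(small_truth)
    y1_e, y1_s = score_landscape(rescaled)
    p0 = class_probabilities(
        y0_e, small_truth.theta_nw, small_truth.theta_ws,
        small_truth.link_scale,
    )
    p1 = class_probabilities(
        y1_e, rescaled.theta_nw, rescaled.theta_ws, rescaled.link_scale
    )
    np.testing.assert_allclose(p0, p1, atol=1e-9)


def test_rescale_preserves_fvar(small_truth):
    before = variance_partition(small_truth).per_term
    after = variance_partition(rescale_scores(small_truth)).per_term
    np.testing.assert_allclose(
        before["fvar"].to_numpy(), after["fvar"].to_numpy(), atol=1e-9
    )


def test_rescale_degenerate_threshold():
    table = CoefficientTable.zeros(tuple("AC"), 1, 1)
    with pytest.raises(InputError):
        rescale_scores(table)  # theta_WS == global mean == 0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_misclassification_costs():
    pred = np.array([0, 0, 1, 2, 2])
    obs = np.array([0, 2, 2, 2, 0])
    # costs: 0, 2, 1, 0, 2 -> mean 1.0
    assert weighted_misclassification(pred, obs) == pytest.approx(1.0)
    assert weighted_misclassification(obs, obs) == 0.0


def test_fit_requires_all_classes(small_dataset, small_truth):
    null_only = small_dataset[small_dataset["cls"] == "Null"]
    with pytest.raises(InputError):
        fit(null_only, FitConfig.reduced(), 2, space=small_truth.space)


def test_fit_rejects_duplicate_complexes(small_dataset, small_truth):
    dup = pd.concat([small_dataset, small_dataset.iloc[:1]])
    with pytest.raises(InputError):
        fit(dup, FitConfig.reduced(), 2, space=small_truth.space)


def test_fit_recovers_first_order_architecture():
    """Argmax-labeled synthetic data: refit + recenter recovers the ranking
    of the ground-truth main effects and reproduces the labels."""
    spec = SyntheticSpec(
        alphabet=tuple("ACDEFGHI"),
        n_sites=3,
        max_order=1,
        beta_sd=(1.2,),
        sigma_sd=(0.6,),
        theta_nw=0.3,
        theta_ws=2.3,
        seed=5,
    )
    truth = generate_coefficients(spec)
    dataset = sample_classes(truth, spec)
    result = fit(
        dataset, FitConfig.reduced(seed=2, n_lambda=12), 1, space=truth.space
    )
    fitted = recenter(result.coefficients)
    tv = np.concatenate(
        [truth.tables[k].ravel() for k in truth.tables if len(k[1]) == 1]
    )
    fv = np.concatenate(
        [fitted.tables[k].ravel() for k in truth.tables if len(k[1]) == 1]
    )
    assert spearmanr(tv, fv).statistic > 0.95
    pred = predict_landscape_classes(fitted)
    true = predict_landscape_classes(truth)
    agreement = np.mean(np.concatenate(pred) == np.concatenate(true))
    assert agreement >= 0.99
    # chosen lambda attains the CV minimum
    curve = result.cv_curve
    assert curve.loc[
        curve["lam"] == result.chosen_lambda, "mean_misclassification"
    ].iloc[0] == pytest.approx(curve["mean_misclassification"].min())


def test_fit_and_averaging_oracle_agree(small_spec, small_truth,
                                        small_dataset):
    """Regularized fit + recenter approaches the score-averaging oracle on
    argmax-labeled data up to the link's affine calibration."""
    result = fit(
        small_dataset,
        FitConfig.reduced(seed=3, n_lambda=10),
        2,
        space=small_truth.space,
    )
    fitted = recenter(result.coefficients)
    y_ere, y_sre = score_landscape(fitted)
    oracle = reffree_coefficients_from_scores(y_ere, y_sre, fitted.space, 2)
    for key in fitted.tables:
        np.testing.assert_allclose(
            fitted.tables[key], oracle.tables[key], atol=1e-6
        )


# ---------------------------------------------------------------------------
# diagnostics and calibration
# ---------------------------------------------------------------------------


def test_proportional_odds_diagnostic():
    """Both binary collapses of proportional-odds data estimate the same
    coefficients; a deliberate violation lowers the agreement."""
    spec = SyntheticSpec(
        alphabet=tuple("ACDEFGHI"),
        n_sites=3,
        max_order=1,
        beta_sd=(1.2,),
        sigma_sd=(0.6,),
        theta_nw=0.3,
        theta_ws=2.3,
        seed=5,
    )
    truth = generate_coefficients(spec)
    dataset = sample_classes(truth, spec)
    pairs, corr = check_proportional_odds(
        dataset, max_order=1, space=truth.space
    )
    assert corr > 0.95
    assert len(pairs) > 1
    # violation: relabel the strong class by an unrelated rule
    broken = dataset.copy()
    rng = np.random.default_rng(0)
    strong = rng.random(len(broken)) < 0.15
    broken.loc[strong, "cls"] = "Strong"
    broken.loc[~strong & (broken["cls"] == "Strong"), "cls"] = "Weak"
    _, corr_broken = check_proportional_odds(
        broken, max_order=1, space=truth.space
    )
    assert corr_broken < corr


def test_proportional_odds_degenerate_collapse(small_truth):
    df = pd.DataFrame(
        {
            "genotype": ["AAA", "CCC"],
            "re": ["ERE", "SRE"],
            "cls": ["Null", "Weak"],
        }
    )
    with pytest.raises(InputError):
        check_proportional_odds(df, 1, space=small_truth.space)


def test_calibrate_ddg_exact_line():
    scores = np.array([0.0, 1.0, 2.0, 3.0])
    slope, intercept, r2 = calibrate_ddg(scores, 2 * scores + 1)
    assert slope == pytest.approx(2.0)
    assert intercept == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)


def test_calibrate_ddg_noisy_recovery(rng):
    scores = rng.normal(size=200)
    dg = -1.7 * scores + 0.4 + rng.normal(scale=0.1, size=200)
    slope, intercept, r2 = calibrate_ddg(scores, dg)
    assert slope == pytest.approx(-1.7, abs=0.05)
    assert r2 > 0.9


def test_calibrate_ddg_errors():
    with pytest.raises(InputError):
        calibrate_ddg([1.0, 2.0], [0.0, 1.0])
    with pytest.raises(InputError):
        calibrate_ddg([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
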