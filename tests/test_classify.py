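"""Logistic scorer contracts: ML identities, transfer, aggregation."""

import numpy as np
import pandas as pd
import pytest

from morphoscore import (
    CohortConfig,
    aggregate_individual_means,
    fit_cell_classifier,
    probability_histogram,
    score_cells,
    simulate_feature_table,
)
from morphoscore.classify import ScoringModel, cross_validated_scores
from morphoscore.features import FEATURE_NAMES
from morphoscore.synthetic import planted_effect_vector


@pytest.fixture(scope="module")
def fitted(strong_cohort):
    cfg, table = strong_cohort
    model = fit_cell_classifier(table)
    return cfg, table, model, score_cells(model, table)


def test_probability_mass_balance(null_cohort):
    """Unpenalized in-sample ML fit with intercept: sum p-hat = n1."""
    _, table = null_cohort
    model = fit_cell_classifier(table)
    assert not model.penalized
    scores = score_cells(model, table)
    n1 = int((table["group"] == 1).sum())
    assert scores.cells["probability"].sum() == pytest.approx(n1, rel=1e-6)


def test_no_signal_scores_at_prevalence():
    """With zero-variance-free but signal-less features, class-1 mean
    fitted probability equals the class-1 prevalence."""
    cfg = CohortConfig(n_group0=4, n_group1=2, cells_per_individual=60,
                       effect_size=0.0, affected_count=0, individual_sd=0.0,
                       seed=31)
    table = simulate_feature_table(cfg)
    model = fit_cell_classifier(table)
    scores = score_cells(model, table)
    prevalence = (table["group"] == 1).mean()
    overall = scores.cells["probability"].mean()
    assert overall == pytest.approx(prevalence, rel=1e-6)


def test_separating_feature_triggers_ridge_fallback():
    rng = np.random.default_rng(0)
    n = 60
    table = pd.DataFrame(rng.normal(size=(n, 124)), columns=list(FEATURE_NAMES))
    table["group"] = [0] * 30 + [1] * 30
    table["individual_id"] = ["a"] * 30 + ["b"] * 30
    table["treatment"] = "untreated"
    # one perfectly separating feature
    table[FEATURE_NAMES[0]] = np.r_[rng.normal(-5, 0.1, 30), rng.normal(5, 0.1, 30)]
    model = fit_cell_classifier(table)
    assert model.penalized
    p = score_cells(model, table).cells["probability"].to_numpy()
    assert np.all(p[:30] < 0.01) and np.all(p[30:] > 0.99)


def test_planted_sign_recovered(fitted):
    """Coefficients on affected features point in the planted direction."""
    cfg, _, model, _ = fitted
    delta = planted_effect_vector(cfg)
    affected = delta != 0
    coef = model.coef
    assert (np.sign(coef[affected]) == 1).mean() > 0.8
    # and the combined score separates the classes
    assert model.coef.shape == (124,)


def test_training_table_ordering(fitted):
    _, table, _, scores = fitted
    means = scores.cells.groupby(scores.cells["group"])["probability"].mean()
    assert means[1] > means[0]


def test_zero_model_scores_half(null_cohort):
    _, table = null_cohort
    model = ScoringModel(feature_names=list(FEATURE_NAMES),
                         coef=np.zeros(124), intercept=0.0,
                         std_mean=np.zeros(124), std_sd=np.ones(124),
                         marker_set="combined", coding={0: 0, 1: 1})
    p = score_cells(model, table).cells["probability"]
    assert np.all(p == 0.5)


def test_duplicated_cell_scores_identically(fitted):
    _, table, model, _ = fitted
    dup = pd.concat([table.iloc[[0]], table.iloc[[0]]], ignore_index=True)
    p = score_cells(model, dup).cells["probability"]
    assert p.iloc[0] == p.iloc[1]


def test_affine_feature_rescaling_leaves_scores_unchanged(strong_cohort):
    """Standardization inside the model absorbs any feature gain/offset."""
    _, table = strong_cohort
    rescaled = table.copy()
    col = FEATURE_NAMES[3]
    rescaled[col] = rescaled[col] * 12.5 - 7.0
    p0 = score_cells(fit_cell_classifier(table), table).cells["probability"]
    p1 = score_cells(fit_cell_classifier(rescaled), rescaled).cells["probability"]
    np.testing.assert_allclose(p0, p1, atol=1e-6)


def test_model_json_roundtrip(tmp_path, fitted):
    _, table, model, scores = fitted
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = ScoringModel.from_json(path)
    np.testing.assert_array_equal(loaded.coef, model.coef)
    p = score_cells(loaded, table).cells["probability"]
    np.testing.assert_allclose(p, scores.cells["probability"], rtol=1e-12)


def test_single_class_rejected(null_cohort):
    _, table = null_cohort
    with pytest.raises(ValueError):
        fit_cell_classifier(table[table["group"] == 0])


def test_nonfinite_features_named(null_cohort):
    _, table = null_cohort
    bad = table.copy()
    bad.loc[bad.index[0], FEATURE_NAMES[5]] = np.nan
    with pytest.raises(ValueError, match=FEATURE_NAMES[5].replace(".", r"\.")):
        fit_cell_classifier(bad)


def test_marker_subset_model(strong_cohort):
    _, table = strong_cohort
    model = fit_cell_classifier(table, marker_set="mito")
    assert len(model.coef) == 31
    assert all(c.startswith("mito.") for c in model.feature_names)


class TestAggregation:
    def test_simple_mean(self):
        cells = pd.DataFrame({"probability": [0.2, 0.4, 0.5, 0.5],
                              "individual_id": ["a", "a", "b", "b"],
                              "group": [0, 0, 1, 1],
                              "treatment": "untreated"})
        from morphoscore.classify import ProbabilityScores
        means = aggregate_individual_means(
            ProbabilityScores(cells=cells, marker_set="combined"))
        assert means.set_index("individual_id")["mean_probability"].to_dict() \
            == {"a": pytest.approx(0.3), "b": pytest.approx(0.5)}

    def test_weighted_pooling_identity(self, fitted):
        """Grand mean of cell scores = cell-count-weighted mean of
        individual means."""
        _, _, _, scores = fitted
        means = aggregate_individual_means(scores)
        weighted = (means["mean_probability"] * means["n_cells"]).sum() \
            / means["n_cells"].sum()
        assert weighted == pytest.approx(scores.cells["probability"].mean(),
                                         rel=1e-12)


class TestHistogram:
    def test_counts_conserved_per_group(self, fitted):
        _, _, _, scores = fitted
        hist = probability_histogram(scores, bins=20)
        for group, counts in hist["counts"].items():
            assert counts.sum() == (scores.cells["group"] == group).sum()

    def test_degenerate_scores_occupy_one_bin(self):
        from morphoscore.classify import ProbabilityScores
        cells = pd.DataFrame({"probability": [0.5] * 10,
                              "individual_id": "a", "group": 0,
                              "treatment": "untreated"})
        hist = probability_histogram(
            ProbabilityScores(cells=cells, marker_set="combined"), bins=50)
        assert (hist["counts"][0] > 0).sum() == 1

    def test_uniform_scores_flat(self, rng):
        from morphoscore.classify import ProbabilityScores
        cells = pd.DataFrame({"probability": rng.random(20000),
                              "individual_id": "a", "group": 0,
                              "treatment": "untreated"})
        hist = probability_histogram(
            ProbabilityScores(cells=cells, marker_set="combined"), bins=10)
        counts = hist["counts"][0]
        assert counts.max() - counts.min() < 6 * np.sqrt(2000)


def test_cross_validation_avoids_individual_leakage():
    """In-sample individual AUC saturates at 1 under the null; grouped CV
    does not."""
    from morphoscore import roc_individuals
    cfg = CohortConfig(n_group0=8, n_group1=8, cells_per_individual=100,
                       effect_size=0.0, affected_count=0, individual_sd=0.4,
                       seed=41)
    table = simulate_feature_table(cfg)
    insample = score_cells(fit_cell_classifier(table), table)
    auc_in = roc_individuals(
        insample.individual_means["mean_probability"].to_numpy(),
        insample.individual_means["group"].to_numpy(), positive_label=1).auc
    cv = cross_validated_scores(table, n_folds=4, seed=1)
    auc_cv = roc_individuals(
        cv.individual_means["mean_probability"].to_numpy(),
        cv.individual_means["group"].to_numpy(), positive_label=1).auc
    assert auc_in > 0.95      # leakage saturates the in-sample AUC
    assert auc_cv < auc_in    # held-out scoring deflates it
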