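"""Screening model: design matrix, splits, metrics, bootstrap, calibration."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pars.cohort import Cohort, Visit
from pars.scoring import ParsScoreModel
from pars.screening import (
    FeatureMatrix,
    FittedModel,
    RiskScreeningModel,
    ScreeningError,
    bootstrap_ci,
    build_design_matrix,
    calibration_report,
    coefficient_table,
    evaluate,
    fit_logistic,
    group_kfold,
    patient_strata,
    predict_proba,
    select_threshold,
    stratified_patient_split,
    threshold_report,
    youden_j,
)


def mk_visit(vid, pid, drugs, sex="F", age=60.0):
    return Visit(visit_id=vid, patient_id=pid, date=dt.date(2023, 1, 1),
                 sex=sex, age=age, drugs=frozenset(drugs))


@pytest.fixture(scope="module")
def labeled(small_sim_module):
    from pars.components import components_frame

    _, kb, cohort, _ = small_sim_module
    comp = components_frame(cohort, kb)
    labels = ParsScoreModel(comp).fit().high_risk
    return cohort, labels


@pytest.fixture(scope="module")
def small_sim_module():
    from pars.synth import SynthConfig, generate_cohort, generate_knowledge_base

    cfg = SynthConfig(n_patients=150)
    kb = generate_knowledge_base(cfg, seed=43)
    cohort, truth = generate_cohort(cfg, seed=42, kb=kb)
    return cfg, kb, cohort, truth


# ---------------------------------------------------------------- features

def test_design_matrix_dimensions_and_encoding():
    cohort = Cohort([
        mk_visit("v1", "p1", {"a", "c"}, sex="F", age=60),
        mk_visit("v2", "p2", {"b", "c"}, sex="M", age=40),
    ])
    fm = build_design_matrix(cohort)
    assert fm.shape == (2, 3 + 2)
    assert fm.columns == ["a", "b", "c", "age", "sex"]
    X = fm.X.toarray()
    assert list(X[0]) == [1, 0, 1, 60, 1]   # F = 1
    assert list(X[1]) == [0, 1, 1, 40, 0]   # M = 0


def test_out_of_vocabulary_drugs_dropped():
    cohort = Cohort([mk_visit("v1", "p1", {"a", "zzz"})])
    fm = build_design_matrix(cohort, vocabulary=["a", "b"])
    assert fm.X.toarray()[0, :2].tolist() == [1, 0]


def test_engineered_components_never_enter_the_design(labeled):
    cohort, _ = labeled
    fm = build_design_matrix(cohort)
    forbidden = {"ddi_score", "has_polypharmacy", "azcert_max", "acb_score",
                 "sero_any", "pars", "pars_rescaled", "high_risk"}
    assert not forbidden & set(fm.columns)


# ------------------------------------------------------------------ splits

def test_combined_stratification_yields_eight_strata(labeled):
    cohort, labels = labeled
    strata = patient_strata(cohort, labels, "highrisk_age_sex")
    assert strata.nunique() == 8


def test_split_deterministic_and_disjoint(labeled):
    cohort, labels = labeled
    s1 = stratified_patient_split(cohort, labels, "highrisk", seed=7)
    s2 = stratified_patient_split(cohort, labels, "highrisk", seed=7)
    assert s1.train_patients == s2.train_patients
    assert not s1.train_patients & s1.test_patients
    assert s1.train_patients | s1.test_patients == set(cohort.patient_ids)
    # roughly 80-20 by patient
    frac = len(s1.test_patients) / cohort.n_patients
    assert 0.15 < frac < 0.25


def test_group_kfold_partitions_patients():
    cohort = Cohort([
        mk_visit(f"v{i}{j}", f"p{i}", {"a", "b"})
        for i in range(10) for j in range(i % 3 + 1)
    ])
    plans = group_kfold(cohort, k=5)
    test_sets = [p.test_patients for p in plans]
    assert all(len(s) == 2 for s in test_sets)
    assert set().union(*test_sets) == set(cohort.patient_ids)
    for i, a in enumerate(test_sets):
        for b in test_sets[i + 1:]:
            assert not a & b
    # all visits of a patient stay in one fold
    for p in plans:
        for v in cohort:
            assert (v.patient_id in p.test_patients) == (
                v.visit_id in set(p.test_visit_ids(cohort)))


def test_group_kfold_needs_enough_patients():
    cohort = Cohort([mk_visit("v1", "p1", {"a", "b"})])
    with pytest.raises(ScreeningError):
        group_kfold(cohort, k=5)


# --------------------------------------------------------------------- fit

def _toy_features(X):
    X = np.asarray(X, float)
    return FeatureMatrix(X=sp.csr_matrix(X), columns=[f"f{i}" for i in range(X.shape[1])],
                         visit_ids=[f"v{i}" for i in range(X.shape[0])],
                         vocabulary=[f"f{i}" for i in range(X.shape[1])])


def test_separable_toy_data_fits_perfectly():
    X = [[0, 0], [0, 1], [1, 0], [1, 1]] * 5
    y = [0, 0, 1, 1] * 5
    m = fit_logistic(_toy_features(X), np.array(y))
    proba = predict_proba(m, _toy_features(X))
    assert (((proba >= 0.5).astype(int)) == y).all()


def test_single_class_training_errors():
    with pytest.raises(ScreeningError):
        fit_logistic(_toy_features([[0], [1]]), np.array([1, 1]))


def test_permuted_labels_give_chance_auc(labeled):
    cohort, labels = labeled
    rng = np.random.default_rng(0)
    noise = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
    model = RiskScreeningModel(cohort, noise, drugs_only=True)
    res = model.fit(model.patient_split(seed=0))
    assert abs(res.metrics()["auc"] - 0.5) < 0.12


def test_zero_model_predicts_half_and_alert_is_inclusive():
    m = FittedModel(intercept=0.0, coef=pd.Series([0.0, 0.0], index=["f0", "f1"]),
                    vocabulary=["f0", "f1"], C=1.0, age_params=None)
    fm = _toy_features([[1, 0], [0, 1]])
    assert (predict_proba(m, fm) == 0.5).all()
    from pars.screening import predictions_frame

    preds = predictions_frame(m, fm, threshold=0.5)
    assert (preds["alert"] == 1).all()  # 0.5 >= 0.5, inclusive


def test_probability_monotone_in_positive_feature():
    m = FittedModel(intercept=-1.0, coef=pd.Series([2.0], index=["f0"]),
                    vocabulary=["f0"], C=1.0, age_params=None)
    p0 = predict_proba(m, _toy_features([[0.0]]))[0]
    p1 = predict_proba(m, _toy_features([[1.0]]))[0]
    assert p1 > p0


def test_column_mismatch_rejected():
    m = FittedModel(intercept=0.0, coef=pd.Series([0.0], index=["other"]),
                    vocabulary=["other"], C=1.0, age_params=None)
    with pytest.raises(ScreeningError):
        predict_proba(m, _toy_features([[1.0]]))


def test_model_json_round_trip(tmp_path, labeled):
    cohort, labels = labeled
    model = RiskScreeningModel(cohort, labels)
    res = model.fit(model.patient_split(seed=3))
    path = tmp_path / "model.json"
    res.fitted.to_json(path)
    again = FittedModel.from_json(path)
    fm = build_design_matrix(cohort, vocabulary=again.vocabulary,
                             age_params=again.age_params)
    assert np.allclose(predict_proba(again, fm), predict_proba(res.fitted, fm))


# ----------------------------------------------------------------- metrics

def test_confusion_arithmetic():
    m = evaluate([1, 1, 0, 0], [1, 0, 1, 0], threshold=0.5)
    assert m["precision_1"] == 0.5 and m["recall_1"] == 0.5 and m["accuracy"] == 0.5


def test_perfect_probabilities():
    m = evaluate([1, 1, 0, 0], [1, 1, 0, 0], threshold=0.5)
    assert m["auc"] == 1.0 and m["brier"] == 0.0


def test_auc_matches_concordance_oracle():
    rng = np.random.default_rng(6)
    proba = rng.random(20)
    y = rng.integers(0, 2, 20)
    if y.sum() in (0, 20):
        y[0] = 1 - y[0]
    # O(n^2) pairwise concordance with midrank tie handling
    pos, neg = proba[y == 1], proba[y == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert abs(evaluate(proba, y)["auc"] - conc / (len(pos) * len(neg))) < 1e-12


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(7)
    proba = rng.random(50)
    y = rng.integers(0, 2, 50)
    y[0], y[1] = 0, 1
    a1 = evaluate(proba, y)["auc"]
    a2 = evaluate(1 / (1 + np.exp(-(5 * proba - 2))), y)["auc"]
    assert abs(a1 - a2) < 1e-12


def test_single_class_auc_undefined():
    with pytest.raises(ScreeningError):
        evaluate([0.2, 0.8], [1, 1])


def test_perfect_classifier_youden_is_one():
    proba = np.array([0.9, 0.8, 0.1, 0.2])
    y = np.array([1, 1, 0, 0])
    assert youden_j(proba, y, 0.5) == 1.0
    t = select_threshold(proba, y, "youden")
    assert youden_j(proba, y, t) == 1.0


def test_degenerate_constant_predictions_fall_back_to_grid_minimum():
    proba = np.full(10, 0.2)
    y = np.zeros(10, int)
    assert select_threshold(proba, y, "f1") == 0.30


def test_selected_thresholds_never_consult_test_labels(labeled):
    cohort, labels = labeled
    model = RiskScreeningModel(cohort, labels)
    res = model.fit(model.patient_split(seed=1))
    t_f1 = select_threshold(res.train_proba, res.y_train, "f1")
    t_j = select_threshold(res.train_proba, res.y_train, "youden")
    rng = np.random.default_rng(0)
    rep1 = threshold_report(res.train_proba, res.y_train, res.test_proba, res.y_test)
    rep2 = threshold_report(res.train_proba, res.y_train, res.test_proba,
                            rng.permutation(res.y_test))
    # permuting test labels changes metrics but not the selected cutoffs
    assert rep1.loc["f1_optimal_train", "threshold"] == t_f1
    assert rep2.loc["f1_optimal_train", "threshold"] == t_f1
    assert rep2.loc["youden_optimal_train", "threshold"] == t_j


def test_threshold_report_has_grid_and_optima(labeled):
    cohort, labels = labeled
    model = RiskScreeningModel(cohort, labels)
    res = model.fit(model.patient_split(seed=1))
    rep = res.threshold_report()
    assert {"fixed_0.30", "fixed_0.40", "fixed_0.50", "fixed_0.60",
            "f1_optimal_train", "youden_optimal_train"} <= set(rep.index)
    assert rep["youden_j"].between(-1, 1).all()


# ------------------------------------------------------------- calibration

def test_calibration_exact_cases():
    y = np.array([0, 1] * 10)
    tab, brier = calibration_report(y.astype(float), y, bins=10)
    assert brier == 0.0
    tab2, brier2 = calibration_report(np.full(20, 0.5), y, bins=10)
    assert brier2 == 0.25
    assert tab["count"].sum() == 20 and tab2["count"].sum() == 20


def test_calibration_needs_enough_points():
    with pytest.raises(ScreeningError):
        calibration_report([0.1, 0.2], [0, 1], bins=10)


def test_calibration_bins_ordered(labeled):
    cohort, labels = labeled
    model = RiskScreeningModel(cohort, labels)
    res = model.fit(model.patient_split(seed=1))
    tab, _ = res.calibration()
    assert tab["mean_predicted"].is_monotonic_increasing
    assert tab["count"].sum() == len(res.y_test)


# --------------------------------------------------------------- bootstrap

def test_bootstrap_zero_variance_statistic():
    ci = bootstrap_ci(lambda pats: 1.0, np.array(["a", "b", "c"]), B=50, seed=0)
    assert ci["low"] == ci["high"] == 1.0


def test_bootstrap_deterministic_and_ordered():
    rng = np.random.default_rng(8)
    vals = {f"p{i}": rng.normal() for i in range(30)}

    def stat(pats):
        return float(np.mean([vals[p] for p in pats]))

    ids = np.array(list(vals))
    c1 = bootstrap_ci(stat, ids, B=200, seed=5)
    c2 = bootstrap_ci(stat, ids, B=200, seed=5)
    assert c1 == c2
    point = stat(list(ids))
    assert c1["low"] <= point <= c1["high"]


def test_bootstrap_coverage_close_to_nominal():
    """95% percentile interval for a patient-level mean covers the truth
    ~95% of the time across simulations."""
    rng = np.random.default_rng(9)
    hits = 0
    n_sim, n_pat = 150, 40
    for _ in range(n_sim):
        vals = dict(enumerate(rng.normal(size=n_pat)))
        ids = np.array(list(vals))

        def stat(pats, vals=vals):
            return float(np.mean([vals[p] for p in pats]))

        ci = bootstrap_ci(stat, ids, B=200, seed=int(rng.integers(2**31)))
        hits += ci["low"] <= 0.0 <= ci["high"]
    assert abs(hits / n_sim - 0.95) < 0.06


# ------------------------------------------------------------ coefficients

def test_coefficient_table_support_rule(labeled):
    cohort, labels = labeled
    model = RiskScreeningModel(cohort, labels, drugs_only=True)
    res = model.fit(model.patient_split(seed=2))
    tab = res.coefficient_table(min_support=20)
    # support equals a direct visit-count oracle, and respects the floor
    for row in tab.itertuples():
        assert row.support == sum(row.drug in v.drugs for v in cohort)
        assert row.support >= 20
    assert np.allclose(tab["odds_ratio"], np.exp(tab["coefficient"]))
    assert tab["coefficient"].is_monotonic_decreasing


def test_zero_coefficient_gives_unit_odds_ratio():
    cohort = Cohort([mk_visit(f"v{i}", f"p{i}", {"a", "b"}) for i in range(25)])
    m = FittedModel(intercept=0.0, coef=pd.Series({"a": 0.0, "b": 1.0}),
                    vocabulary=["a", "b"], C=1.0, age_params=None)
    tab = coefficient_table(m, cohort, min_support=20)
    assert float(tab.loc[tab.drug == "a", "odds_ratio"].iloc[0]) == 1.0


# ------------------------------------------------------------------- e2e

def test_cv_and_heldout_discrimination_agree_on_strong_signal():
    from pars.components import components_frame
    from pars.synth import SynthConfig, generate_cohort, generate_knowledge_base

    cfg = SynthConfig.strong_signal(n_patients=250)
    kb = generate_knowledge_base(cfg, seed=13)
    cohort, _ = generate_cohort(cfg, seed=12, kb=kb)
    comp = components_frame(cohort, kb)
    labels = ParsScoreModel(comp).fit().high_risk
    model = RiskScreeningModel(cohort, labels, drugs_only=True)
    heldout = model.fit(model.patient_split(seed=12)).metrics()["auc"]
    pooled = model.cross_validate(k=5).pooled_metrics()["auc"]
    assert heldout > 0.8 and pooled > 0.8
    assert abs(heldout - pooled) < 0.1
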