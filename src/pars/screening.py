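"""Drug-indicator logistic screening model with patient-level validation.

An L2-regularized logistic regression predicts the per-visit High-risk label
from the prescribed drugs only (one sparse binary indicator per active
substance in the training vocabulary) plus age (continuous) and sex (F=1,
M=0).  The engineered risk components and the composite score itself are
deliberately excluded from the predictors: the model screens, the score
defines the label.

Validation follows three schemes, all at the *patient* level so that no
patient's visits span train and test:

* 80-20 split stratified by a patient indicator of having >= 1 High-risk visit;
* 80-20 split with combined stratification by age group (<65 / >=65), sex,
  and the high-risk indicator (8 strata);
* 5-fold GroupKFold with patient id as the group.

A fixed probability cutoff of 0.30 (inclusive) converts predicted
probabilities into screening alerts; F1- and Youden-optimal alternatives are
selected on the training set only.  Uncertainty uses patient-level bootstrap
resampling (percentile intervals, 2,000 replicates by default), and
calibration is summarized by the Brier score with 10 quantile reliability
bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    brier_score_loss,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GroupKFold, train_test_split

from .cohort import Cohort

OPERATING_THRESHOLD = 0.30
THRESHOLD_GRID = (0.30, 0.40, 0.50, 0.60)
AGE_CUTOFF = 65.0
DEFAULT_BOOTSTRAP = 2000

#: feature names the design matrix must never contain (leakage audit)
FORBIDDEN_FEATURES = frozenset(
    {"ddi_score", "has_polypharmacy", "azcert_max", "azcert_sum", "acb_score",
     "sero_count", "sero_any", "pars", "pars_rescaled", "high_risk"}
)


class ScreeningError(ValueError):
    pass


# ---------------------------------------------------------------- features

@dataclass
class FeatureMatrix:
    """Sparse visit-by-feature design matrix.

    Columns are the drug vocabulary (binary indicators) followed by ``age``
    and ``sex`` (F=1, M=0).  Test-time drugs outside the vocabulary are
    dropped.
    """

    X: sp.csr_matrix
    columns: list
    visit_ids: list
    vocabulary: list
    age_params: tuple | None = None  # (mean, sd) when age is standardized

    @property
    def shape(self):
        return self.X.shape


def build_design_matrix(
    cohort: Cohort,
    vocabulary: list | None = None,
    standardize_age: bool = False,
    age_params: tuple | None = None,
) -> FeatureMatrix:
    """Drug-indicator + demographics design matrix.

    Training mode (``vocabulary=None``) derives the vocabulary from the
    cohort (sorted unique drugs) and, if requested, fits the age scaler;
    application mode reuses both, ignoring out-of-vocabulary drugs.
    """
    if len(cohort) == 0:
        raise ScreeningError("empty cohort")
    if vocabulary is None:
        vocab = sorted({d for v in cohort for d in v.drugs})
    else:
        vocab = list(vocabulary)
        if not vocab:
            raise ScreeningError("empty vocabulary in application mode")
    bad = FORBIDDEN_FEATURES.intersection(vocab)
    if bad:
        raise ScreeningError(f"engineered components leaked into vocabulary: {sorted(bad)}")
    col_of = {d: j for j, d in enumerate(vocab)}

    rows, cols = [], []
    ages = np.empty(len(cohort))
    sexes = np.empty(len(cohort))
    visit_ids = []
    for i, v in enumerate(cohort):
        visit_ids.append(v.visit_id)
        ages[i] = v.age
        sexes[i] = 1.0 if v.sex == "F" else 0.0
        for d in v.drugs:
            j = col_of.get(d)
            if j is not None:
                rows.append(i)
                cols.append(j)
    drug_block = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(cohort), len(vocab))
    )

    if standardize_age and age_params is None:
        mu, sdev = float(ages.mean()), float(ages.std(ddof=0)) or 1.0
        age_params = (mu, sdev)
    if age_params is not None:
        ages = (ages - age_params[0]) / age_params[1]

    X = sp.hstack([drug_block, sp.csr_matrix(np.column_stack([ages, sexes]))]).tocsr()
    return FeatureMatrix(
        X=X, columns=vocab + ["age", "sex"], visit_ids=visit_ids,
        vocabulary=vocab, age_params=age_params,
    )


# ------------------------------------------------------------------ splits

@dataclass
class SplitPlan:
    """Disjoint patient-level train/test assignment."""

    train_patients: frozenset
    test_patients: frozenset
    scheme: str
    seed: int | None = None
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise ScreeningError("patients span train and test")

    def train_visit_ids(self, cohort: Cohort) -> list:
        return [v.visit_id for v in cohort if v.patient_id in self.train_patients]

    def test_visit_ids(self, cohort: Cohort) -> list:
        return [v.visit_id for v in cohort if v.patient_id in self.test_patients]


def patient_strata(cohort: Cohort, labels: pd.Series, scheme: str) -> pd.Series:
    """Per-patient stratification label.

    ``highrisk``: binary indicator of >= 1 High-risk visit.
    ``highrisk_age_sex``: (age<65 / >=65) x (F/M) x (high-risk yes/no),
    i.e. 8 possible strata; patient age is taken at the first visit.
    """
    from .cohort import patient_table

    pt = patient_table(cohort)
    hr = {}
    for pid in pt.index:
        vids = [v.visit_id for v in cohort.patient_visits(pid)]
        hr[pid] = int(labels.loc[vids].max())
    pt["high_risk"] = pd.Series(hr)
    if scheme == "highrisk":
        return pt["high_risk"].astype(str)
    if scheme == "highrisk_age_sex":
        age_grp = np.where(pt["age"] >= AGE_CUTOFF, "65+", "<65")
        return pd.Series(
            [f"{a}|{s}|hr{h}" for a, s, h in zip(age_grp, pt["sex"], pt["high_risk"])],
            index=pt.index,
        )
    raise ScreeningError(f"unknown scheme {scheme!r}")


def _merge_small_strata(strata: pd.Series, notes: list) -> pd.Series:
    """Merge strata with < 2 patients into the stratum differing only in age group."""
    strata = strata.copy()
    counts = strata.value_counts()
    for label in counts[counts < 2].index:
        if "|" in label:
            age_grp, rest = label.split("|", 1)
            partner = ("65+" if age_grp == "<65" else "<65") + "|" + rest
            target = partner if (strata == partner).any() else counts.idxmax()
        else:
            target = counts.idxmax()
        notes.append(f"stratum {label!r} (<2 patients) merged into {target!r}")
        strata[strata == label] = target
    return strata


def stratified_patient_split(
    cohort: Cohort,
    labels: pd.Series,
    scheme: str = "highrisk",
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """80-20 (by default) patient-level split, stratified per ``scheme``.

    Deterministic given the seed; every visit of a patient lands on one side.
    """
    strata = patient_strata(cohort, labels, scheme)
    notes: list = []
    merged = _merge_small_strata(strata, notes)
    if notes:
        warnings.warn("; ".join(notes), stacklevel=2)
    patients = np.array(merged.index)
    train, test = train_test_split(
        patients, test_size=test_fraction, random_state=seed, stratify=merged.to_numpy()
    )
    return SplitPlan(frozenset(train), frozenset(test), scheme=scheme, seed=seed, notes=notes)


def group_kfold(cohort: Cohort, k: int = 5) -> list[SplitPlan]:
    """k patient-grouped folds: each patient's visits reside in one fold."""
    patients = np.array(cohort.patient_ids)
    if len(patients) < k:
        raise ScreeningError(f"need >= {k} patients, got {len(patients)}")
    gkf = GroupKFold(n_splits=k)
    plans = []
    for i, (tr, te) in enumerate(gkf.split(patients, groups=patients)):
        plans.append(
            SplitPlan(frozenset(patients[tr]), frozenset(patients[te]), scheme=f"groupkfold{k}-fold{i}")
        )
    return plans


# --------------------------------------------------------------- model fit

@dataclass
class FittedModel:
    """Fitted logistic screener: coefficients, vocabulary, settings."""

    intercept: float
    coef: pd.Series  # indexed by feature name
    vocabulary: list
    C: float
    age_params: tuple | None
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "coef": self.coef.to_dict(),
            "columns": list(self.coef.index),
            "vocabulary": self.vocabulary,
            "C": self.C,
            "age_params": list(self.age_params) if self.age_params else None,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            intercept=p["intercept"],
            coef=pd.Series(p["coef"]).reindex(p["columns"]),
            vocabulary=p["vocabulary"],
            C=p["C"],
            age_params=tuple(p["age_params"]) if p["age_params"] else None,
            metadata=p.get("metadata", {}),
        )


def fit_logistic(
    features: FeatureMatrix,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 5000,
    metadata: dict | None = None,
) -> FittedModel:
    """Penalized (L2) maximum-likelihood logistic fit; deterministic."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ScreeningError("single-class training data")
    # L2 penalty is sklearn's default; strength surfaces through C
    clf = LogisticRegression(C=C, tol=tol, max_iter=max_iter, solver="lbfgs")
    clf.fit(features.X, y)
    return FittedModel(
        intercept=float(clf.intercept_[0]),
        coef=pd.Series(clf.coef_[0], index=features.columns),
        vocabulary=features.vocabulary,
        C=C,
        age_params=features.age_params,
        metadata=dict(metadata or {}),
    )


def predict_proba(model: FittedModel, features: FeatureMatrix) -> np.ndarray:
    """P(high-risk) per visit via the logistic link; always strictly in (0,1)."""
    if list(features.columns) != list(model.coef.index):
        raise ScreeningError("feature columns do not match the model")
    eta = features.X @ model.coef.to_numpy() + model.intercept
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


def predictions_frame(
    model: FittedModel, features: FeatureMatrix, threshold: float = OPERATING_THRESHOLD
) -> pd.DataFrame:
    proba = predict_proba(model, features)
    return pd.DataFrame(
        {"proba": proba, "alert": (proba >= threshold).astype(int)},
        index=pd.Index(features.visit_ids, name="visit_id"),
    )


# ----------------------------------------------------------------- metrics

def evaluate(proba: np.ndarray, y: np.ndarray, threshold: float = OPERATING_THRESHOLD) -> dict:
    """Threshold-free AUC plus positive-class metrics at an inclusive cutoff."""
    proba = np.asarray(proba, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ScreeningError("AUC undefined for single-class labels")
    pred = (proba >= threshold).astype(int)
    return {
        "auc": float(roc_auc_score(y, proba)),
        "accuracy": float(accuracy_score(y, pred)),
        "precision_1": float(precision_score(y, pred, zero_division=0)),
        "recall_1": float(recall_score(y, pred, zero_division=0)),
        "f1_1": float(f1_score(y, pred, zero_division=0)),
        "brier": float(brier_score_loss(y, proba)),
        "threshold": float(threshold),
        "n": int(len(y)),
    }


def youden_j(proba: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """J = recall + specificity - 1 at an inclusive cutoff."""
    y = np.asarray(y, int)
    pred = (np.asarray(proba, float) >= threshold).astype(int)
    pos, neg = y == 1, y == 0
    recall = pred[pos].mean() if pos.any() else 0.0
    spec = (1 - pred[neg]).mean() if neg.any() else 0.0
    return float(recall + spec - 1.0)


def select_threshold(proba: np.ndarray, y: np.ndarray, criterion: str) -> float:
    """Best cutoff over the sorted unique probabilities (train set only).

    ``criterion`` is ``f1`` or ``youden``.  Degenerate case (constant
    predictions, or F1 zero everywhere): falls back to the grid minimum.
    """
    cands = np.unique(np.asarray(proba, float))
    y = np.asarray(y, int)
    best_t, best_v = None, -np.inf
    for t in cands:
        pred = (proba >= t).astype(int)
        if criterion == "f1":
            v = f1_score(y, pred, zero_division=0)
        elif criterion == "youden":
            v = youden_j(proba, y, t)
        else:
            raise ScreeningError(f"unknown criterion {criterion!r}")
        if v > best_v:
            best_t, best_v = float(t), float(v)
    if best_v <= 0.0:
        return float(min(THRESHOLD_GRID))
    return best_t


def threshold_report(
    train_proba, y_train, test_proba, y_test, grid=THRESHOLD_GRID
) -> pd.DataFrame:
    """Metrics on the test set for the fixed grid plus train-selected optima.

    The F1- and Youden-optimal rows are selected on the training set only and
    then evaluated on test; test labels never influence the selection.
    """
    rows = {}
    for t in grid:
        rows[f"fixed_{t:.2f}"] = evaluate(test_proba, y_test, t)
    t_f1 = select_threshold(train_proba, y_train, "f1")
    t_j = select_threshold(train_proba, y_train, "youden")
    rows["f1_optimal_train"] = evaluate(test_proba, y_test, t_f1)
    rows["youden_optimal_train"] = evaluate(test_proba, y_test, t_j)
    rep = pd.DataFrame(rows).T
    rep["youden_j"] = [youden_j(test_proba, y_test, t) for t in rep["threshold"]]
    return rep


def calibration_report(proba, y, bins: int = 10) -> tuple[pd.DataFrame, float]:
    """Reliability table with quantile bins plus the overall Brier score.

    Bins are deciles of the predicted probability (duplicate edges dropped on
    heavily tied inputs); bin counts conserve n.  For cross-validated models
    call this on the pooled out-of-fold predictions.
    """
    proba = np.asarray(proba, float)
    y = np.asarray(y, int)
    if len(proba) < bins:
        raise ScreeningError(f"need >= {bins} observations, got {len(proba)}")
    binned = pd.qcut(proba, q=bins, labels=False, duplicates="drop")
    if pd.isna(binned).all():  # constant predictions: a single bin
        binned = np.zeros(len(proba), dtype=int)
    tab = (
        pd.DataFrame({"bin": binned, "proba": proba, "y": y})
        .groupby("bin")
        .agg(mean_predicted=("proba", "mean"), observed_rate=("y", "mean"), count=("y", "size"))
        .reset_index(drop=True)
    )
    brier = float(np.mean((proba - y) ** 2))
    return tab, brier


# --------------------------------------------------------------- bootstrap

def bootstrap_ci(
    statistic,
    patient_ids: np.ndarray,
    B: int = DEFAULT_BOOTSTRAP,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Patient-level percentile bootstrap.

    ``statistic(selected_patient_list) -> float`` is recomputed on each
    replicate drawn by resampling *patients* with replacement (a patient's
    visits always move together).  Replicates where the statistic is
    undefined (raise ``ScreeningError``) are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    unique = np.asarray(sorted(set(patient_ids)))
    stats, dropped = [], 0
    for _ in range(B):
        sample = rng.choice(unique, size=len(unique), replace=True)
        try:
            stats.append(float(statistic(list(sample))))
        except ScreeningError:
            dropped += 1
    if not stats:
        raise ScreeningError("statistic undefined in every bootstrap replicate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return {"low": float(lo), "high": float(hi), "n_replicates": len(stats), "n_dropped": dropped}


def coefficient_table(
    model: FittedModel,
    cohort: Cohort,
    min_support: int = 20,
    ci: dict | None = None,
) -> pd.DataFrame:
    """Per-drug coefficients, odds ratios and cohort-wide support.

    Support is the number of visits in the *full* cohort containing the drug;
    only drugs with support >= ``min_support`` are reported (rare exposures
    give unstable estimates).  ``ci`` optionally maps drug -> (low, high)
    bootstrap bounds on the odds ratio.  Sorted by coefficient, descending.
    """
    support = {d: 0 for d in model.vocabulary}
    for v in cohort:
        for d in v.drugs:
            if d in support:
                support[d] += 1
    rows = []
    for d in model.vocabulary:
        if support[d] < min_support:
            continue
        coef = float(model.coef[d])
        row = {"drug": d, "coefficient": coef, "odds_ratio": float(np.exp(coef)), "support": support[d]}
        if ci and d in ci:
            row["or_ci_low"], row["or_ci_high"] = ci[d]
        rows.append(row)
    tab = pd.DataFrame(rows)
    if len(tab):
        tab = tab.sort_values("coefficient", ascending=False).reset_index(drop=True)
    return tab


# --------------------------------------------- statsmodels-style interface

class RiskScreeningModel:
    """Screening classifier for the High-risk label, built from a cohort.

    Parameters
    ----------
    cohort : Cohort
        Filtered visit cohort.
    labels : Series
        visit_id -> {0,1} High-risk label (from a PARS fit whose reference
        set respects the split in use).
    drugs_only : bool
        Drop age and sex, keeping drug indicators only (the variant used to
        rank drugs by association).

    Examples
    --------
    >>> sm = RiskScreeningModel(cohort, labels)
    >>> res = sm.fit(sm.patient_split(seed=42))
    >>> res.metrics()                 # at the 0.30 operating point
    >>> res.threshold_report()
    >>> cv = sm.cross_validate(k=5)   # pooled out-of-fold results
    """

    def __init__(self, cohort: Cohort, labels: pd.Series, C: float = 1.0,
                 standardize_age: bool = True, drugs_only: bool = False):
        missing = [v.visit_id for v in cohort if v.visit_id not in labels.index]
        if missing:
            raise ScreeningError(f"unlabeled visits: {missing[:5]}")
        self.cohort = cohort
        self.labels = labels
        self.C = C
        self.standardize_age = standardize_age
        self.drugs_only = drugs_only

    def _features(self, cohort, vocabulary=None, age_params=None) -> FeatureMatrix:
        fm = build_design_matrix(
            cohort, vocabulary=vocabulary,
            standardize_age=self.standardize_age and not self.drugs_only,
            age_params=age_params,
        )
        if self.drugs_only:
            fm = FeatureMatrix(
                X=fm.X[:, : len(fm.vocabulary)],
                columns=list(fm.vocabulary),
                visit_ids=fm.visit_ids,
                vocabulary=fm.vocabulary,
            )
        return fm

    def patient_split(self, scheme: str = "highrisk", test_fraction: float = 0.2,
                      seed: int = 0) -> SplitPlan:
        return stratified_patient_split(self.cohort, self.labels, scheme, test_fraction, seed)

    def fit(self, split: SplitPlan) -> "ScreeningResults":
        train = self.cohort.subset_patients(split.train_patients)
        test = self.cohort.subset_patients(split.test_patients)
        fm_train = self._features(train)
        y_train = self.labels.loc[fm_train.visit_ids].to_numpy(int)
        fitted = fit_logistic(
            fm_train, y_train, C=self.C,
            metadata={"scheme": split.scheme, "seed": split.seed, "n_train": len(train)},
        )
        fm_test = self._features(test, vocabulary=fitted.vocabulary, age_params=fitted.age_params)
        return ScreeningResults(self, fitted, split, fm_train, y_train, fm_test,
                                self.labels.loc[fm_test.visit_ids].to_numpy(int))

    def cross_validate(self, k: int = 5) -> "CrossValResults":
        """Patient-grouped k-fold; returns per-fold metrics and pooled
        out-of-fold predictions (the unbiased basis for calibration)."""
        folds = group_kfold(self.cohort, k)
        fold_results = [self.fit(plan) for plan in folds]
        return CrossValResults(self, fold_results)


class ScreeningResults:
    """Fitted screener with its held-out evaluation."""

    def __init__(self, model, fitted: FittedModel, split: SplitPlan,
                 fm_train, y_train, fm_test, y_test):
        self.model = model
        self.fitted = fitted
        self.split = split
        self._fm_train, self.y_train = fm_train, y_train
        self._fm_test, self.y_test = fm_test, y_test
        self.train_proba = predict_proba(fitted, fm_train)
        self.test_proba = predict_proba(fitted, fm_test)

    @property
    def test_visit_ids(self):
        return list(self._fm_test.visit_ids)

    def predictions(self, threshold: float = OPERATING_THRESHOLD) -> pd.DataFrame:
        return pd.DataFrame(
            {"proba": self.test_proba, "alert": (self.test_proba >= threshold).astype(int),
             "y": self.y_test},
            index=pd.Index(self._fm_test.visit_ids, name="visit_id"),
        )

    def metrics(self, threshold: float = OPERATING_THRESHOLD) -> dict:
        return evaluate(self.test_proba, self.y_test, threshold)

    def threshold_report(self, grid=THRESHOLD_GRID) -> pd.DataFrame:
        return threshold_report(self.train_proba, self.y_train,
                                self.test_proba, self.y_test, grid)

    def calibration(self, bins: int = 10):
        return calibration_report(self.test_proba, self.y_test, bins)

    def auc_ci(self, B: int = DEFAULT_BOOTSTRAP, level: float = 0.95, seed: int = 0) -> dict:
        """Patient-bootstrap CI for the held-out AUC."""
        test = self.model.cohort.subset_patients(self.split.test_patients)
        proba = pd.Series(self.test_proba, index=self._fm_test.visit_ids)

        def stat(patients):
            vids = [v.visit_id for p in patients for v in test.patient_visits(p)]
            y = self.model.labels.loc[vids].to_numpy(int)
            if len(np.unique(y)) < 2:
                raise ScreeningError("single-class replicate")
            return roc_auc_score(y, proba.loc[vids].to_numpy())

        return bootstrap_ci(stat, np.array(sorted(self.split.test_patients)),
                            B=B, level=level, seed=seed)

    def coefficient_table(self, min_support: int = 20, bootstrap_B: int = 0,
                          seed: int = 0, level: float = 0.95) -> pd.DataFrame:
        """OR table; with ``bootstrap_B`` > 0 adds patient-bootstrap CIs on
        the training set (refitting the model per replicate)."""
        ci = None
        if bootstrap_B:
            ci = self._or_bootstrap(min_support, bootstrap_B, seed, level)
        return coefficient_table(self.fitted, self.model.cohort, min_support, ci)

    def _or_bootstrap(self, min_support, B, seed, level) -> dict:
        train = self.model.cohort.subset_patients(self.split.train_patients)
        rng = np.random.default_rng(seed)
        patients = np.array(sorted(self.split.train_patients))
        reported = set(coefficient_table(self.fitted, self.model.cohort, min_support)["drug"])
        draws: dict[str, list] = {d: [] for d in reported}
        from .cohort import Visit

        for _ in range(B):
            sample = rng.choice(patients, size=len(patients), replace=True)
            visits, ys = [], []
            j = 0
            for i, p in enumerate(sample):
                # re-key so patients drawn twice keep distinct identities
                for v in train.patient_visits(p):
                    visits.append(Visit(visit_id=str(j), patient_id=f"b{i}", date=v.date,
                                        sex=v.sex, age=v.age, drugs=v.drugs,
                                        diagnosis=v.diagnosis))
                    ys.append(int(self.model.labels.loc[v.visit_id]))
                    j += 1
            y = np.array(ys, dtype=int)
            if len(np.unique(y)) < 2:
                continue
            boot = Cohort(visits)
            fm = self.model._features(boot, vocabulary=self.fitted.vocabulary,
                                      age_params=self.fitted.age_params)
            fb = fit_logistic(fm, y, C=self.model.C)
            for d in reported:
                draws[d].append(np.exp(float(fb.coef[d])))
        alpha = (1.0 - level) / 2.0
        return {
            d: tuple(np.quantile(v, [alpha, 1.0 - alpha])) for d, v in draws.items() if v
        }

    def summary(self) -> str:
        m = self.metrics()
        lines = [
            "High-risk screening model (L2 logistic regression)",
            f"  split scheme: {self.split.scheme} (seed {self.split.seed})",
            f"  train: {len(self.y_train)} visits / {len(self.split.train_patients)} patients",
            f"  test:  {len(self.y_test)} visits / {len(self.split.test_patients)} patients",
            f"  features: {len(self.fitted.coef)} ({len(self.fitted.vocabulary)} drug indicators)",
            f"  held-out AUC {m['auc']:.3f} | Brier {m['brier']:.4f}",
            f"  at threshold {m['threshold']:.2f}: accuracy {m['accuracy']:.3f}, "
            f"precision(1) {m['precision_1']:.3f}, recall(1) {m['recall_1']:.3f}, "
            f"F1(1) {m['f1_1']:.3f}",
        ]
        return "\n".join(lines)


class CrossValResults:
    """Per-fold metrics and pooled out-of-fold predictions."""

    def __init__(self, model, fold_results: list):
        self.model = model
        self.folds = fold_results
        frames = [r.predictions() for r in fold_results]
        self.oof = pd.concat(frames)

    def fold_metrics(self, threshold: float = OPERATING_THRESHOLD) -> pd.DataFrame:
        return pd.DataFrame([r.metrics(threshold) for r in self.folds])

    def pooled_metrics(self, threshold: float = OPERATING_THRESHOLD) -> dict:
        return evaluate(self.oof["proba"].to_numpy(), self.oof["y"].to_numpy(), threshold)

    def calibration(self, bins: int = 10):
        return calibration_report(self.oof["proba"].to_numpy(), self.oof["y"].to_numpy(), bins)
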