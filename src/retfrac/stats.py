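"""Cohort statistics: group comparisons, rank correlation, PCA, and
leave-one-out classification of collateral status.

The unit of analysis is a per-patient feature table (one row per patient)
holding both-eye-averaged retinal metrics, clinical covariates, and — for
stroke patients — the ordinal pial-collateral score (0 = absent supply,
"poor"; 3 = complete supply, "good").  Group contrasts use two-sided
independent t tests (pooled variance by default, Welch by flag); monotone
association uses Spearman's rho; unsupervised structure uses PCA on
standardised features; and the poor-vs-good classifier is evaluated by
leave-one-out cross-validation with standardisation refit inside every
training fold so no information from the held-out patient leaks into the
model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "RETINAL_FEATURES",
    "CLINICAL_FEATURES",
    "GroupComparison",
    "PCAResult",
    "ClassifierReport",
    "InsufficientDataError",
    "dichotomize_collaterals",
    "compare_groups",
    "compare_many",
    "spearman_corr",
    "pca_project",
    "loocv_classify",
    "load_feature_table",
    "DEFAULT_CLASSIFIER_FEATURES",
]

#: retinal metric columns, in the reporting order of the study tables
RETINAL_FEATURES = (
    "crae_um",
    "crve_um",
    "avr",
    "tortuosity_index",
    "df",
    "lacunarity",
    "d0",
    "d1",
    "d2",
    "curve_asymmetry",
    "singularity_length",
    "f_alpha_max",
)

CLINICAL_FEATURES = (
    "age",
    "bmi",
    "sbp",
    "hba1c",
    "mrs_admission",
    "mrs_discharge",
    "nihss_admission",
    "nihss_discharge",
    "total_cholesterol",
    "triglycerides",
    "ldl",
    "hdl",
)

#: classifier features: f(alpha)_max and D1 (D0 is dropped because it is
#: almost perfectly correlated with f(alpha)_max)
DEFAULT_CLASSIFIER_FEATURES = ("f_alpha_max", "d1")


class InsufficientDataError(ValueError):
    """A statistic was requested with too few non-missing observations."""


# ---------------------------------------------------------------------------
# feature table I/O

def load_feature_table(
    path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-patient feature CSV, optionally renaming columns.

    ``column_map`` maps source column names (e.g. of an externally deposited
    table) to the canonical names in RETINAL_FEATURES / CLINICAL_FEATURES /
    {patient_id, group, collateral_score, collateral_class}.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def dichotomize_collaterals(
    scores: pd.Series, poor_max_score: int = 1
) -> pd.Series:
    """Collapse ordinal collateral scores 0-3 into poor/good.

    Scores <= ``poor_max_score`` are "poor", the rest "good"; missing stays
    missing (controls carry no collateral grade).
    """
    out = pd.Series(pd.NA, index=scores.index, dtype="object")
    ok = scores.notna()
    out[ok] = np.where(scores[ok] <= poor_max_score, "poor", "good")
    return out


# ---------------------------------------------------------------------------
# group comparison

@dataclass(frozen=True)
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    grouping: str,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided independent t test of one feature between two groups."""
    a = pd.to_numeric(table.loc[table[grouping] == group_a, feature],
                      errors="coerce").dropna()
    b = pd.to_numeric(table.loc[table[grouping] == group_b, feature],
                      errors="coerce").dropna()
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"{feature}: need >=2 values per group, got {len(a)}/{len(b)}"
        )
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        t_statistic=float(t),
        p_value=float(p),
    )


def compare_many(
    table: pd.DataFrame,
    features: tuple[str, ...],
    grouping: str,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Table of group comparisons (one row per feature)."""
    rows = []
    for feat in features:
        if feat not in table.columns:
            continue
        try:
            gc = compare_groups(table, feat, grouping, group_a, group_b, equal_var)
        except InsufficientDataError:
            continue
        rows.append(vars(gc))
    return pd.DataFrame(rows)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling.

    Returns (rho, p); (nan, nan) with a warning when either vector is
    constant or fewer than 3 complete pairs remain.
    """
    x = pd.to_numeric(pd.Series(x), errors="coerce")
    y = pd.to_numeric(pd.Series(y), errors="coerce")
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise InsufficientDataError("Spearman needs >=3 complete pairs")
    if x.nunique() < 2 or y.nunique() < 2:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return math.nan, math.nan
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# PCA

@dataclass(frozen=True)
class PCAResult:
    n_components: int
    explained_variance_fractions: np.ndarray
    cumulative_fraction: float
    projections: pd.DataFrame  # patients x components


def pca_project(
    table: pd.DataFrame, feature_set: tuple[str, ...], n_components: int
) -> PCAResult:
    """PCA of standardised features over complete cases."""
    from sklearn.decomposition import PCA

    data = table[list(feature_set)].apply(pd.to_numeric, errors="coerce").dropna()
    if len(data) < n_components:
        raise ValueError(
            f"{len(data)} complete cases < {n_components} requested components"
        )
    z = StandardScaler().fit_transform(data.values)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z)
    fracs = pca.explained_variance_ratio_
    proj = pd.DataFrame(
        coords,
        index=data.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PCAResult(
        n_components=n_components,
        explained_variance_fractions=fracs,
        cumulative_fraction=float(fracs.sum()),
        projections=proj,
    )


# ---------------------------------------------------------------------------
# leave-one-out classification

@dataclass(frozen=True)
class ClassifierReport:
    learner: str
    confusion_matrix: np.ndarray  # rows: true (poor, good); cols: predicted
    accuracy: float
    sensitivity_poor: float       # recall of the poor class (positive)
    specificity_poor: float       # recall of the good class
    sensitivity_weighted: float   # class-weighted recall (equals accuracy)
    specificity_weighted: float
    n_failed_folds: int = 0

    @property
    def n_total(self) -> int:
        return int(self.confusion_matrix.sum())


def _make_learner(learner: str, params: dict | None = None):
    params = params or {}
    if learner == "svm_linear":
        return SVC(kernel="linear", C=params.get("C", 1.0))
    if learner == "svm_sigmoid":
        return SVC(
            kernel="sigmoid",
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            coef0=params.get("coef0", 0.0),
        )
    if learner == "logistic":
        return LogisticRegression(max_iter=params.get("max_iter", 1000))
    raise ValueError(f"unknown learner {learner!r}")


def loocv_classify(
    table: pd.DataFrame,
    feature_set: tuple[str, ...] = DEFAULT_CLASSIFIER_FEATURES,
    learner: str = "svm_sigmoid",
    label_column: str = "collateral_class",
    positive_label: str = "poor",
    learner_params: dict | None = None,
) -> ClassifierReport:
    """Leave-one-out evaluation of a poor-vs-good collateral classifier.

    Each patient is predicted by a model trained on all others; feature
    standardisation is refit on every training fold.  The pooled predictions
    give the confusion matrix, accuracy, and sensitivity/specificity both
    with the poor class as positive and class-weighted (the weighted recall
    equals accuracy by construction; both conventions are reported).
    """
    data = table.dropna(subset=[*feature_set, label_column])
    y = data[label_column].astype(str).values
    X = data[list(feature_set)].apply(pd.to_numeric, errors="coerce").values
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 classes, got {list(labels)}")
    if min((y == lab).sum() for lab in labels) < 2:
        raise InsufficientDataError("need >=2 patients per class for LOOCV")

    neg_label = labels[labels != positive_label][0]
    order = [positive_label, neg_label]

    preds = np.empty(len(y), dtype=object)
    n_failed = 0
    for train_idx, test_idx in LeaveOneOut().split(X):
        model = make_pipeline(StandardScaler(), _make_learner(learner, learner_params))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X[train_idx], y[train_idx])
                preds[test_idx[0]] = model.predict(X[test_idx])[0]
            except Exception:  # non-convergent fold
                n_failed += 1
                preds[test_idx[0]] = None

    ok = np.array([p is not None for p in preds])
    cm = np.zeros((2, 2), dtype=int)
    for true, pred in zip(y[ok], preds[ok]):
        cm[order.index(true), order.index(pred)] += 1
    total = cm.sum()
    acc = float(np.trace(cm) / total) if total else math.nan
    n_pos, n_neg = cm[0].sum(), cm[1].sum()
    sens = float(cm[0, 0] / n_pos) if n_pos else math.nan
    spec = float(cm[1, 1] / n_neg) if n_neg else math.nan
    # class-weighted convention: each class's recall weighted by prevalence
    w_sens = float((cm[0, 0] + cm[1, 1]) / total) if total else math.nan
    w_spec = (
        float((sens * n_neg + spec * n_pos) / total)
        if total and n_pos and n_neg
        else math.nan
    )
    return ClassifierReport(
        learner=learner,
        confusion_matrix=cm,
        accuracy=acc,
        sensitivity_poor=sens,
        specificity_poor=spec,
        sensitivity_weighted=w_sens,
        specificity_weighted=w_spec,
        n_failed_folds=n_failed,
    )
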