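"""Patient-level diagnosis from per-patient cell classifications.

Each patient's detected nuclei are reduced to seven features -- age, the
three class counts (yin, yin-yang, yang), the diseased-cell fraction
``yang_ratio``, the combined suspected+diseased count ``combined_yang``
and its fraction ``combined_yang_ratio`` -- and four classifier families
(logistic regression, SVM, random forest, gradient-boosted trees) are
trained and compared under stratified 10-fold cross-validation with the
full screening metric panel (ROC-AUC, accuracy, sensitivity,
specificity, PPV/NPV, F1, G-Mean).  Tree ensembles additionally report
split-gain feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from cytoscreen.evalkit import f1_gmean

FEATURE_NAMES = (
    "age",
    "yin",
    "yin_yang",
    "yang",
    "yang_ratio",
    "combined_yang",
    "combined_yang_ratio",
)

METHODS = ("logistic", "svm", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class PatientFeatures:
    """The seven per-patient predictors."""

    age: float
    yin: int
    yin_yang: int
    yang: int
    yang_ratio: float
    combined_yang: int
    combined_yang_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


def extract_features(detections: Sequence, age: float) -> PatientFeatures:
    """Aggregate one patient's classified nuclei into the seven features.

    ``detections`` is any iterable of objects with a ``cls`` attribute
    (detections or ground-truth annotations).  Order-invariant; raises
    on a patient with zero cells, where the ratios are undefined.
    """
    counts = {"yin": 0, "yin-yang": 0, "yang": 0}
    for d in detections:
        counts[d.cls] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("patient has zero classified cells; ratios undefined")
    combined = counts["yin-yang"] + counts["yang"]
    return PatientFeatures(
        age=float(age),
        yin=counts["yin"],
        yin_yang=counts["yin-yang"],
        yang=counts["yang"],
        yang_ratio=counts["yang"] / total,
        combined_yang=combined,
        combined_yang_ratio=combined / total,
    )


def features_from_counts(
    yin: int, yin_yang: int, yang: int, age: float
) -> PatientFeatures:
    """Build the feature vector directly from class counts."""
    class _C:
        def __init__(self, cls):
            self.cls = cls
    cells = [_C("yin")] * yin + [_C("yin-yang")] * yin_yang + [_C("yang")] * yang
    return extract_features(cells, age)


def feature_table(features: Sequence[PatientFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.as_array() for f in features], columns=FEATURE_NAMES)


def _build_model(method: str, seed: int):
    if method == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=1000, random_state=seed),
        )
    if method == "svm":
        # RBF SVM with Platt-calibrated probabilities
        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed), method="sigmoid", ensemble=False
            ),
        )
    if method == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if method == "gradient_boosting":
        return XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            importance_type="gain",
            eval_metric="logloss",
        )
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _fold_metrics(y_true, y_prob, threshold: float = 0.5) -> dict[str, float]:
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1, gmean = f1_gmean(ppv, sens, spec)
    return {
        "auc": 100.0 * roc_auc_score(y_true, y_prob),
        "accuracy": 100.0 * (tp + tn) / len(y_true),
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "ppv": 100.0 * ppv,
        "npv": 100.0 * npv,
        "f1": 100.0 * f1,
        "g_mean": 100.0 * gmean,
    }


def train_patient_models(
    features: pd.DataFrame,
    labels: Sequence[int],
    methods: Sequence[str] = METHODS,
    cv_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Cross-validate the four patient classifiers on the seven features.

    Folds are stratified by outcome and shared across methods so the
    per-fold metric matrices feed paired model comparisons directly.

    Returns a dict with:

    ``fold_metrics``
        DataFrame, one row per (method, fold) with the full metric panel.
    ``summary``
        mean +/- sd per method and metric.
    ``models``
        per-method model refitted on the full cohort.
    ``importances``
        DataFrame of split-gain feature importances (tree ensembles only),
        normalized to sum to 1.
    """
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; cannot train")
    if counts.min() < cv_folds:
        raise ValueError(
            f"need at least {cv_folds} patients per class for {cv_folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    rows = []
    models = {}
    for method in methods:
        for fold_idx, (tr, te) in enumerate(folds):
            model = _build_model(method, seed)
            model.fit(X[tr], y[tr])
            prob = model.predict_proba(X[te])[:, 1]
            rows.append(
                {"method": method, "fold": fold_idx, **_fold_metrics(y[te], prob)}
            )
        full = _build_model(method, seed)
        full.fit(X, y)
        models[method] = full

    fold_metrics = pd.DataFrame(rows)
    summary = (
        fold_metrics.drop(columns="fold")
        .groupby("method", sort=False)
        .agg(["mean", "std"])
    )

    imp_rows = {}
    for method in methods:
        if method in ("random_forest", "gradient_boosting"):
            imp_rows[method] = rank_feature_importance(models[method])
    importances = (
        pd.DataFrame(imp_rows, index=list(FEATURE_NAMES)) if imp_rows else pd.DataFrame()
    )
    return {
        "fold_metrics": fold_metrics,
        "summary": summary,
        "models": models,
        "importances": importances,
        "folds": folds,
    }


def rank_feature_importance(model) -> np.ndarray:
    """Split-gain importances of a fitted tree ensemble over the 7 features.

    Nonnegative and normalized to sum to 1.  Raises for models without
    split-based importances (linear or kernel classifiers).
    """
    if not hasattr(model, "feature_importances_"):
        raise TypeError(
            f"{type(model).__name__} exposes no split-gain feature importances"
        )
    imp = np.asarray(model.feature_importances_, dtype=float)
    if imp.sum() <= 0:
        return np.full(len(imp), 1.0 / len(imp))
    return imp / imp.sum()
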