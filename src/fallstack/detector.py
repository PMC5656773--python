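"""Fall detectors: a stacked four-classifier ensemble and a one-feature
threshold baseline.

The stacked detector combines a random forest (100 trees), a linear-kernel
max-margin classifier (C=1, probabilities via a logistic link on its
decision values fitted on internal folds), gradient-boosted trees (100
trees, depth 2) and extreme-gradient-boosted trees (150 trees, depth 2,
learning rate 0.5, feature subsampling 0.6). Each base classifier emits
P_i(fall | x); the meta-feature vector

    x_meta = [P_1, P_2, P_3, P_4, sigma(P_i)]

(sigma = population standard deviation of the four probabilities) feeds a
logistic-regression meta-classifier that outputs the final fall
probability. Meta-training uses out-of-fold base probabilities from a
subject-grouped internal cross-validation, so no clip ever contributes to
both a base fit and its own meta-feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .features import FEATURE_NAMES, MANIFEST_HASH, MAX_ACCEL_FEATURE

BASE_CLASSIFIER_NAMES = ("random_forest", "svm_linear", "gboost", "xgboost")


def make_base_classifiers(seed: int = 0) -> list:
    """The four base classifiers with the published hyperparameters."""
    svm = make_pipeline(
        StandardScaler(),
        CalibratedClassifierCV(
            LinearSVC(C=1.0, random_state=seed), method="sigmoid", cv=3
        ),
    )
    return [
        RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
        svm,
        GradientBoostingClassifier(n_estimators=100, max_depth=2, random_state=seed),
        XGBClassifier(
            n_estimators=150,
            max_depth=2,
            learning_rate=0.5,
            colsample_bytree=0.6,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        ),
    ]


def build_meta_features(base_probs: np.ndarray,
                        include_sigma: bool = True) -> np.ndarray:
    """Map base probabilities (n, 4) to meta-features (n, 5).

    The fifth feature is the dispersion sigma(P_i), the population standard
    deviation (divide by 4) of the four base probabilities — the complete
    population of base outputs, not a sample from one. ``include_sigma``
    exists as an ablation hook.
    """
    base_probs = np.atleast_2d(np.asarray(base_probs, dtype=float))
    if base_probs.shape[1] != 4:
        raise ValueError(f"expected 4 base probabilities, got {base_probs.shape[1]}")
    if np.any(base_probs < 0) or np.any(base_probs > 1):
        raise ValueError("base probabilities must lie in [0, 1]")
    if not include_sigma:
        return base_probs
    sigma = base_probs.std(axis=1, ddof=0)
    return np.column_stack([base_probs, sigma])


def _feature_matrix(features: pd.DataFrame) -> np.ndarray:
    return features[list(FEATURE_NAMES)].to_numpy(dtype=float)


@dataclass
class StackedModel:
    """Fitted stacking ensemble (see module docstring)."""

    base_classifiers: list = field(default_factory=list)
    meta_classifier: LogisticRegression | None = None
    include_sigma: bool = True
    manifest_hash: str = MANIFEST_HASH
    seed: int = 0
    train_population: str = ""

    def base_probabilities(self, features: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(self._check(features))
        cols = [clf.predict_proba(X)[:, 1] for clf in self.base_classifiers]
        return np.column_stack(cols)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Final P(fall | x) for each row of the feature table."""
        meta = build_meta_features(
            self.base_probabilities(features), self.include_sigma
        )
        return self.meta_classifier.predict_proba(meta)[:, 1]

    def _check(self, features: pd.DataFrame) -> pd.DataFrame:
        if self.manifest_hash != MANIFEST_HASH:
            raise ValueError(
                "model was fitted under a different feature manifest "
                f"({self.manifest_hash} != {MANIFEST_HASH})"
            )
        return features


@dataclass
class ThresholdModel:
    """Baseline: score a clip by its maximum resultant acceleration.

    ``predict_proba`` maps the feature through the monotone squashing
    a / (1 + a) so scores live in [0, 1); the ranking is exactly the
    ranking by peak acceleration, which is all an ROC analysis sees.
    ``threshold_g``, when set, is the operating threshold in g.
    """

    threshold_g: float = np.inf
    manifest_hash: str = MANIFEST_HASH

    def fit(self, features: pd.DataFrame) -> "ThresholdModel":
        return self  # nothing to learn; the threshold is set by evaluation

    def scores(self, features: pd.DataFrame) -> np.ndarray:
        return features[MAX_ACCEL_FEATURE].to_numpy(dtype=float)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        a = self.scores(features)
        return a / (1.0 + a)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.scores(features) >= self.threshold_g


def fit_stacked(
    train: pd.DataFrame,
    seed: int = 0,
    include_sigma: bool = True,
    n_inner_folds: int = 5,
    train_population: str = "",
) -> StackedModel:
    """Fit the stacking ensemble on a training feature table.

    Out-of-fold base probabilities for the meta-classifier come from a
    subject-grouped internal cross-validation (``n_inner_folds`` capped at
    the number of training subjects), after which the base classifiers are
    refitted on the full training set. Only training-set rows are ever
    touched; the evaluation harness passes training folds exclusively.
    """
    y = train["is_fall"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both falls and non-falls")
    subjects = train["subject"].to_numpy()
    unique_subjects = np.unique(subjects)
    if unique_subjects.size < 2:
        raise ValueError("stacking needs >= 2 training subjects for internal folds")
    X = _feature_matrix(train)

    templates = make_base_classifiers(seed)
    n_folds = min(n_inner_folds, unique_subjects.size)
    oof = np.full((len(y), 4), np.nan)
    splitter = GroupKFold(n_splits=n_folds)
    for fold_train, fold_test in splitter.split(X, y, groups=subjects):
        if len(np.unique(y[fold_train])) < 2:
            raise ValueError(
                "an internal fold lost one class; use more subjects or fewer folds"
            )
        for j, template in enumerate(templates):
            clf = clone(template)
            clf.fit(X[fold_train], y[fold_train])
            oof[fold_test, j] = clf.predict_proba(X[fold_test])[:, 1]
    assert not np.isnan(oof).any()

    meta_X = build_meta_features(oof, include_sigma)
    meta = LogisticRegression(max_iter=1000, random_state=seed)
    meta.fit(meta_X, y)

    bases = []
    for template in templates:
        clf = clone(template)
        clf.fit(X, y)
        bases.append(clf)
    return StackedModel(
        base_classifiers=bases,
        meta_classifier=meta,
        include_sigma=include_sigma,
        seed=seed,
        train_population=train_population,
    )


def predict_proba(model, features: pd.DataFrame) -> np.ndarray:
    """Score a feature table with either detector kind."""
    if getattr(model, "manifest_hash", MANIFEST_HASH) != MANIFEST_HASH:
        raise ValueError("feature manifest mismatch between model and table")
    return model.predict_proba(features)


def grid_search_spaces() -> dict[str, dict[str, Sequence]]:
    """Small hyperparameter grids around the published settings.

    Off by default — the published values are the defaults; the grids exist
    for users who want to re-tune on their own data.
    """
    return {
        "random_forest": {"n_estimators": [50, 100, 200]},
        "svm_linear": {
            "calibratedclassifiercv__estimator__C": [0.1, 1.0, 10.0]
        },
        "gboost": {"n_estimators": [50, 100, 200], "max_depth": [1, 2, 3]},
        "xgboost": {"n_estimators": [100, 150, 200], "learning_rate": [0.25, 0.5, 1.0]},
    }
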