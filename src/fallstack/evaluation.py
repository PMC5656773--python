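"""Evaluation protocol: subject-wise cross-validation, ROC analysis,
operating-point selection, false alarms per day, and model comparison.

All cohort summaries are reported as the across-subject mean with a
1.96 x SEM half-width. The ROC operating point is the point with the
greatest sum of sensitivity and specificity (Youden-style); the false-alarm
rate fixes the threshold at a target sensitivity on labeled fall clips and
counts supra-threshold clips in a fall-free free-living stream per
monitored day.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal, rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from . import detector as _detector

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    """ROC curve with AUC, bootstrap CI, and the optimal operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_level: float = 0.95
    ci_reps: int = 0
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    operating_point: tuple[float, float, float] = (float("nan"),) * 3

    def to_dict(self) -> dict:
        thr, sens, spec = self.operating_point
        return {
            "auc": self.auc,
            "ci_level": self.ci_level,
            "ci_reps": self.ci_reps,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "operating_point": {
                "threshold": thr,
                "sensitivity": sens,
                "specificity": spec,
            },
            "curve": {
                "thresholds": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            },
        }


def compute_roc(
    labels: np.ndarray,
    scores: np.ndarray,
    n_bootstrap: int = 1000,
    ci_level: float = 0.95,
    subjects: np.ndarray | None = None,
    seed: int = 0,
) -> ROCResult:
    """ROC curve and AUC with a bootstrap confidence interval.

    The AUC equals the probability that a random fall clip outranks a
    random non-fall clip, with ties counted 1/2. The bootstrap resamples
    clips within subject strata when ``subjects`` is given (clips of one
    subject are correlated; stratified resampling keeps every subject
    represented), plain otherwise.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    result = ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        ci_level=ci_level,
        ci_reps=n_bootstrap,
    )
    result.operating_point = optimal_point(result)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        strata = (
            [np.arange(len(labels))]
            if subjects is None
            else [np.nonzero(np.asarray(subjects) == s)[0]
                  for s in np.unique(subjects)]
        )
        reps = []
        for _ in range(n_bootstrap):
            idx = np.concatenate(
                [stratum[rng.integers(0, len(stratum), len(stratum))]
                 for stratum in strata]
            )
            if len(np.unique(labels[idx])) < 2:
                continue
            reps.append(roc_auc_score(labels[idx], scores[idx]))
        if reps:
            alpha = (1.0 - ci_level) / 2.0
            result.ci_low = float(np.quantile(reps, alpha))
            result.ci_high = float(np.quantile(reps, 1.0 - alpha))
    return result


def optimal_point(roc: ROCResult) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing sens + spec.

    Ties are broken toward the lower threshold, i.e. the higher
    sensitivity.
    """
    if len(roc.thresholds) == 0:
        raise ValueError("empty ROC")
    youden = roc.sensitivity + roc.specificity
    # thresholds from roc_curve are descending: the last argmax is the
    # lowest threshold among ties
    best = len(youden) - 1 - int(np.argmax(youden[::-1]))
    return (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )


def _fit_and_score(model_kind: str, train: pd.DataFrame, test: pd.DataFrame,
                   seed: int, **fit_kwargs):
    if model_kind == "stacked":
        model = _detector.fit_stacked(train, seed=seed, **fit_kwargs)
    elif model_kind == "threshold":
        model = _detector.ThresholdModel().fit(train)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return model, _detector.predict_proba(model, test)


def run_losocv(
    features: pd.DataFrame,
    model_kind: str = "stacked",
    seed: int = 0,
    n_bootstrap: int = 0,
    test_location: str | None = None,
    **fit_kwargs,
) -> dict:
    """Leave-one-subject-out cross-validation over a feature table.

    One fold per subject; each fold's model never sees the held-out
    subject. ``test_location`` restricts each fold's *test* clips to one
    carry location while training still uses all locations. Folds whose
    test set contains a single class are flagged and excluded from the
    AUC summary with a logged warning. Returns ``{"per_subject": {...},
    "summary": {...}, "pooled": {...}, "scores": DataFrame}`` where the
    summary lists across-subject means with 1.96 x SEM half-widths.
    """
    subjects = sorted(features["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSOCV needs at least 2 subjects")
    per_subject: dict[str, dict] = {}
    pooled_scores, pooled_labels, pooled_subjects = [], [], []
    for subject in subjects:
        test = features[features["subject"] == subject]
        if test_location is not None:
            test = test[test["location"] == test_location]
            if len(test) == 0:
                per_subject[subject] = {"excluded": True, "n_clips": 0}
                continue
        train = features[features["subject"] != subject]
        _, scores = _fit_and_score(model_kind, train, test, seed, **fit_kwargs)
        labels = test["is_fall"].to_numpy(dtype=int)
        pooled_scores.append(scores)
        pooled_labels.append(labels)
        pooled_subjects.append(test["subject"].to_numpy())
        if len(np.unique(labels)) < 2:
            logger.warning(
                "subject %s has single-class test data; fold excluded "
                "from the AUC summary", subject
            )
            per_subject[subject] = {"excluded": True, "n_clips": len(labels)}
            continue
        roc = compute_roc(labels, scores, n_bootstrap=n_bootstrap, seed=seed)
        thr, sens, spec = roc.operating_point
        per_subject[subject] = {
            "excluded": False,
            "auc": roc.auc,
            "sensitivity": sens,
            "specificity": spec,
            "threshold": thr,
            "n_clips": len(labels),
            "n_falls": int(labels.sum()),
        }
    scores_df = pd.DataFrame(
        {
            "subject": np.concatenate(pooled_subjects),
            "is_fall": np.concatenate(pooled_labels),
            "score": np.concatenate(pooled_scores),
        }
    )
    pooled = compute_roc(
        scores_df["is_fall"].to_numpy(),
        scores_df["score"].to_numpy(),
        n_bootstrap=n_bootstrap,
        subjects=scores_df["subject"].to_numpy(),
        seed=seed,
    )
    return {
        "model_kind": model_kind,
        "per_subject": per_subject,
        "summary": summarize_subjects(per_subject),
        "pooled": pooled.to_dict(),
        "scores": scores_df,
    }


def run_external(
    train_features: pd.DataFrame,
    test_features: pd.DataFrame,
    model_kind: str = "stacked",
    seed: int = 0,
    n_bootstrap: int = 0,
    test_location: str | None = None,
    **fit_kwargs,
) -> dict:
    """External-validation evaluation: fit once on the training cohort,
    report per-test-subject metrics plus the pooled ROC. Training and test
    subjects must be disjoint; ``test_location`` restricts the test clips
    to one carry location (the model still trains on all locations)."""
    overlap = set(train_features["subject"]) & set(test_features["subject"])
    if overlap:
        raise ValueError(f"train/test subject overlap: {sorted(overlap)}")
    if test_location is not None:
        test_features = test_features[
            test_features["location"] == test_location
        ]
        if len(test_features) == 0:
            raise ValueError(f"no test clips at location {test_location!r}")
    model, scores = _fit_and_score(model_kind, train_features, test_features,
                                   seed, **fit_kwargs)
    labels = test_features["is_fall"].to_numpy(dtype=int)
    subjects = test_features["subject"].to_numpy()
    per_subject: dict[str, dict] = {}
    for subject in sorted(np.unique(subjects)):
        sel = subjects == subject
        if len(np.unique(labels[sel])) < 2:
            logger.warning("subject %s has single-class test data", subject)
            per_subject[subject] = {"excluded": True, "n_clips": int(sel.sum())}
            continue
        roc = compute_roc(labels[sel], scores[sel], n_bootstrap=n_bootstrap,
                          seed=seed)
        thr, sens, spec = roc.operating_point
        per_subject[subject] = {
            "excluded": False,
            "auc": roc.auc,
            "sensitivity": sens,
            "specificity": spec,
            "threshold": thr,
            "n_clips": int(sel.sum()),
            "n_falls": int(labels[sel].sum()),
        }
    pooled = compute_roc(labels, scores, n_bootstrap=n_bootstrap,
                         subjects=subjects, seed=seed)
    return {
        "model_kind": model_kind,
        "per_subject": per_subject,
        "summary": summarize_subjects(per_subject),
        "pooled": pooled.to_dict(),
        "scores": pd.DataFrame(
            {"subject": subjects, "is_fall": labels, "score": scores}
        ),
        "model": model,
    }


def summarize_subjects(per_subject: dict[str, dict]) -> dict:
    """Across-subject mean (1.96 SEM) of AUC / sensitivity / specificity."""
    rows = [v for v in per_subject.values() if not v.get("excluded")]
    out: dict[str, float | int] = {"n_subjects": len(rows)}
    for metric in ("auc", "sensitivity", "specificity"):
        vals = np.array([r[metric] for r in rows], dtype=float)
        out[f"{metric}_mean"] = float(vals.mean()) if vals.size else float("nan")
        if vals.size > 1:
            sem = vals.std(ddof=1) / math.sqrt(vals.size)
            out[f"{metric}_ci95"] = float(1.96 * sem)
        else:
            out[f"{metric}_ci95"] = float("nan")
    return out


def sensitivity_threshold(fall_scores: np.ndarray, target_sensitivity: float
                          ) -> float:
    """Largest score threshold achieving >= the target sensitivity on
    labeled fall clips. A target of 0 yields +inf (never alarm)."""
    fall_scores = np.sort(np.asarray(fall_scores, dtype=float))
    n = fall_scores.size
    if not 0.0 <= target_sensitivity <= 1.0:
        raise ValueError("target sensitivity must lie in [0, 1]")
    if n == 0:
        raise ValueError("no fall clips to calibrate the threshold on")
    k = math.ceil(target_sensitivity * n)  # falls that must score >= threshold
    if k == 0:
        return float("inf")
    return float(fall_scores[n - k])


def false_alarms_per_day(
    model,
    home_features: pd.DataFrame,
    lab_fall_features: pd.DataFrame,
    target_sensitivity: float = 0.9,
    home_days: float | None = None,
) -> dict:
    """False alarms per monitored day at a fixed target sensitivity.

    The decision threshold is the largest achieving the target sensitivity
    on the lab fall clips; the rate counts supra-threshold clips in the
    (fall-free, already 2 g pre-filtered) free-living table per day.
    """
    if home_days is None or home_days <= 0:
        raise ValueError("home_days must be a positive duration in days")
    if home_features["is_fall"].any():
        raise ValueError("home stream must be fall-free")
    if not lab_fall_features["is_fall"].all():
        raise ValueError("lab_fall_features must contain fall clips only")
    fall_scores = _detector.predict_proba(model, lab_fall_features)
    threshold = sensitivity_threshold(fall_scores, target_sensitivity)
    home_scores = _detector.predict_proba(model, home_features)
    n_alarms = int(np.sum(home_scores >= threshold))
    return {
        "threshold": threshold,
        "target_sensitivity": target_sensitivity,
        "n_alarms": n_alarms,
        "home_days": home_days,
        "rate_per_day": n_alarms / home_days,
    }


def _ranksum_stat(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks under ties
    w = float(ranks[: len(a)].sum())
    n1, n2 = len(a), len(b)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return w, mu, var


def compare_models(auc_a, auc_b) -> dict:
    """Two-sided Wilcoxon rank-sum test on two independent samples of
    per-subject AUCs.

    Exact enumeration of all rank assignments when the combined sample is
    below 12; otherwise the normal approximation with tie correction. A
    degenerate pooled sample (all values identical) returns p = 1.
    """
    a = np.asarray(list(auc_a), dtype=float)
    b = np.asarray(list(auc_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    w, mu, var = _ranksum_stat(a, b)
    if var == 0:
        return {"statistic": 0.0, "p_value": 1.0, "method": "degenerate"}
    n = a.size + b.size
    if n < 12:
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        obs_dev = abs(w - mu)
        count = total = 0
        for combo in itertools.combinations(range(n), a.size):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= obs_dev - 1e-12:
                count += 1
        z = (w - mu) / math.sqrt(var)
        return {
            "statistic": z,
            "p_value": count / total,
            "method": "exact",
        }
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * _normal.sf(abs(z))
    return {"statistic": z, "p_value": p, "method": "normal"}


def plot_roc(results: dict[str, ROCResult], path) -> None:
    """Plot one or more ROC curves (with CI annotation) to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in results.items():
        label = f"{name} (AUC {roc.auc:.3f})"
        if np.isfinite(roc.ci_low):
            label += f" [{roc.ci_low:.3f}, {roc.ci_high:.3f}]"
        ax.plot(1.0 - roc.specificity, roc.sensitivity, label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
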