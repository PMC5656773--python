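"""End-to-end orchestration: simulate cohorts, assemble clip datasets,
run the population-transfer experiment matrix and the free-living
false-alarm analysis.

Every stage derives its random state deterministically from one global
seed, so a whole study run is reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from . import evaluation
from .detector import ThresholdModel, fit_stacked
from .features import features_dataframe
from .preprocess import (
    WindowingConfig,
    extract_activity_clips,
    extract_fall_clips,
    extract_home_clips,
    magnitude_filter,
)
from .simulate import SimConfig, simulate_home_stream, simulate_lab_session, \
    subject_ids

logger = logging.getLogger(__name__)

# deterministic per-stage seed offsets derived from the global seed
_SIM_OFFSET = 0
_WINDOW_OFFSET = 101
_MODEL_OFFSET = 202
_EVAL_OFFSET = 303


def stage_seeds(seed: int) -> dict[str, int]:
    base = int(seed) % (2**31 - 1000)
    return {
        "simulation": base + _SIM_OFFSET,
        "windowing": base + _WINDOW_OFFSET,
        "model": base + _MODEL_OFFSET,
        "evaluation": base + _EVAL_OFFSET,
    }


def _subject_window_rng(wcfg: WindowingConfig, subject: str) -> np.random.Generator:
    return np.random.default_rng([wcfg.rng_seed, zlib.crc32(subject.encode())])


def build_subject_features(
    sim_config: SimConfig,
    subject: str,
    population: str,
    wcfg: WindowingConfig,
) -> pd.DataFrame:
    """Simulate one subject's lab session and return its feature table.

    Fall events yield ``windows_per_fall`` clips each (all retained);
    activity intervals are tiled with non-overlapping windows and passed
    through the 2 g magnitude filter.
    """
    stream, events = simulate_lab_session(sim_config, subject, population)
    rng = _subject_window_rng(wcfg, subject)
    clips = []
    for event in events:
        if event.is_fall:
            clips.extend(extract_fall_clips(stream, event, wcfg, rng=rng))
    activity = extract_activity_clips(
        stream, [e for e in events if not e.is_fall], wcfg
    )
    clips.extend(magnitude_filter(activity, wcfg.filter_threshold_g))
    return features_dataframe(clips)


def build_population_features(
    sim_config: SimConfig, population: str, wcfg: WindowingConfig
) -> pd.DataFrame:
    frames = [
        build_subject_features(sim_config, subject, population, wcfg)
        for subject in subject_ids(sim_config, population)
    ]
    df = pd.concat(frames, ignore_index=True)
    df["clip_id"] = np.arange(len(df))
    logger.info(
        "%s cohort: %d clips (%d falls, %d non-falls) from %d subjects",
        population, len(df), int(df["is_fall"].sum()),
        int((~df["is_fall"]).sum()), df["subject"].nunique(),
    )
    return df


def build_home_features(
    sim_config: SimConfig, subject: str, wcfg: WindowingConfig
) -> tuple[pd.DataFrame, float]:
    """Simulate one free-living stream and return its (pre-filtered)
    feature table together with the monitored duration in days."""
    stream = simulate_home_stream(sim_config, subject)
    days = stream.duration_s / 86400.0
    clips = extract_home_clips(stream, wcfg)
    df = features_dataframe(clips)
    df["subject"] = subject
    logger.info("home stream %s: %.2f days, %d supra-threshold clips",
                subject, days, len(df))
    return df, days


def _per_location_summary(result: dict, test_features: pd.DataFrame) -> dict:
    """Re-summarize an external run with the test clips filtered by carry
    location (the model itself is trained on all locations)."""
    scores = result["scores"]
    out = {}
    for location in sorted(test_features["location"].unique()):
        sel = (test_features["location"] == location).to_numpy()
        sub = scores[sel]
        per_subject = {}
        for subject in sorted(sub["subject"].unique()):
            s = sub[sub["subject"] == subject]
            labels = s["is_fall"].to_numpy(dtype=int)
            if len(np.unique(labels)) < 2:
                per_subject[subject] = {"excluded": True, "n_clips": len(s)}
                continue
            roc = evaluation.compute_roc(labels, s["score"].to_numpy(),
                                         n_bootstrap=0)
            thr, sens, spec = roc.operating_point
            per_subject[subject] = {
                "excluded": False, "auc": roc.auc, "sensitivity": sens,
                "specificity": spec, "threshold": thr,
                "n_clips": len(s), "n_falls": int(labels.sum()),
            }
        out[location] = evaluation.summarize_subjects(per_subject)
    return out


def run_transfer_experiments(
    sim_config: SimConfig,
    wcfg: WindowingConfig,
    seed: int = 0,
    n_bootstrap: int = 0,
    model_kinds: tuple[str, ...] = ("stacked", "threshold"),
    by_location: bool = True,
) -> dict:
    """The population-transfer experiment matrix.

    Three training conditions — control-to-control (LOSOCV),
    control-to-amputee (external validation), amputee-to-amputee (LOSOCV)
    — each evaluated with the stacked detector and the threshold baseline,
    plus rank-sum comparisons of per-subject AUCs across conditions and
    between detectors.
    """
    control = build_population_features(sim_config, "control", wcfg)
    amputee = build_population_features(sim_config, "amputee", wcfg)
    model_seed = stage_seeds(seed)["model"]

    results: dict[str, dict] = {"experiments": {}}
    for kind in model_kinds:
        results["experiments"][f"control_to_control/{kind}"] = evaluation.run_losocv(
            control, model_kind=kind, seed=model_seed, n_bootstrap=n_bootstrap
        )
        c2a = evaluation.run_external(
            control, amputee, model_kind=kind, seed=model_seed,
            n_bootstrap=n_bootstrap,
        )
        results["experiments"][f"control_to_amputee/{kind}"] = c2a
        results["experiments"][f"amputee_to_amputee/{kind}"] = evaluation.run_losocv(
            amputee, model_kind=kind, seed=model_seed, n_bootstrap=n_bootstrap
        )
        if by_location:
            c2a["by_location"] = _per_location_summary(c2a, amputee)

    def _aucs(name: str) -> list[float]:
        per = results["experiments"][name]["per_subject"]
        return [v["auc"] for v in per.values() if not v.get("excluded")]

    comparisons = {}
    if "stacked" in model_kinds:
        comparisons["transfer_vs_native_stacked"] = evaluation.compare_models(
            _aucs("control_to_amputee/stacked"), _aucs("amputee_to_amputee/stacked")
        )
        comparisons["control_vs_transfer_stacked"] = evaluation.compare_models(
            _aucs("control_to_control/stacked"), _aucs("control_to_amputee/stacked")
        )
    if set(model_kinds) >= {"stacked", "threshold"}:
        for exp in ("control_to_control", "control_to_amputee",
                    "amputee_to_amputee"):
            comparisons[f"stacked_vs_threshold_{exp}"] = evaluation.compare_models(
                _aucs(f"{exp}/stacked"), _aucs(f"{exp}/threshold")
            )
    results["comparisons"] = comparisons
    results["datasets"] = {
        "control": {
            "n_clips": len(control),
            "n_falls": int(control["is_fall"].sum()),
            "n_subjects": control["subject"].nunique(),
        },
        "amputee": {
            "n_clips": len(amputee),
            "n_falls": int(amputee["is_fall"].sum()),
            "n_subjects": amputee["subject"].nunique(),
        },
    }
    results["_features"] = {"control": control, "amputee": amputee}
    return results


def run_home_analysis(
    sim_config: SimConfig,
    wcfg: WindowingConfig,
    seed: int = 0,
    n_home_subjects: int = 3,
    target_sensitivity: float = 0.9,
    control_features: pd.DataFrame | None = None,
    amputee_features: pd.DataFrame | None = None,
) -> dict:
    """Free-living false-alarm analysis.

    A control-trained model (stacked and threshold variants) is applied to
    fall-free home streams of amputee subjects; the decision threshold is
    calibrated at the target sensitivity on the amputee cohort's lab fall
    clips, and alarms are counted per monitored day.
    """
    if control_features is None:
        control_features = build_population_features(sim_config, "control", wcfg)
    if amputee_features is None:
        amputee_features = build_population_features(sim_config, "amputee", wcfg)
    model_seed = stage_seeds(seed)["model"]
    lab_falls = amputee_features[amputee_features["is_fall"]]

    stacked = fit_stacked(control_features, seed=model_seed,
                          train_population="control")
    threshold = ThresholdModel().fit(control_features)

    home_subjects = subject_ids(sim_config, "amputee")[:n_home_subjects]
    out: dict[str, dict] = {"per_subject": {}, "target_sensitivity": target_sensitivity}
    rates: dict[str, list[float]] = {"stacked": [], "threshold": []}
    for subject in home_subjects:
        home_df, days = build_home_features(sim_config, subject, wcfg)
        entry = {"home_days": days, "n_clips_over_2g": len(home_df)}
        for kind, model in (("stacked", stacked), ("threshold", threshold)):
            if len(home_df) == 0:
                fa = {"threshold": float("inf"), "n_alarms": 0,
                      "home_days": days, "rate_per_day": 0.0,
                      "target_sensitivity": target_sensitivity}
            else:
                fa = evaluation.false_alarms_per_day(
                    model, home_df, lab_falls, target_sensitivity, days
                )
            entry[kind] = fa
            rates[kind].append(fa["rate_per_day"])
        out["per_subject"][subject] = entry
    for kind in ("stacked", "threshold"):
        arr = np.array(rates[kind])
        out[f"{kind}_rate_mean"] = float(arr.mean())
        out[f"{kind}_rate_sd"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return out


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items()
                if not k.startswith("_") and k not in ("scores", "model")}
    return obj


def summary_table(transfer: dict) -> pd.DataFrame:
    """Metrics x experiment table of across-subject means (1.96 SEM)."""
    rows = []
    for name, res in transfer["experiments"].items():
        exp, kind = name.split("/")
        s = res["summary"]
        rows.append(
            {
                "experiment": exp,
                "model": kind,
                "auc": s["auc_mean"],
                "auc_ci95": s["auc_ci95"],
                "sensitivity": s["sensitivity_mean"],
                "sensitivity_ci95": s["sensitivity_ci95"],
                "specificity": s["specificity_mean"],
                "specificity_ci95": s["specificity_ci95"],
                "n_subjects": s["n_subjects"],
            }
        )
    return pd.DataFrame(rows)


def reproduce(
    sim_config: SimConfig | None = None,
    wcfg: WindowingConfig | None = None,
    seed: int = 0,
    n_bootstrap: int = 0,
    with_home: bool = True,
) -> dict:
    """Run the full synthetic study: population-transfer matrix plus the
    free-living false-alarm analysis. Returns a JSON-serializable report
    (plus a ``table`` DataFrame of the headline summary)."""
    seeds = stage_seeds(seed)
    if sim_config is None:
        sim_config = SimConfig(seed=seeds["simulation"])
    else:
        sim_config = replace(sim_config, seed=seeds["simulation"])
    if wcfg is None:
        wcfg = WindowingConfig(rng_seed=seeds["windowing"])
    else:
        wcfg = replace(wcfg, rng_seed=seeds["windowing"])

    transfer = run_transfer_experiments(
        sim_config, wcfg, seed=seed, n_bootstrap=n_bootstrap
    )
    report = {
        "seed": seed,
        "stage_seeds": seeds,
        "transfer": _strip_private(transfer),
    }
    if with_home:
        report["home"] = run_home_analysis(
            sim_config,
            wcfg,
            seed=seed,
            control_features=transfer["_features"]["control"],
            amputee_features=transfer["_features"]["amputee"],
        )
    report["table"] = summary_table(transfer)
    return report
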