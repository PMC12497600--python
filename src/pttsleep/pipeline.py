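"""End-to-end workflow: simulate (or load) recordings, extract PTT and
oximetry features, categorise, apply the exclusion flow, and run the
statistical analysis, writing all artifacts to an output directory.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import categorise, oximetry, ptt, stats, synth
from .config import RunConfig
from .types import Category, Recording

#: Mapping of categories onto the 3-level score of the multinomial model.
CATEGORY_TO_SCORE3 = {
    Category.NORMAL: 1, Category.PRIMARY_SNORING: 1,
    Category.UARS_MILD_OSA: 2, Category.MODERATE_OSA: 3,
    Category.SEVERE_OSA: 3,
}


def extract_features(recording: Recording, min_ptt_hours: float = 3.0,
                     min_oximetry_hours: float = 4.0,
                     ) -> categorise.StudyAssessment:
    """Run both extraction chains on one recording and assemble the
    15-variable feature row (plus age in months for the score model)."""
    ptt_summary, _channels = ptt.extract_ptt(recording, min_ptt_hours)
    oxi = oximetry.compute_oximetry_summary(
        recording.spo2, min_hours=min_oximetry_hours)
    rr = np.diff(recording.r_peak_times)
    inst_hr = 60.0 / rr[rr > 0]
    truth = recording.truth
    features = {
        "pttrs": ptt_summary.pttrs,
        "ptt_ai": ptt_summary.ptt_ai,
        "ptt_duration": ptt_summary.ptt_duration_hours,
        "oximetry_score": oxi.score,
        "odi3": oxi.odi3,
        "odi4": oxi.odi4,
        "min_spo2": oxi.min_spo2,
        "mean_spo2": oxi.mean_spo2,
        "mean_nadir": oxi.mean_nadir if oxi.mean_nadir is not None
        else float("nan"),
        "study_duration": recording.duration / 3600.0,
        "sex": (1 if truth.sex == "M" else 0) if truth else float("nan"),
        "weight": truth.weight_kg if truth else float("nan"),
        "height": truth.height_cm if truth else float("nan"),
        "heart_rate": float(inst_hr.mean()) if inst_hr.size else float("nan"),
        "heart_rate_sd": float(inst_hr.std(ddof=1)) if inst_hr.size > 1
        else float("nan"),
        "age_months": truth.age_months if truth else float("nan"),
    }
    n_epi = len(recording.video_labels)
    assessment = categorise.StudyAssessment(
        snoring_present=recording.snoring,
        n_obstructive_episodes=n_epi,
        episodes_with_arousal=sum(e.has_arousal for e in recording.video_labels),
        oximetry=oxi, ptt=ptt_summary, features=features)
    categorise.assign_category(assessment)
    return assessment


def feature_frame(assessments: list[categorise.StudyAssessment]) -> pd.DataFrame:
    """Feature table for the included cohort (one row per subject)."""
    rows = []
    for a in assessments:
        row = dict(a.features)
        row["category"] = a.category.value
        row["disorder"] = int(a.category in
                              {Category.UARS_MILD_OSA, Category.MODERATE_OSA,
                               Category.SEVERE_OSA})
        rows.append(row)
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def analyse_features(df: pd.DataFrame, config: RunConfig) -> dict:
    """Statistical layer on an included-cohort feature table."""
    report: dict = {"n": int(len(df))}
    selection = stats.select_variables(df, alpha=config.alpha)
    report["selected_variables"] = selection.selected
    report["top2_variables"] = selection.top2_variables
    report["metrics"] = {name: m.to_dict()
                         for name, m in selection.metrics.items()}
    scored = selection.significant or selection.full
    auc, curve = stats.roc_auc(scored.predict(df), df["disorder"])
    report["auc"] = auc
    tree = stats.fit_tree(df, selection.top2_variables or stats.TWO_VARIABLES,
                          split=config.tree_split, seed=config.seed)
    report["tree_accuracy"] = tree.extra["test_accuracy"]
    # duration sensitivity: re-fit the parsimonious model on the >= 4 h subset
    sub = df[df["ptt_duration"] >= 4.0]
    if len(sub) > 20 and sub["disorder"].nunique() == 2 and selection.top2:
        top2_4h = stats.fit_logistic(sub, selection.top2_variables)
        report["metrics"]["top2_4h"] = stats.metrics_from_predictions(
            sub["disorder"], (top2_4h.predict(sub) >= 0.5)).to_dict()
        report["n_4h"] = int(len(sub))
    df3 = df[df["category"].isin([c.value for c in CATEGORY_TO_SCORE3])].copy()
    df3["score3"] = df3["category"].map(
        {c.value: s for c, s in CATEGORY_TO_SCORE3.items()})
    if df3["score3"].nunique() == 3:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mn = stats.fit_multinomial(df3, outcome="score3", reference=3)
        report["multinomial"] = _jsonable(
            mn.table.reset_index(names="variable").to_dict(orient="records"))
    return report | {"_curve": curve}


def run_pipeline(config: RunConfig) -> dict:
    """Simulate → extract → categorise → exclude → analyse; write artifacts.

    With ``generator="signals"`` the full waveform chain runs on every
    subject; ``generator="features"`` draws the included-cohort feature
    table directly (the cohort-scale path).  Deterministic in the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mix = None
    if config.mix:
        mix = {Category(k): v for k, v in config.mix.items()}
    if config.generator == "signals":
        recordings = synth.simulate_cohort(
            config.n_subjects, mix, config.seed,
            artefact_level=config.artefact_level,
            study_hours=(config.study_hours_mean, config.study_hours_sd))
        assessments = [extract_features(r, config.min_ptt_hours,
                                        config.min_oximetry_hours)
                       for r in recordings]
        included, exclusions = categorise.apply_exclusions(
            assessments, config.min_ptt_hours, config.min_oximetry_hours)
        df = feature_frame(included)
    else:
        df = synth.simulate_features(config.n_subjects, mix, config.seed)
        exclusions = pd.DataFrame(
            {"reason": ["total excluded", "included"],
             "n": [0, len(df)]})
    df.to_csv(out / "features.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    report: dict = {
        "seed": config.seed, "generator": config.generator,
        "n_included": int(len(df)),
        "exclusions": exclusions.set_index("reason")["n"].to_dict(),
    }
    if config.analyze and len(df) and df["disorder"].nunique() == 2:
        analysis = analyse_features(df, config)
        curve = analysis.pop("_curve")
        curve.to_csv(out / "roc.csv", index=False)
        report["analysis"] = analysis
    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True))
    return report
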