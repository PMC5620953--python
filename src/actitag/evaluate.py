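"""Metrics, leave-one-subject-out cross-validation and training settings.

Metrics follow the one-vs-rest convention, macro-averaged over the ten
tags: sensitivity (recall), specificity and F-score per tag, overall
accuracy as the fraction of correct windows.  All values are reported on a
0-100 scale; the confusion matrix holds percentages of the total number of
predictions.  LOSO cross-validation holds out every window of one subject
per fold — no held-out window leaks into SFFS, the mapping, the forests or
the confidence-bound calibration.

Three training settings probe how patient and healthy data mix:

* **A** — mappings and classifiers trained on patients + healthy;
* **B** — patients only;
* **C** — SFFS + mapping fitted on patient data, classifiers trained on
  healthy data.

In every setting the evaluation windows come from held-out patients only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import dmf as _dmf
from . import logicfilter as lf
from .features import DESCRIPTOR_NAMES
from .tags import TAG_ORDER, as_tag

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "compute_metrics",
    "PipelineConfig",
    "train_fold",
    "predict_fold",
    "loso_cv",
    "run_training_setting",
]


@dataclass
class EvaluationReport:
    """Metrics on a 0-100 scale; across-fold std where applicable."""

    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    confusion: pd.DataFrame  # percent of total predictions per cell
    per_tag_recall: pd.Series
    accuracy_std: float = 0.0
    sensitivity_std: float = 0.0
    specificity_std: float = 0.0
    f_score_std: float = 0.0
    n_folds: int = 1
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        pm = "+/-"
        return (
            f"accuracy    {self.accuracy:6.2f} {pm} {self.accuracy_std:.2f}\n"
            f"sensitivity {self.sensitivity:6.2f} {pm} {self.sensitivity_std:.2f}\n"
            f"specificity {self.specificity:6.2f} {pm} {self.specificity_std:.2f}\n"
            f"f_score     {self.f_score:6.2f} {pm} {self.f_score_std:.2f}"
            f"   ({self.n_folds} folds)"
        )


def compute_metrics(y_true, y_pred) -> EvaluationReport:
    """Single-fold metrics from paired tag sequences."""
    yt = [as_tag(t) for t in y_true]
    yp = [as_tag(t) for t in y_pred]
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have equal length")
    if not yt:
        raise ValueError("empty input")
    names = [t.value for t in TAG_ORDER]
    n = len(yt)
    counts = np.zeros((10, 10), dtype=float)
    from .tags import TAG_INDEX

    for a, b in zip(yt, yp):
        counts[TAG_INDEX[a], TAG_INDEX[b]] += 1
    acc = 100.0 * np.trace(counts) / n

    sens, spec, fsc, recall = [], [], [], {}
    for i, name in enumerate(names):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = n - tp - fn - fp
        se = tp / (tp + fn) if tp + fn > 0 else np.nan
        sp = tn / (tn + fp) if tn + fp > 0 else np.nan
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        f1 = 2 * prec * se / (prec + se) if (prec + se) > 0 else 0.0
        sens.append(se)
        spec.append(sp)
        fsc.append(0.0 if np.isnan(se) else f1)
        recall[name] = 100.0 * se if not np.isnan(se) else np.nan
    conf = pd.DataFrame(100.0 * counts / n, index=names, columns=names)
    return EvaluationReport(
        accuracy=float(acc),
        sensitivity=float(100.0 * np.nanmean(sens)),
        specificity=float(100.0 * np.nanmean(spec)),
        f_score=float(100.0 * np.mean(fsc)),
        confusion=conf,
        per_tag_recall=pd.Series(recall),
    )


def _aggregate(reports: list[EvaluationReport]) -> EvaluationReport:
    acc = np.array([r.accuracy for r in reports])
    sen = np.array([r.sensitivity for r in reports])
    spe = np.array([r.specificity for r in reports])
    fsc = np.array([r.f_score for r in reports])
    conf = sum(r.confusion for r in reports) / len(reports)
    rec = pd.concat([r.per_tag_recall for r in reports], axis=1).mean(axis=1)
    return EvaluationReport(
        accuracy=float(acc.mean()), accuracy_std=float(acc.std()),
        sensitivity=float(sen.mean()), sensitivity_std=float(sen.std()),
        specificity=float(spe.mean()), specificity_std=float(spe.std()),
        f_score=float(fsc.mean()), f_score_std=float(fsc.std()),
        confusion=conf, per_tag_recall=rec, n_folds=len(reports),
    )


# ---------------------------------------------------------------------------
# Pipeline folds
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end configuration of one train/evaluate fold."""

    dmf: _dmf.DMFConfig = field(default_factory=_dmf.DMFConfig)
    filter_order: int = 2
    #: held-out fraction of training windows used for delta calibration
    calibration_fraction: float = 0.15
    apply_filter: bool = True
    rng_seed: int = 0


def _split_xy(df: pd.DataFrame):
    X = df[DESCRIPTOR_NAMES].to_numpy(dtype=float)
    y = df["tag"].tolist()
    return X, y


def train_fold(
    train_df: pd.DataFrame,
    cfg: PipelineConfig,
    selection_df: pd.DataFrame | None = None,
) -> tuple[_dmf.DMFModel, float]:
    """Train a DMF on the fold's training windows and calibrate delta.

    A stratified ``calibration_fraction`` of the training windows is held
    out of model fitting and used only to calibrate the confidence bound.
    Returns (model, delta).
    """
    y_all = train_df["tag"].map(as_tag)
    strat = y_all.astype(str)
    try:
        fit_df, cal_df = train_test_split(
            train_df,
            test_size=cfg.calibration_fraction,
            stratify=strat,
            random_state=cfg.rng_seed % (2**31),
        )
    except ValueError:  # a tag with a single window cannot be stratified
        fit_df, cal_df = train_test_split(
            train_df,
            test_size=cfg.calibration_fraction,
            random_state=cfg.rng_seed % (2**31),
        )
    if set(fit_df["tag"].map(as_tag)) < set(TAG_ORDER):
        fit_df = train_df  # too few windows to spare; calibrate in-sample
    sel = None
    provenance = None
    if selection_df is not None:
        sel = (selection_df[DESCRIPTOR_NAMES].to_numpy(dtype=float), selection_df["tag"].tolist())
        provenance = sorted(set(selection_df.get("group", pd.Series(dtype=str))))
    model = _dmf.train_dmf(
        *_split_xy(fit_df),
        config=cfg.dmf,
        rng_seed=cfg.rng_seed,
        feature_names=DESCRIPTOR_NAMES,
        selection_data=sel,
        mapping_provenance=provenance,
    )
    preds = _dmf.predict_dmf(cal_df[DESCRIPTOR_NAMES].to_numpy(dtype=float), model)
    correct = [p.tag is as_tag(t) for p, t in zip(preds, cal_df["tag"])]
    conf = [p.confidence for p in preds]
    if all(correct) or not any(correct):
        delta = 0.0  # degenerate calibration set: never trigger the filter
        logger.warning("delta calibration degenerate (all %s); filter disabled",
                       "correct" if all(correct) else "incorrect")
    else:
        delta = lf.confidence_threshold(conf, correct).delta
    return model, delta


def predict_fold(
    test_df: pd.DataFrame,
    model: _dmf.DMFModel,
    delta: float,
    cfg: PipelineConfig,
    theta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predict the fold's windows; apply the logic filter per subject session."""
    preds = _dmf.predict_dmf(test_df[DESCRIPTOR_NAMES].to_numpy(dtype=float), model)
    out = test_df[["subject", "start_s", "tag"]].copy()
    out["pred"] = [p.tag for p in preds]
    out["confidence"] = [p.confidence for p in preds]
    out["filtered"] = out["pred"]
    out["corrected"] = False
    if cfg.apply_filter:
        for sid, grp in out.groupby("subject", sort=False):
            grp = grp.sort_values("start_s")
            if len(grp) < 2:
                continue
            fixed, changed = lf.apply_filter(
                grp["pred"].tolist(), grp["confidence"].to_numpy(),
                theta=theta, delta=delta, order=cfg.filter_order,
            )
            out.loc[grp.index, "filtered"] = fixed
            out.loc[grp.index, "corrected"] = changed
    return out


# ---------------------------------------------------------------------------
# LOSO CV
# ---------------------------------------------------------------------------

def loso_cv(
    features: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    test_subjects: "list[str] | None" = None,
    setting: str = "A",
) -> dict[str, EvaluationReport]:
    """Leave-one-subject-out cross-validation over a labelled feature table.

    ``features`` has one row per window with columns subject, group,
    start_s, tag and the descriptors.  One fold per held-out subject in
    ``test_subjects`` (default: all subjects for setting A, patients for
    B/C).  Returns reports keyed ``"raw"`` (unfiltered) and ``"filtered"``.
    """
    cfg = cfg or PipelineConfig()
    # canonical row order: results must not depend on table assembly order
    features = features.sort_values(["subject", "start_s"], kind="mergesort").reset_index(
        drop=True
    )
    subjects = sorted(features["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if setting not in ("A", "B", "C"):
        raise ValueError("setting must be 'A', 'B' or 'C'")
    groups = features.groupby("subject")["group"].first() if "group" in features else None
    if test_subjects is None:
        if setting == "A":
            test_subjects = subjects
        else:
            if groups is None:
                raise ValueError(f"setting {setting} needs a 'group' column")
            test_subjects = [s for s in subjects if groups[s] == "patient"]
    if setting in ("A", "C") and groups is not None and set(groups) < {"healthy", "patient"}:
        raise ValueError(f"setting {setting} requires both subject groups")

    raw_reports, filt_reports = [], []
    for sid in test_subjects:
        test_df = features[features["subject"] == sid]
        rest = features[features["subject"] != sid]
        if setting == "A":
            train_df, sel_df = rest, None
        elif setting == "B":
            train_df, sel_df = rest[rest["group"] == "patient"], None
        else:  # C: SFFS+mapping on patients, classifiers on healthy only
            train_df = rest[rest["group"] == "healthy"]
            sel_df = rest[rest["group"] == "patient"]
        if test_df["tag"].nunique() < 2:
            warnings.warn(f"subject {sid} has a single tag; fold still evaluated")
        model, delta = train_fold(train_df, cfg, selection_df=sel_df)
        pred_df = predict_fold(test_df, model, delta, cfg)
        raw_reports.append(compute_metrics(pred_df["tag"], pred_df["pred"]))
        filt_reports.append(compute_metrics(pred_df["tag"], pred_df["filtered"]))
        logger.info(
            "fold %s: acc %.1f -> %.1f (filtered)", sid,
            raw_reports[-1].accuracy, filt_reports[-1].accuracy,
        )
    return {"raw": _aggregate(raw_reports), "filtered": _aggregate(filt_reports)}


def run_training_setting(
    features: pd.DataFrame,
    setting: str,
    cfg: PipelineConfig | None = None,
) -> dict[str, EvaluationReport]:
    """LOSO evaluation under one of the training settings A/B/C.

    Evaluation folds always hold out one *patient*; the composition of the
    training side varies with the setting (see module docstring).
    """
    cfg = cfg or PipelineConfig()
    if "group" not in features:
        raise ValueError("run_training_setting needs a 'group' column")
    patients = sorted(features.loc[features["group"] == "patient", "subject"].unique())
    if not patients:
        raise ValueError("no patient subjects in the dataset")
    return loso_cv(features, cfg, test_subjects=patients, setting=setting)
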