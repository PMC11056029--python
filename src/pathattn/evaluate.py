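"""Classification metrics and the repeated stratified cross-validation harness.

Metrics follow the standard confusion-matrix definitions (accuracy,
precision, recall, F1 at a configurable threshold, default 0.5) plus
rank-based AUC and step-interpolated AUPR.  A denominator of zero yields 0
(logged).

The harness runs R repeats of stratified K-fold cross-validation (default
five 5-fold, reporting the average as the final result).  Within each
training split, chi-square feature selection, membership-matrix
construction and model training are all re-fitted, so no test information
leaks into the pipeline.  Ablation switches restrict modalities or set the
attention dimension (0 bypasses the attention block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import TrainConfig, predict, train
from .pathways import PathwayCollection, build_membership_matrix
from .preprocess import LabeledCohort, chi2_select

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "confusion",
    "metrics_from_counts",
    "metrics",
    "fit_fold",
    "repeated_cv",
]

METRIC_NAMES = ("ACC", "PRE", "REC", "F1", "AUC", "AUPR")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    ACC: float
    PRE: float
    REC: float
    F1: float
    AUC: float
    AUPR: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts of thresholded scores against binary labels."""
    y = np.asarray(labels)
    s = np.asarray(scores)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {s.shape} scores")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int((pred & pos).sum()),
        TN=int((~pred & ~pos).sum()),
        FP=int((pred & ~pos).sum()),
        FN=int((~pred & pos).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.info("metric %s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """Accuracy / precision / recall / F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = _safe_div(c.TP + c.TN, c.total, "ACC")
    pre = _safe_div(c.TP, c.TP + c.FP, "PRE")
    rec = _safe_div(c.TP, c.TP + c.FN, "REC")
    f1 = _safe_div(2.0 * pre * rec, pre + rec, "F1")
    return {"ACC": acc, "PRE": pre, "REC": rec, "F1": f1}


def metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full metric report: thresholded metrics plus AUC and AUPR."""
    y = np.asarray(labels)
    s = np.asarray(scores)
    if y.size == 0:
        raise ValueError("empty input")
    thresh = metrics_from_counts(confusion(y, s, threshold))
    if len(np.unique(y)) < 2:
        logger.info("single-class evaluation set; AUC/AUPR reported as 0")
        auc = aupr = 0.0
    else:
        auc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))
    return MetricsReport(AUC=auc, AUPR=aupr, **thresh)


@dataclass
class CVResult:
    """Per-fold records plus aggregates of a repeated CV run."""

    records: pd.DataFrame  # columns: repeat, fold, metrics..., n_test
    fold_sample_ids: dict  # (repeat, fold) -> list of test sample ids

    def mean(self) -> pd.Series:
        return self.records[list(METRIC_NAMES)].mean()

    def sd_over_folds(self) -> pd.Series:
        return self.records[list(METRIC_NAMES)].std(ddof=1)

    def sd_over_repeat_means(self) -> pd.Series:
        per_repeat = self.records.groupby("repeat")[list(METRIC_NAMES)].mean()
        return per_repeat.std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.mean(),
            "sd_folds": self.sd_over_folds(),
            "sd_repeat_means": self.sd_over_repeat_means(),
        })

    def summary_strings(self) -> pd.Series:
        """mean +/- sd (over folds) formatted to three decimals."""
        return pd.Series({
            m: f"{self.mean()[m]:.3f} ± {self.sd_over_folds()[m]:.3f}"
            for m in METRIC_NAMES
        })

    def write(self, path):
        self.records.to_csv(path, index=False)


def fit_fold(cohort: LabeledCohort, train_idx, test_idx,
             collections: dict, config: TrainConfig,
             feature_counts: dict | None = None,
             exclude_patterns=None, threshold: float = 0.5):
    """Fit the full pipeline on one train/test split; return (report, scores, model).

    Chi-square selection is fitted on the training samples only; membership
    matrices are rebuilt from the selected features.
    """
    from .pathways import filter_pathways

    train_cohort = cohort.subset_samples(train_idx)
    layers, memberships = {}, {}
    for mod in cohort.modalities:
        layer = cohort.layers[mod]
        m = None if feature_counts is None else feature_counts.get(mod)
        if m is not None:
            m = min(m, layer.n_features)
            layer = chi2_select(
                layer, cohort.labels, m,
                fit_values=train_cohort.layers[mod].values,
                fit_labels=train_cohort.labels)
        coll = collections[mod]
        if exclude_patterns:
            coll = filter_pathways(coll, exclude_patterns)
        membership, retained = build_membership_matrix(
            layer.feature_ids, coll, drop_unannotated=True)
        layers[mod] = layer.subset_features(retained)
        memberships[mod] = membership

    selected = LabeledCohort(layers=layers, labels=cohort.labels)
    model, _ = train(selected.subset_samples(train_idx), memberships, config)
    test_cohort = selected.subset_samples(test_idx)
    scores = predict(model, test_cohort, batch_policy=config.batch_policy)
    report = metrics(test_cohort.labels, scores, threshold)
    return report, scores, model


def repeated_cv(cohort: LabeledCohort, collections: dict,
                config: TrainConfig, repeats: int = 5, folds: int = 5,
                feature_counts: dict | None = None,
                modalities=None, exclude_patterns=None,
                threshold: float = 0.5) -> CVResult:
    """Repeated stratified K-fold cross-validation of the full pipeline.

    Folds are stratified and reshuffled per repeat with seed
    ``config.seed + repeat``; every pipeline stage is refitted per fold.
    ``modalities`` restricts the run to a subset (single-omics ablation);
    ``config.attn_dim = 0`` bypasses the attention block (the 0 point of
    the attention-dimension sweep).
    """
    if modalities is not None:
        cohort = cohort.restrict_modalities(list(modalities))
    y = cohort.labels
    class_counts = np.bincount(y)
    if (class_counts < folds).any():
        raise ValueError(f"each class needs >= {folds} members for {folds}-fold CV")

    records = []
    fold_ids = {}
    for repeat in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=config.seed + repeat)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            if len(np.unique(y[te])) < 2:
                raise ValueError(f"fold {fold} of repeat {repeat} has one class")
            fold_cfg = replace(config, seed=config.seed + repeat * folds + fold)
            report, scores, _ = fit_fold(
                cohort, tr, te, collections, fold_cfg,
                feature_counts=feature_counts,
                exclude_patterns=exclude_patterns, threshold=threshold)
            rec = {"repeat": repeat, "fold": fold, "n_test": len(te)}
            rec.update(report.as_dict())
            records.append(rec)
            fold_ids[(repeat, fold)] = [cohort.sample_ids[i] for i in te]

    return CVResult(records=pd.DataFrame.from_records(records),
                    fold_sample_ids=fold_ids)
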