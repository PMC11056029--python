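"""Pre-registered synthetic study protocols for validating the pipeline.

Real recurrence cohorts require controlled-access downloads and preprocessing
choices that cannot be pinned down from public summaries, so the pipeline's
quantitative claims are validated on synthetic cohorts with known ground
truth instead.  Three protocols are defined here and reused by the test
suite, the acceptance script, and the examples:

* **null calibration** — no class signal (effect size 0, 200 samples per
  class): cross-validated AUC must sit at chance level.
* **planted recovery** — strong pathway-structured signal (effect size 2 sd,
  150 samples per class, 3 planted pathways per modality): cross-validated
  AUC must be high, and the attribution pipeline must recover the planted
  features and pathways.
* **ablation panel** — the same planted cohort scored with single modalities
  and with the attention block bypassed, to confirm that multi-omics fusion
  and cross-sample attention do not hurt.

Problem sizes follow the generator defaults (1000/1000/400 mRNA/SNV/miRNA
features); chi-square selection keeps 300/300/100 features, the same ~3x
reduction the selection step applies to real cohorts.  Training uses 150
epochs of Adam; the attention block converges noticeably more slowly than
the rest of the network and needs most of that budget.
"""

from __future__ import annotations

import numpy as np

from .attribution import (aggregate_importance, feature_contributions,
                          pathway_scores, top_biomarkers)
from .evaluate import repeated_cv
from .model import TrainConfig, train
from .pathways import build_membership_matrix
from .preprocess import LabeledCohort, chi2_select, standardize_cohort
from .simulate import SimConfig, simulate_cohort

__all__ = ["SELECT_COUNTS", "study_cohort", "null_calibration",
           "planted_recovery", "ablation_panel"]

SELECT_COUNTS = {"mRNA": 300, "SNV": 300, "miRNA": 100}
EPOCHS = 150


def study_cohort(effect_size: float, n_per_class: int, seed: int,
                 n_signal_pathways: int = 3):
    """Standardized synthetic cohort at the protocol's conditions."""
    cfg = SimConfig(n_recurrence=n_per_class, n_nonrecurrence=n_per_class,
                    effect_size=effect_size,
                    n_signal_pathways=n_signal_pathways, seed=seed)
    cohort, collections, truth = simulate_cohort(cfg)
    return standardize_cohort(cohort), collections, truth


def _cv_auc(cohort, collections, seed, *, attn_dim=64, modalities=None,
            repeats=1, folds=5, epochs=EPOCHS):
    config = TrainConfig(epochs=epochs, seed=seed, attn_dim=attn_dim)
    result = repeated_cv(cohort, collections, config, repeats=repeats,
                         folds=folds, feature_counts=SELECT_COUNTS,
                         modalities=modalities)
    return float(result.mean()["AUC"]), result


def null_calibration(seed: int, n_per_class: int = 200) -> dict:
    """Cross-validated AUC on a cohort with no class signal."""
    cohort, collections, _ = study_cohort(0.0, n_per_class, seed)
    auc, result = _cv_auc(cohort, collections, seed)
    return {"auc": auc, "result": result}


def planted_recovery(seed: int, n_per_class: int = 150,
                     top_count: int = 20) -> dict:
    """CV performance plus attribution recovery on a planted-signal cohort.

    Returns the multi-omics CV AUC, the fraction of the top-`top_count`
    attributed features that are planted (per modality), and the rank of
    every planted pathway in the redistributed pathway scores.
    """
    cohort, collections, truth = study_cohort(2.0, n_per_class, seed)
    auc, result = _cv_auc(cohort, collections, seed)

    # full-cohort fit for attribution
    layers, memberships = {}, {}
    for mod in cohort.modalities:
        layer = chi2_select(cohort.layers[mod], cohort.labels,
                            min(SELECT_COUNTS[mod],
                                cohort.layers[mod].n_features))
        membership, retained = build_membership_matrix(
            layer.feature_ids, collections[mod])
        layers[mod] = layer.subset_features(retained)
        memberships[mod] = membership
    selected = LabeledCohort(layers=layers, labels=cohort.labels)
    model, _ = train(selected, memberships,
                     TrainConfig(epochs=EPOCHS, seed=seed))
    contribs = feature_contributions(model, selected)
    importance = aggregate_importance(contribs, selected.labels)

    top_planted_frac, pathway_ranks = {}, {}
    for mod in selected.modalities:
        planted = set(truth.planted_features[mod])
        count = min(top_count, len(importance[mod]))
        top = top_biomarkers(importance, count=count)[mod]
        top_planted_frac[mod] = float(
            np.mean([f in planted for f in top["feature_id"]]))
        scores = pathway_scores(importance[mod], memberships[mod])
        order = list(scores["pathway_id"])
        pathway_ranks[mod] = {
            pid: (order.index(pid) + 1 if pid in order else len(order) + 1)
            for pid in truth.planted_pathways[mod]
        }
    return {
        "auc": auc, "result": result,
        "top_planted_frac": top_planted_frac,
        "pathway_ranks": pathway_ranks,
        "cohort": cohort, "collections": collections, "truth": truth,
    }


def ablation_panel(cohort, collections, seed: int) -> dict:
    """Single-omics and attention-off CV AUCs on an existing cohort."""
    out = {}
    for mod in cohort.modalities:
        out[f"auc_{mod}"], _ = _cv_auc(cohort, collections, seed,
                                       modalities=[mod])
    out["auc_attn0"], _ = _cv_auc(cohort, collections, seed, attn_dim=0)
    return out
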