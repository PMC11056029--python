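"""Train on a full cohort and rank biomarkers and pathway scores.

Demonstrates the attribution pipeline: gradient x input contributions per
sample, summed over recurrence samples, then redistributed onto pathways
by each feature's out-degree.  Compares the top-ranked units against the
generator's ground truth.
"""

import numpy as np

from pathattn import (LabeledCohort, SimConfig, TrainConfig,
                      aggregate_importance, build_membership_matrix,
                      chi2_select, feature_contributions, pathway_scores,
                      simulate_cohort, standardize_cohort, top_biomarkers,
                      train)

cohort, collections, truth = simulate_cohort(
    SimConfig(n_recurrence=60, n_nonrecurrence=90, effect_size=2.0, seed=7))
cohort = standardize_cohort(cohort)

# keep chi-square-selected, pathway-annotated features only
layers, memberships = {}, {}
for mod in cohort.modalities:
    layer = chi2_select(cohort.layers[mod], cohort.labels,
                        min(200, cohort.layers[mod].n_features))
    membership, retained = build_membership_matrix(layer.feature_ids,
                                                   collections[mod])
    layers[mod] = layer.subset_features(retained)
    memberships[mod] = membership
selected = LabeledCohort(layers=layers, labels=cohort.labels)

model, log = train(selected, memberships, TrainConfig(epochs=100, seed=7))
print(f"final training cross-entropy {log['ce'].iloc[-1]:.4f}, "
      f"training AUC {log['train_auc'].iloc[-1]:.3f}\n")

contribs = feature_contributions(model, selected)
importance = aggregate_importance(contribs, selected.labels)
top = top_biomarkers(importance, count=10)

for mod in selected.modalities:
    planted = set(truth.planted_features[mod])
    hits = [f for f in top[mod]["feature_id"] if f in planted]
    print(f"{mod}: top-10 biomarkers, {len(hits)}/10 are planted features")
    print("   " + ", ".join(top[mod]["feature_id"].head(10)))
    scores = pathway_scores(importance[mod], memberships[mod])
    order = list(scores["pathway_id"])
    ranks = {p: order.index(p) + 1 for p in truth.planted_pathways[mod]}
    total_P, total_C = scores["P"].sum(), importance[mod]["C"].sum()
    print(f"   planted pathway ranks: {ranks} "
          f"(conservation: sum P = {total_P:.3f} = sum C = {total_C:.3f})\n")
# High planted fractions and low ranks show the attribution chain
# (contributions -> importances -> out-degree redistribution) pointing
# back at the pathways that actually generated the signal.
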