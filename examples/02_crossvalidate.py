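"""Cross-validate the pathway-attention classifier on a synthetic cohort.

Runs the full pipeline — per-fold chi-square feature selection, membership
matrix construction, training, prediction — under stratified 5-fold CV and
prints the metric table (mean over folds, as a study would report it).
"""

from pathattn import SimConfig, TrainConfig, repeated_cv, simulate_cohort, \
    standardize_cohort

cohort, collections, _ = simulate_cohort(
    SimConfig(n_recurrence=60, n_nonrecurrence=90, effect_size=2.0, seed=7))
cohort = standardize_cohort(cohort)  # binarize SNV, min-max expression

config = TrainConfig(epochs=60, seed=7)
result = repeated_cv(
    cohort, collections, config,
    repeats=1, folds=5,
    feature_counts={"mRNA": 200, "SNV": 200, "miRNA": 80},
)

print(result.summary().round(3).to_string())
print()
print("mean ± sd over folds:")
print(result.summary_strings().to_string())
# AUC/AUPR well above 0.5 show the pathway-masked network finds the
# planted signal; with effect size 0 the same pipeline sits at chance.
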