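"""Shared fixtures: small synthetic cohorts and a trained model."""

import numpy as np
import pytest

from pathattn import (LabeledCohort, SimConfig, TrainConfig,
                      build_membership_matrix, simulate_cohort,
                      standardize_cohort, train)


SMALL_SIM = dict(
    n_recurrence=40, n_nonrecurrence=60,
    feature_counts={"mRNA": 120, "SNV": 80, "miRNA": 50},
    n_pathways=10, pathway_size_min=5, pathway_size_max=12,
    n_signal_pathways=2, effect_size=2.0, penetrance=1.0, seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """100-sample, 3-modality cohort with strong planted signal."""
    cohort, colls, truth = simulate_cohort(SimConfig(**SMALL_SIM))
    return standardize_cohort(cohort), colls, truth


@pytest.fixture(scope="session")
def small_selected(small_cohort):
    """Cohort restricted to pathway-annotated features, plus memberships."""
    cohort, colls, truth = small_cohort
    layers, mems = {}, {}
    for mod in cohort.modalities:
        mm, retained = build_membership_matrix(
            cohort.layers[mod].feature_ids, colls[mod])
        layers[mod] = cohort.layers[mod].subset_features(retained)
        mems[mod] = mm
    return LabeledCohort(layers=layers, labels=cohort.labels), mems, truth


@pytest.fixture(scope="session")
def trained_model(small_selected):
    cohort, mems, _ = small_selected
    config = TrainConfig(epochs=80, seed=3)
    model, log = train(cohort, mems, config)
    return model, log, cohort, mems


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
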