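"""Attribution: gradient x input contributions and pathway redistribution."""

import numpy as np
import pandas as pd
import pytest

from pathattn.attribution import (FeatureContributions, aggregate_importance,
                                  feature_contributions, pathway_scores,
                                  top_biomarkers)
from pathattn.model import PathAttnModel, TrainConfig
from pathattn.pathways import MembershipMatrix


def linear_model(mems):
    """No hidden layers, identity activation, no attention: y is linear in x."""
    cfg = TrainConfig(seed=2, attn_dim=0, hidden_sizes=(),
                      activation="identity")
    return PathAttnModel(mems, cfg)


@pytest.fixture()
def single_membership(rng):
    k, p = 7, 3
    M = (rng.random((k, p)) < 0.5).astype(float)
    M[M.sum(axis=1) == 0, 0] = 1.0
    return {"mRNA": MembershipMatrix([f"G{i}" for i in range(k)],
                                     [f"P{j}" for j in range(p)], M)}


class TestFeatureContributions:
    def test_linear_model_contributions_are_weight_times_input(
            self, single_membership, rng):
        model = linear_model(single_membership)
        X = rng.normal(size=(5, 7))
        contribs = feature_contributions(model, {"mRNA": X})
        hl = model.hierarchical["mRNA"]
        w_out = model.head.W_out.data[:, 1] - model.head.W_out.data[:, 0]
        w_eff = (hl.weight.data * hl.mask.data) @ w_out
        np.testing.assert_allclose(contribs.contributions["mRNA"],
                                   w_eff[None, :] * X, atol=1e-10)

    def test_input_at_reference_gives_zero(self, single_membership):
        model = linear_model(single_membership)
        contribs = feature_contributions(model, {"mRNA": np.zeros((3, 7))})
        np.testing.assert_array_equal(contribs.contributions["mRNA"], 0.0)

    def test_scaling_an_input_scales_its_contribution(self, single_membership,
                                                      rng):
        model = linear_model(single_membership)
        X = rng.normal(size=(2, 7))
        c1 = feature_contributions(model, {"mRNA": X}).contributions["mRNA"]
        X2 = X.copy()
        X2[:, 3] *= 5.0
        c2 = feature_contributions(model, {"mRNA": X2}).contributions["mRNA"]
        np.testing.assert_allclose(c2[:, 3], 5.0 * c1[:, 3], atol=1e-10)

    def test_gradient_times_delta_matches_finite_differences(
            self, trained_model):
        model, _, cohort, _ = trained_model
        X = {m: cohort.layers[m].values[:6] for m in model.modalities}
        contribs = feature_contributions(model, X)
        from pathattn.autodiff import Tensor
        eps = 1e-5
        rng = np.random.default_rng(0)
        for mod in model.modalities:
            for _ in range(10):  # spot-check random (sample, feature) cells
                s = rng.integers(0, 6)
                i = rng.integers(0, X[mod].shape[1])
                up, down = {m: v.copy() for m, v in X.items()}, \
                           {m: v.copy() for m, v in X.items()}
                up[mod][s, i] += eps
                down[mod][s, i] -= eps
                lg_up = model.forward({m: Tensor(v) for m, v in up.items()}
                                      ).data[s]
                lg_dn = model.forward({m: Tensor(v) for m, v in down.items()}
                                      ).data[s]
                grad_fd = ((lg_up[1] - lg_up[0])
                           - (lg_dn[1] - lg_dn[0])) / (2 * eps)
                expected = grad_fd * X[mod][s, i]
                got = contribs.contributions[mod][s, i]
                assert got == pytest.approx(expected, rel=1e-4, abs=1e-8)

    def test_reference_policy_differentiates_query_only(self, trained_model):
        model, _, cohort, _ = trained_model
        X = {m: cohort.layers[m].values[:3] for m in model.modalities}
        contribs = feature_contributions(model, X, batch_policy="reference")
        for mod in model.modalities:
            assert np.isfinite(contribs.contributions[mod]).all()
            assert contribs.contributions[mod].shape == X[mod].shape


def contrib_set(values, labels=None):
    n, k = values.shape
    return FeatureContributions(
        sample_ids=[f"S{i}" for i in range(n)],
        contributions={"mRNA": values},
        feature_ids={"mRNA": [f"G{i}" for i in range(k)]},
    )


class TestAggregateImportance:
    def test_sums_over_recurrence_samples_only(self):
        c = contrib_set(np.array([[0.2], [0.3], [99.0]]))
        out = aggregate_importance(c, labels=[1, 1, 0])
        assert out["mRNA"]["C"].iloc[0] == pytest.approx(0.5)

    def test_changing_nonrecurrence_rows_leaves_c_unchanged(self, rng):
        base = rng.normal(size=(6, 4))
        labels = np.array([1, 0, 1, 0, 0, 1])
        out1 = aggregate_importance(contrib_set(base), labels)
        noisy = base.copy()
        noisy[labels == 0] = rng.normal(size=(3, 4)) * 100
        out2 = aggregate_importance(contrib_set(noisy), labels)
        pd.testing.assert_frame_equal(out1["mRNA"], out2["mRNA"])

    def test_single_recurrence_sample_equals_its_row(self, rng):
        vals = rng.normal(size=(3, 5))
        out = aggregate_importance(contrib_set(vals), [0, 1, 0])
        np.testing.assert_allclose(out["mRNA"]["C"], vals[1])

    def test_no_recurrence_samples_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            aggregate_importance(contrib_set(np.ones((2, 2))), [0, 0])

    def test_rank_is_permutation_with_id_tiebreak(self):
        c = contrib_set(np.array([[1.0, 3.0, 1.0]]))
        out = aggregate_importance(c, [1])["mRNA"]
        assert sorted(out["rank"]) == [1, 2, 3]
        assert out.loc[out["feature_id"] == "G1", "rank"].item() == 1
        # tied C=1.0 for G0 and G2: lexicographic id order
        assert out.loc[out["feature_id"] == "G0", "rank"].item() == 2


class TestPathwayScores:
    def test_out_degree_split_across_three_pathways(self):
        mm = MembershipMatrix(["G0"], ["P0", "P1", "P2"],
                              np.ones((1, 3)))
        imp = pd.DataFrame({"feature_id": ["G0"], "C": [6.0], "rank": [1]})
        out = pathway_scores(imp, mm)
        np.testing.assert_allclose(out["P"], [2.0, 2.0, 2.0])

    def test_hand_example_and_conservation(self):
        # G0: C=4 in {P1}; G1: C=2 in {P1,P2} -> P1 = 4 + 1 = 5, P2 = 1
        mm = MembershipMatrix(["G0", "G1"], ["P1", "P2"],
                              np.array([[1.0, 0.0], [1.0, 1.0]]))
        imp = pd.DataFrame({"feature_id": ["G0", "G1"], "C": [4.0, 2.0],
                            "rank": [1, 2]})
        out = pathway_scores(imp, mm).set_index("pathway_id")
        assert out.loc["P1", "P"] == pytest.approx(5.0)
        assert out.loc["P2", "P"] == pytest.approx(1.0)
        assert out["P"].sum() == pytest.approx(imp["C"].sum(), abs=1e-8)

    def test_zero_importance_gives_zero_scores(self):
        mm = MembershipMatrix(["G0", "G1"], ["P1"], np.ones((2, 1)))
        imp = pd.DataFrame({"feature_id": ["G0", "G1"], "C": [0.0, 0.0],
                            "rank": [1, 2]})
        assert (pathway_scores(imp, mm)["P"] == 0).all()

    def test_missing_feature_rejected(self):
        mm = MembershipMatrix(["G0"], ["P1"], np.ones((1, 1)))
        imp = pd.DataFrame({"feature_id": ["G9"], "C": [1.0], "rank": [1]})
        with pytest.raises(KeyError, match="absent"):
            pathway_scores(imp, mm)

    def test_conservation_on_random_fixtures(self, rng):
        for _ in range(100):
            k, p = rng.integers(2, 15), rng.integers(1, 8)
            M = (rng.random((k, p)) < 0.4).astype(float)
            M[M.sum(axis=1) == 0, rng.integers(0, p)] = 1.0
            keep = M.sum(axis=0) > 0
            M = M[:, keep]
            mm = MembershipMatrix([f"G{i}" for i in range(k)],
                                  [f"P{j}" for j in range(int(keep.sum()))], M)
            C = rng.normal(size=k)
            imp = pd.DataFrame({"feature_id": mm.feature_ids, "C": C,
                                "rank": np.arange(1, k + 1)})
            out = pathway_scores(imp, mm)
            assert out["P"].sum() == pytest.approx(C.sum(), abs=1e-8)


class TestTopBiomarkers:
    def test_top_count_rows_per_modality(self, rng):
        c = contrib_set(rng.normal(size=(4, 30)))
        imp = aggregate_importance(c, [1, 1, 0, 0])
        top = top_biomarkers(imp, count=20)
        assert len(top["mRNA"]) == 20
        assert top["mRNA"]["rank"].tolist() == list(range(1, 21))

    def test_count_equals_k_gives_full_ranking(self, rng):
        c = contrib_set(rng.normal(size=(2, 5)))
        imp = aggregate_importance(c, [1, 0])
        assert len(top_biomarkers(imp, count=5)["mRNA"]) == 5

    def test_count_exceeding_features_rejected(self, rng):
        c = contrib_set(rng.normal(size=(2, 5)))
        imp = aggregate_importance(c, [1, 0])
        with pytest.raises(ValueError, match="only 5"):
            top_biomarkers(imp, count=6)


def test_planted_features_enriched_in_top_ranks(trained_model, small_selected):
    """Top-ranked features are enriched for planted ones on every modality.

    On this small cohort the three modalities carry redundant signal, so the
    model need not use each one equally; the check is enrichment over the
    modality's planted-feature base rate, not absolute recovery (that bar is
    set by the dedicated planted-recovery test at full study size).
    """
    model, _, cohort, mems = trained_model
    _, _, truth = small_selected
    contribs = feature_contributions(model, cohort)
    imp = aggregate_importance(contribs, cohort.labels)
    ratios = []
    for mod in model.modalities:
        planted = set(truth.planted_features[mod])
        n_top = min(10, len(imp[mod]))
        top = top_biomarkers(imp, count=n_top)[mod]
        frac = np.mean([f in planted for f in top["feature_id"]])
        base = np.mean([f in planted for f in imp[mod]["feature_id"]])
        assert frac >= base, f"{mod}: top-{n_top} below base rate"
        ratios.append(frac / base)
    assert np.mean(ratios) >= 1.5, f"weak mean enrichment: {ratios}"
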