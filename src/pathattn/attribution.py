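"""Gradient-based feature attribution and pathway score redistribution.

Per sample s and input feature i the contribution is

    c_i^s = (d y / d x_i^s) * (t_i - t_i^0)

with y the pre-softmax recurrence-class logit margin (probabilities
saturate and flatten gradients; with a two-logit softmax head only the
difference between the logits is identified) and the reference activation
t^0 = 0 by default.  This is the gradient x input special case of
DeepLIFT's rescale rule.

Feature importances are the sum of c_i^s over the recurrence samples,
C_i = sum_s c_i^s, and are redistributed to pathways through the membership
matrix: each feature's C is divided by its out-degree (number of pathways
it connects to) and the pathway score P is the sum of those shares over
its members.  When every feature is annotated this conserves the total:
sum_p P_p = sum_i C_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import PathAttnModel
from .pathways import MembershipMatrix
from .preprocess import LabeledCohort

__all__ = [
    "FeatureContributions",
    "feature_contributions",
    "aggregate_importance",
    "pathway_scores",
    "top_biomarkers",
]


@dataclass
class FeatureContributions:
    """Per-sample, per-feature contribution scores, one matrix per modality."""

    sample_ids: list
    contributions: dict   # modality -> (n, k) array
    feature_ids: dict     # modality -> list of k ids

    def to_frame(self, modality: str) -> pd.DataFrame:
        return pd.DataFrame(self.contributions[modality],
                            index=self.sample_ids,
                            columns=self.feature_ids[modality])


def _graph_nodes(output: Tensor) -> list:
    nodes, stack, seen = [], [output], set()
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        nodes.append(node)
        stack.extend(node._parents)
    return nodes


def feature_contributions(
    model: PathAttnModel,
    cohort,
    target: str = "logit",
    reference: dict | None = None,
    batch_policy: str = "self",
    reference_bank: dict | None = None,
) -> FeatureContributions:
    """Gradient x (input - reference) for every sample and input feature.

    ``target`` selects what y is: the recurrence-class pre-softmax logit
    (default) or the recurrence probability (``"proba"``).  The batch
    policy matches prediction: under ``"self"`` all samples form one
    attention batch and each sample's own-input gradient is taken; under
    ``"reference"`` each sample is scored against the training bank and
    only the query sample's input is differentiated.
    """
    if isinstance(cohort, LabeledCohort):
        sample_ids = cohort.sample_ids
        inputs = {m: cohort.layers[m].values for m in model.modalities}
    else:
        inputs = {m: np.asarray(v, dtype=np.float64) for m, v in cohort.items()}
        sample_ids = list(range(next(iter(inputs.values())).shape[0]))
    if reference is None:
        reference = {m: np.zeros(inputs[m].shape[1]) for m in model.modalities}

    n = len(sample_ids)
    out = {m: np.empty_like(inputs[m]) for m in model.modalities}

    def _target_tensor(tensors: dict) -> Tensor:
        if target == "logit":
            # margin between the two class logits: the head is a 2-logit
            # softmax, so only the difference is identified — attributing
            # one raw logit would split credit arbitrarily between the two
            logits = model.forward(tensors)
            return logits.take_column(1) - logits.take_column(0)
        if target == "proba":
            return model.forward_proba(tensors)
        raise ValueError(f"unknown attribution target {target!r}")

    if batch_policy == "self":
        tensors = {m: Tensor(inputs[m], requires_grad=True)
                   for m in model.modalities}
        y = _target_tensor(tensors)
        nodes = _graph_nodes(y)
        for s in range(n):
            for node in nodes:
                node.zero_grad()
            onehot = np.zeros(n)
            onehot[s] = 1.0
            y.backward(onehot)
            for m in model.modalities:
                grad = tensors[m].grad[s]
                out[m][s] = grad * (inputs[m][s] - reference[m])
    elif batch_policy == "reference":
        bank = reference_bank if reference_bank is not None else model.train_bank
        if bank is None:
            raise ValueError("reference batch policy requires a training bank")
        for s in range(n):
            query = {m: Tensor(inputs[m][s:s + 1], requires_grad=True)
                     for m in model.modalities}
            batch = {}
            for m in model.modalities:
                bank_t = Tensor(bank[m])
                from .autodiff import concat
                batch[m] = concat([bank_t, query[m]], axis=0)
            y = _target_tensor(batch)
            y.backward(np.eye(y.shape[0])[-1])
            for m in model.modalities:
                out[m][s] = query[m].grad[0] * (inputs[m][s] - reference[m])
    else:
        raise ValueError(f"unknown batch policy {batch_policy!r}")

    if any(not np.isfinite(v).all() for v in out.values()):
        raise ValueError("non-finite contribution scores")
    return FeatureContributions(
        sample_ids=list(sample_ids),
        contributions=out,
        feature_ids={m: list(model.feature_ids(m)) for m in model.modalities},
    )


def aggregate_importance(contribs: FeatureContributions, labels,
                         restrict_to: int = 1,
                         use_abs: bool = False) -> dict:
    """Sum contributions over the samples of one class (recurrence default).

    Returns one DataFrame per modality with columns ``feature_id``, ``C``
    and ``rank`` (1 = most important; descending by C, signed unless
    ``use_abs``; ties broken by feature id).
    """
    labels = np.asarray(labels)
    if len(labels) != len(contribs.sample_ids):
        raise ValueError("labels do not align with contribution samples")
    mask = labels == restrict_to
    if not mask.any():
        raise ValueError(f"no samples with label {restrict_to} to aggregate over")

    result = {}
    for mod, mat in contribs.contributions.items():
        C = mat[mask].sum(axis=0)
        key = np.abs(C) if use_abs else C
        df = pd.DataFrame({"feature_id": contribs.feature_ids[mod], "C": C})
        order = df.assign(_key=key).sort_values(
            ["_key", "feature_id"], ascending=[False, True], kind="stable"
        ).index
        ranks = np.empty(len(df), dtype=int)
        ranks[order] = np.arange(1, len(df) + 1)
        df["rank"] = ranks
        result[mod] = df
    return result


def pathway_scores(importance: pd.DataFrame,
                   membership: MembershipMatrix) -> pd.DataFrame:
    """Redistribute feature importance onto pathways by out-degree.

    ``importance`` is one modality's aggregated table.  Returns a table
    with ``pathway_id``, ``P`` and ``contributing_features`` (list of
    (feature_id, mean_C) pairs), sorted descending by P.
    """
    pos = {f: i for i, f in enumerate(membership.feature_ids)}
    missing = [f for f in importance["feature_id"] if f not in pos]
    if missing:
        raise KeyError(f"features absent from membership matrix: {missing[:5]}")
    C = np.zeros(membership.n_features)
    for f, c in zip(importance["feature_id"], importance["C"]):
        C[pos[f]] = c
    deg = membership.out_degrees()
    mean_C = C / deg  # membership invariant guarantees deg >= 1
    P = membership.values.T @ mean_C

    rows = []
    for j, pid in enumerate(membership.pathway_ids):
        members = np.flatnonzero(membership.values[:, j])
        contrib = sorted(
            ((membership.feature_ids[i], mean_C[i]) for i in members),
            key=lambda t: (-t[1], t[0]),
        )
        rows.append({"pathway_id": pid, "P": P[j],
                     "contributing_features": contrib})
    df = pd.DataFrame(rows).sort_values(
        ["P", "pathway_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df


def top_biomarkers(importance: dict, count: int = 20) -> dict:
    """Top-`count` features per modality, by rank."""
    out = {}
    for mod, df in importance.items():
        if count > len(df):
            raise ValueError(
                f"{mod}: requested top {count} but only {len(df)} features")
        out[mod] = (df.sort_values("rank", kind="stable")
                      .head(count).reset_index(drop=True))
    return out
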