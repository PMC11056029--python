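"""Pathway-masked network with cross-sample attention for recurrence prediction.

Architecture, per omics modality z:

1. *Pathway layer*: ``H^z = h(X^z (W^z o M^z) + b^z)`` where ``M^z`` is the
   binary feature x pathway membership matrix and ``o`` is the elementwise
   product.  Connections absent from ``M^z`` carry no weight and receive no
   gradient.  In ``literal`` mode the weight is fixed at all-ones so the
   propagation reduces to ``h(X M + b)`` exactly.
2. *Cross-sample self-attention*: pathway representations of the samples in
   a batch attend to each other — ``Q = H Wq``, ``K = H Wk``, ``V = H Wv``,
   ``alpha_ij = Q_i . K_j / sqrt(d)``, ``w_i. = softmax_j(alpha_i.)``,
   ``B_i = sum_j w_ij V_j`` — so each sample's representation borrows from
   similar samples in the batch.  ``attn_dim = 0`` bypasses the block
   (``B = H``).
3. *Fusion + head*: per-modality outputs are concatenated in fixed modality
   order and an MLP produces two class logits; the recurrence probability
   is the softmax of the second logit.

The objective is class-weighted binary cross-entropy with weights
``w_j = N / (2 N_j)`` plus an L2 penalty ``gamma * ||params||^2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .autodiff import Tensor, concat, softmax_rows
from .pathways import MembershipMatrix
from .preprocess import LabeledCohort, MODALITIES

__all__ = [
    "HierarchicalLayerParams",
    "AttentionParams",
    "AttentionOutput",
    "PathAttnModel",
    "TrainConfig",
    "masked_forward",
    "pathway_self_attention",
    "fuse",
    "compute_class_weights",
    "weighted_loss",
    "train",
    "predict",
]

_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
}

_PROB_EPS = 1e-7  # clamp for probabilities entering log()


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    l2_gamma: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    attn_dim: int = 64
    hidden_sizes: tuple = (128, 32)
    activation: str = "relu"
    mask_mode: str = "trainable"  # or "literal"
    class_weights: tuple | None = None  # (w0, w1); None = from labels
    batch_policy: str = "self"  # or "reference"

    def __post_init__(self):
        if self.l2_gamma < 0:
            raise ValueError("l2_gamma must be >= 0")
        if self.attn_dim > 0 and self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 when attention is enabled "
                             "(a 1-sample batch degenerates to identity attention)")
        if self.mask_mode not in ("trainable", "literal"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class HierarchicalLayerParams:
    """Masked feature->pathway layer for one modality."""

    def __init__(self, mask: np.ndarray, activation: str = "relu",
                 mode: str = "trainable", rng: np.random.Generator | None = None):
        self.mask = Tensor(np.asarray(mask, dtype=np.float64))
        k, p = self.mask.shape
        self.mode = mode
        self.activation = activation
        if mode == "literal":
            self.weight = Tensor(np.ones((k, p)))  # fixed, not trained
        else:
            rng = rng or np.random.default_rng(0)
            limit = math.sqrt(6.0 / (k + p))
            self.weight = Tensor(rng.uniform(-limit, limit, size=(k, p)),
                                 requires_grad=True)
        self.bias = Tensor(np.zeros(p), requires_grad=True)

    @property
    def shape(self):
        return self.mask.shape

    def parameters(self):
        params = [self.bias]
        if self.mode == "trainable":
            params.append(self.weight)
        return params

    def effective_weight(self) -> np.ndarray:
        return self.weight.data * self.mask.data


class AttentionParams:
    """Query/key/value projections for cross-sample attention.

    The query/key projections are initialized with a gain on the Glorot
    limit (default 32).  Pathway representations entering the block are
    small at initialization, so unit-gain projections give near-zero
    attention scores, a uniform softmax, and batch-averaged outputs that
    carry almost no per-sample signal — a plateau that Adam escapes only
    very slowly, leaving the block a liability rather than an asset.  The
    gain spreads the initial scores enough for the softmax to
    differentiate samples from the first epochs; the weights then adapt
    from an informative starting point instead of a uniform average.
    """

    def __init__(self, p: int, d: int, rng: np.random.Generator | None = None,
                 qk_gain: float = 32.0):
        if d <= 0:
            raise ValueError("attention dimension must be positive")
        rng = rng or np.random.default_rng(0)
        limit = math.sqrt(6.0 / (p + d))
        qk = qk_gain * limit
        self.Wq = Tensor(rng.uniform(-qk, qk, size=(p, d)), requires_grad=True)
        self.Wk = Tensor(rng.uniform(-qk, qk, size=(p, d)), requires_grad=True)
        self.Wv = Tensor(rng.uniform(-limit, limit, size=(p, d)), requires_grad=True)
        self.d = d
        self.scale = math.sqrt(d)

    def parameters(self):
        return [self.Wq, self.Wk, self.Wv]


@dataclass
class AttentionOutput:
    attn_scores: np.ndarray   # (n, n) alpha_ij
    attn_weights: np.ndarray  # (n, n) row-stochastic w_ij
    values: np.ndarray        # (n, d) B


def masked_forward(layer: HierarchicalLayerParams, X) -> Tensor:
    """h(X (W o M) + b); in literal mode W is all-ones so this is h(X M + b)."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    if X.shape[1] != layer.mask.shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features but mask expects {layer.mask.shape[0]}"
        )
    W = layer.weight * layer.mask if layer.mode == "trainable" else layer.mask
    out = X @ W + layer.bias
    return _ACTIVATIONS[layer.activation](out)


def pathway_self_attention(params: AttentionParams, H) -> tuple:
    """Scaled dot-product attention across the samples of a batch.

    Returns ``(B, AttentionOutput)`` where B is the differentiable output
    tensor and the record holds the realized scores/weights.
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    if not np.isfinite(H.data).all():
        raise ValueError("non-finite values in attention input")
    Q = H @ params.Wq
    K = H @ params.Wk
    V = H @ params.Wv
    scores = (Q @ _transpose(K)) * (1.0 / params.scale)
    weights = softmax_rows(scores)
    B = weights @ V
    record = AttentionOutput(scores.data.copy(), weights.data.copy(), B.data.copy())
    return B, record


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, t.requires_grad, (t,))

    def _backward(g):
        if t.requires_grad:
            t._accum(g.T)

    out._backward = _backward
    return out


def fuse(outputs: list) -> Tensor:
    """Concatenate per-modality representations column-wise."""
    tensors = [o if isinstance(o, Tensor) else Tensor(o) for o in outputs]
    n = tensors[0].shape[0]
    for t in tensors[1:]:
        if t.shape[0] != n:
            raise ValueError("batch size mismatch between modalities")
    if len(tensors) == 1:
        return tensors[0]
    return concat(tensors, axis=1)


def compute_class_weights(labels) -> tuple:
    """w_j = N / (n_class * N_j) for the binary case (n_class = 2)."""
    labels = np.asarray(labels)
    n = len(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    return n / (2.0 * n0), n / (2.0 * n1)


class _MLPHead:
    """Fully connected head ending in two class logits.

    All weights are Glorot-uniform, biases zero.  (A zero-initialized
    output layer would pin every untrained probability at 0.5 but creates
    a saddle that stalls learning through the attention block, whose
    batch-mixed representations carry little per-sample variation at
    initialization.)
    """

    def __init__(self, in_dim: int, hidden_sizes, activation: str,
                 rng: np.random.Generator):
        self.activation = activation
        self.layers = []
        prev = in_dim
        for h in hidden_sizes:
            limit = math.sqrt(6.0 / (prev + h))
            W = Tensor(rng.uniform(-limit, limit, size=(prev, h)), requires_grad=True)
            b = Tensor(np.zeros(h), requires_grad=True)
            self.layers.append((W, b))
            prev = h
        limit = math.sqrt(6.0 / (prev + 2))
        self.W_out = Tensor(rng.uniform(-limit, limit, size=(prev, 2)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(2), requires_grad=True)

    def zero_output_layer(self):
        """Zero the final layer: every probability becomes exactly 0.5."""
        self.W_out.data[:] = 0.0
        self.b_out.data[:] = 0.0

    def forward(self, Z: Tensor) -> Tensor:
        act = _ACTIVATIONS[self.activation]
        for W, b in self.layers:
            Z = act(Z @ W + b)
        return Z @ self.W_out + self.b_out

    def parameters(self):
        params = []
        for W, b in self.layers:
            params.extend([W, b])
        params.extend([self.W_out, self.b_out])
        return params


class PathAttnModel:
    """Trained (or trainable) pathway-attention classifier."""

    def __init__(self, memberships: dict, config: TrainConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.modalities = [m for m in MODALITIES if m in memberships] + [
            m for m in memberships if m not in MODALITIES
        ]
        self.memberships: dict = dict(memberships)
        self.hierarchical: dict = {}
        self.attention: dict = {}
        fused_dim = 0
        for mod in self.modalities:
            mm: MembershipMatrix = memberships[mod]
            self.hierarchical[mod] = HierarchicalLayerParams(
                mm.values, activation=config.activation,
                mode=config.mask_mode, rng=rng)
            if config.attn_dim > 0:
                self.attention[mod] = AttentionParams(mm.n_pathways,
                                                      config.attn_dim, rng=rng)
                fused_dim += config.attn_dim
            else:
                fused_dim += mm.n_pathways
        self.fused_dim = fused_dim
        self.head = _MLPHead(fused_dim, config.hidden_sizes,
                             config.activation, rng)
        self.train_bank: dict | None = None  # inputs for "reference" scoring

    # ---- forward -------------------------------------------------------
    def forward(self, inputs: dict) -> Tensor:
        """Batch forward pass; `inputs` maps modality -> Tensor/array (n, k)."""
        outputs = []
        for mod in self.modalities:
            X = inputs[mod]
            H = masked_forward(self.hierarchical[mod], X)
            if mod in self.attention:
                B, _ = pathway_self_attention(self.attention[mod], H)
            else:
                B = H
            outputs.append(B)
        Z = fuse(outputs)
        return self.head.forward(Z)

    def forward_proba(self, inputs: dict) -> Tensor:
        """Recurrence probability (softmax of the two logits, class-1 column)."""
        logits = self.forward(inputs)
        return softmax_rows(logits).take_column(1)

    def parameters(self):
        params = []
        for mod in self.modalities:
            params.extend(self.hierarchical[mod].parameters())
            if mod in self.attention:
                params.extend(self.attention[mod].parameters())
        params.extend(self.head.parameters())
        return params

    def l2_terms(self):
        """Tensors whose squared norms enter the L2 penalty.

        Hierarchical weights are penalized through the mask so that
        connections absent from the membership matrix stay inert: they
        influence neither the forward pass nor the regularizer.
        """
        terms = []
        for mod in self.modalities:
            hl = self.hierarchical[mod]
            if hl.mode == "trainable":
                terms.append(hl.weight * hl.mask)
            terms.append(hl.bias)
            if mod in self.attention:
                terms.extend(self.attention[mod].parameters())
        terms.extend(self.head.parameters())
        return terms

    def feature_ids(self, modality: str) -> list:
        return self.memberships[modality].feature_ids

    # ---- persistence ---------------------------------------------------
    def save(self, path):
        arrays = {}
        for mod in self.modalities:
            hl = self.hierarchical[mod]
            arrays[f"{mod}__weight"] = hl.weight.data
            arrays[f"{mod}__bias"] = hl.bias.data
            arrays[f"{mod}__mask"] = hl.mask.data
            if mod in self.attention:
                at = self.attention[mod]
                arrays[f"{mod}__Wq"] = at.Wq.data
                arrays[f"{mod}__Wk"] = at.Wk.data
                arrays[f"{mod}__Wv"] = at.Wv.data
        for i, (W, b) in enumerate(self.head.layers):
            arrays[f"head__W{i}"] = W.data
            arrays[f"head__b{i}"] = b.data
        arrays["head__W_out"] = self.head.W_out.data
        arrays["head__b_out"] = self.head.b_out.data
        meta = {
            "config": asdict(self.config),
            "modalities": self.modalities,
            "feature_ids": {m: self.memberships[m].feature_ids
                            for m in self.modalities},
            "pathway_ids": {m: self.memberships[m].pathway_ids
                            for m in self.modalities},
            "mask_checksums": {m: int(self.memberships[m].values.sum())
                               for m in self.modalities},
        }
        np.savez(path, **arrays)
        with open(str(path) + ".json", "wt", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "PathAttnModel":
        with open(str(path) + ".json", "rt", encoding="utf-8") as fh:
            meta = json.load(fh)
        cfg_d = meta["config"]
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        if cfg_d.get("class_weights"):
            cfg_d["class_weights"] = tuple(cfg_d["class_weights"])
        config = TrainConfig(**cfg_d)
        data = np.load(str(path) if str(path).endswith(".npz") else path)
        memberships = {
            m: MembershipMatrix(meta["feature_ids"][m], meta["pathway_ids"][m],
                                data[f"{m}__mask"])
            for m in meta["modalities"]
        }
        model = cls(memberships, config)
        for mod in model.modalities:
            hl = model.hierarchical[mod]
            hl.weight.data = data[f"{mod}__weight"]
            hl.bias.data = data[f"{mod}__bias"]
            if mod in model.attention:
                at = model.attention[mod]
                at.Wq.data = data[f"{mod}__Wq"]
                at.Wk.data = data[f"{mod}__Wk"]
                at.Wv.data = data[f"{mod}__Wv"]
        for i, (W, b) in enumerate(model.head.layers):
            W.data = data[f"head__W{i}"]
            b.data = data[f"head__b{i}"]
        model.head.W_out.data = data["head__W_out"]
        model.head.b_out.data = data["head__b_out"]
        return model


def weighted_loss(model: PathAttnModel | None, proba: Tensor, labels,
                  w0: float, w1: float, gamma: float) -> Tensor:
    """Class-weighted binary cross-entropy plus gamma * ||params||^2.

    ``proba`` holds recurrence probabilities in (0, 1); values at exactly
    0 or 1 are clamped with epsilon 1e-7.  With w0 = w1 = 1 and gamma = 0
    this is plain binary cross-entropy.
    """
    if not np.isfinite(proba.data).all():
        raise ValueError("non-finite predictions in loss")
    y = np.asarray(labels, dtype=np.float64)
    p = proba * (1.0 - 2.0 * _PROB_EPS) + _PROB_EPS
    ll = Tensor(y * w1) * p.log() + Tensor((1.0 - y) * w0) * (1.0 - p).log()
    loss = -ll.mean()
    if gamma > 0 and model is not None:
        reg = None
        terms = model.l2_terms() if hasattr(model, "l2_terms") else model.parameters()
        for prm in terms:
            sq = (prm * prm).sum()
            reg = sq if reg is None else reg + sq
        loss = loss + reg * gamma
    return loss


class _Adam:
    def __init__(self, params: list, lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class _SGD:
    def __init__(self, params: list, lr: float):
        self.params = params
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _cohort_inputs(cohort: LabeledCohort, modalities) -> dict:
    return {m: cohort.layers[m].values for m in modalities}


def train(cohort: LabeledCohort, memberships: dict,
          config: TrainConfig) -> tuple:
    """Fit the model on a cohort; returns ``(model, log)``.

    The log is a DataFrame with one row per epoch: mean batch objective
    (``loss``, including the L2 penalty), the plain weighted cross-entropy
    (``ce``), and full-cohort training AUC.  Deterministic given
    ``config.seed``.  Aborts on a non-finite loss.
    """
    from sklearn.metrics import roc_auc_score

    for mod, mm in memberships.items():
        if mm.feature_ids != cohort.layers[mod].feature_ids:
            raise ValueError(f"membership rows for {mod} do not match the "
                             f"cohort's feature order")
    model = PathAttnModel(memberships, config)
    y = cohort.labels
    if config.class_weights is not None:
        w0, w1 = config.class_weights
    else:
        w0, w1 = compute_class_weights(y)

    opt_cls = {"adam": _Adam, "sgd": _SGD}[config.optimizer]
    opt = opt_cls(model.parameters(), config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = cohort.n_samples
    X_full = _cohort_inputs(cohort, model.modalities)

    records = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        batches = [order[i:i + config.batch_size]
                   for i in range(0, n, config.batch_size)]
        # a trailing 1-sample batch would degenerate attention: merge it
        if len(batches) > 1 and len(batches[-1]) == 1:
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches = batches[:-1]
        epoch_losses: list = []
        epoch_ces: list = []
        for idx in batches:
            inputs = {m: Tensor(X_full[m][idx]) for m in model.modalities}
            proba = model.forward_proba(inputs)
            loss = weighted_loss(model, proba, y[idx], w0, w1, config.l2_gamma)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            p = np.clip(proba.data, _PROB_EPS, 1 - _PROB_EPS)
            yb = y[idx]
            epoch_ces.append(float(-np.mean(
                w1 * yb * np.log(p) + w0 * (1 - yb) * np.log(1 - p))))
        train_scores = predict(model, X_full, batch_policy="self")
        auc = roc_auc_score(y, train_scores) if len(np.unique(y)) == 2 else np.nan
        records.append({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                        "ce": float(np.mean(epoch_ces)),
                        "train_auc": float(auc)})

    model.train_bank = {m: X_full[m].copy() for m in model.modalities}
    log = pd.DataFrame.from_records(records)
    return model, log


def predict(model: PathAttnModel, inputs, batch_policy: str = "self",
            reference_bank: dict | None = None,
            bank_size: int | None = None) -> np.ndarray:
    """Recurrence probabilities for a set of samples.

    ``batch_policy="self"``: the given samples attend among themselves as
    one batch (faithful to batched training; each sample's score depends
    on its co-batch members).

    ``batch_policy="reference"``: each sample is scored alone against a
    fixed bank of training samples, so its score is independent of which
    other samples are submitted alongside it.
    """
    if isinstance(inputs, LabeledCohort):
        inputs = _cohort_inputs(inputs, model.modalities)
    inputs = {m: np.asarray(v, dtype=np.float64) for m, v in inputs.items()}
    for mod in model.modalities:
        if mod not in inputs:
            raise KeyError(f"missing modality {mod!r} in prediction inputs")
        if inputs[mod].shape[1] != len(model.feature_ids(mod)):
            raise ValueError(f"{mod}: feature count does not match training")

    if batch_policy == "self":
        return model.forward_proba(
            {m: Tensor(inputs[m]) for m in model.modalities}).data.copy()
    if batch_policy == "reference":
        bank = reference_bank if reference_bank is not None else model.train_bank
        if bank is None:
            raise ValueError("reference batch policy requires a training bank")
        if bank_size is not None:
            bank = {m: v[:bank_size] for m, v in bank.items()}
        n = next(iter(inputs.values())).shape[0]
        out = np.empty(n)
        for i in range(n):
            batch = {m: Tensor(np.vstack([bank[m], inputs[m][i:i + 1]]))
                     for m in model.modalities}
            out[i] = model.forward_proba(batch).data[-1]
        return out
    raise ValueError(f"unknown batch policy {batch_policy!r}")
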