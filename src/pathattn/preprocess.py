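"""Loading, normalization and chi-square feature selection for omics layers.

Conventions applied here:

* duplicate sample or feature identifiers are collapsed by arithmetic mean;
* SNV values are binarized (any variant count > 0 becomes 1);
* expression is optionally log2(x+1)-transformed, then min-max scaled per
  feature to [0, 1] (a non-negative range is required downstream by the
  chi-square selector);
* feature selection keeps the m highest chi-square statistics between each
  non-negative feature and the binary class label, with ties broken by
  original feature order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2 as _sk_chi2

logger = logging.getLogger(__name__)

MODALITIES = ("mRNA", "SNV", "miRNA")

__all__ = [
    "OmicsLayer",
    "LabeledCohort",
    "load_omics_matrix",
    "load_labels",
    "binarize_snv",
    "normalize_expression",
    "chi2_scores",
    "chi2_select",
    "assemble_cohort",
    "standardize_cohort",
    "MODALITIES",
]


@dataclass
class OmicsLayer:
    """One omics modality: samples x features with identifiers."""

    modality: str
    sample_ids: list
    feature_ids: list
    values: np.ndarray  # (n, k) float64

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n, k = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != k:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.feature_ids)) != k:
            raise ValueError("feature ids are not unique")
        if np.isnan(self.values).any():
            raise ValueError(f"{self.modality}: matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def subset_samples(self, sample_ids) -> "OmicsLayer":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsLayer(self.modality, list(sample_ids),
                          list(self.feature_ids), self.values[idx])

    def subset_features(self, feature_ids) -> "OmicsLayer":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return OmicsLayer(self.modality, list(self.sample_ids),
                          list(feature_ids), self.values[:, idx])


@dataclass
class LabeledCohort:
    """Sample-aligned omics layers plus a binary recurrence label."""

    layers: dict = field(default_factory=dict)  # modality -> OmicsLayer
    labels: np.ndarray = None  # (n,) of {0, 1}; 1 = recurrence

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        sample_ids = None
        for mod, layer in self.layers.items():
            if sample_ids is None:
                sample_ids = layer.sample_ids
            elif layer.sample_ids != sample_ids:
                raise ValueError(f"layer {mod} sample ordering differs")
        if sample_ids is None:
            raise ValueError("cohort has no layers")
        if len(self.labels) != len(sample_ids):
            raise ValueError("labels do not match sample count")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present in a cohort")

    @property
    def sample_ids(self) -> list:
        return next(iter(self.layers.values())).sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def modalities(self) -> list:
        return [m for m in MODALITIES if m in self.layers] + [
            m for m in self.layers if m not in MODALITIES
        ]

    def subset_samples(self, indices) -> "LabeledCohort":
        ids = [self.sample_ids[i] for i in indices]
        return LabeledCohort(
            layers={m: l.subset_samples(ids) for m, l in self.layers.items()},
            labels=self.labels[np.asarray(indices)],
        )

    def restrict_modalities(self, modalities) -> "LabeledCohort":
        missing = [m for m in modalities if m not in self.layers]
        if missing:
            raise KeyError(f"modalities not in cohort: {missing}")
        return LabeledCohort(
            layers={m: self.layers[m] for m in modalities}, labels=self.labels
        )


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average rows/columns sharing an identifier (first-occurrence order)."""
    if df.index.has_duplicates:
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).mean().loc[order]
    if df.columns.has_duplicates:
        order = df.columns.drop_duplicates()
        df = df.T.groupby(level=0, sort=False).mean().T.loc[:, order]
    return df


def load_omics_matrix(path, modality: str,
                      orientation: str = "samples-in-rows") -> OmicsLayer:
    """Read a delimited matrix with one id header row and one id column.

    Duplicate sample or feature ids are collapsed by arithmetic mean.
    Non-numeric cells and missing values are errors (no imputation).
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "features-in-rows":
        df = df.T
    bad = df.map(lambda v: isinstance(v, str))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} (imputation is out of scope)"
        )
    df = _collapse_duplicates(df.astype(np.float64))
    return OmicsLayer(modality, [str(s) for s in df.index],
                      [str(f) for f in df.columns], df.to_numpy())


def load_labels(path) -> pd.Series:
    """Read a two-column sample_id -> binary label table."""
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns, got {df.shape[1]}")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    vals = set(np.unique(s.to_numpy()))
    if not vals <= {0, 1}:
        raise ValueError(f"{path}: labels must be 0/1, found {sorted(vals)}")
    return s.astype(int)


def binarize_snv(layer: OmicsLayer) -> OmicsLayer:
    """Map variant counts to presence/absence: 1 where value > 0, else 0."""
    if (layer.values < 0).any():
        raise ValueError("SNV matrix contains negative values")
    return OmicsLayer(layer.modality, list(layer.sample_ids),
                      list(layer.feature_ids),
                      (layer.values > 0).astype(np.float64))


def normalize_expression(layer: OmicsLayer, log2_first: bool = False,
                         method: str = "minmax") -> OmicsLayer:
    """Optionally log2(x+1)-transform, then scale each feature to [0, 1].

    Constant features map to all-zero columns.  ``method="zscore"`` is
    provided for exploratory use but produces negative values and is
    therefore rejected by the chi-square selector downstream.
    """
    if (layer.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    X = layer.values
    if log2_first:
        X = np.log2(X + 1.0)
    if method == "minmax":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        rng_safe = np.where(rng > 0, rng, 1.0)
        X = (X - lo) / rng_safe
        X[:, rng == 0] = 0.0
    elif method == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return OmicsLayer(layer.modality, list(layer.sample_ids),
                      list(layer.feature_ids), X)


def chi2_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Chi-square statistic of each non-negative feature against the label.

    Class-wise feature sums are treated as observed counts and compared to
    their expectation under class-independence (the standard convention for
    this selection style); on 0/1 data this coincides with the two-way
    contingency statistic without continuity correction.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if (values < 0).any():
        raise ValueError("chi-square selection requires non-negative features "
                         "(z-score normalized input is not supported)")
    if len(np.unique(labels)) < 2:
        raise ValueError("chi-square selection requires both classes")
    scores, _ = _sk_chi2(values, labels)
    return np.nan_to_num(scores, nan=0.0)  # constant features -> 0


def chi2_select(layer: OmicsLayer, labels: np.ndarray, m: int,
                fit_values: np.ndarray | None = None,
                fit_labels: np.ndarray | None = None) -> OmicsLayer:
    """Keep the m features with the largest chi-square statistic.

    Ties are broken by original feature order (stable sort) and the
    selected features keep their original relative order.  When used
    inside cross-validation, pass the training split via ``fit_values`` /
    ``fit_labels`` so the selection never sees test labels.
    """
    k = layer.n_features
    if not 1 <= m <= k:
        raise ValueError(f"m={m} outside [1, {k}]")
    X_fit = layer.values if fit_values is None else np.asarray(fit_values)
    y_fit = labels if fit_labels is None else np.asarray(fit_labels)
    scores = chi2_scores(X_fit, y_fit)
    top = np.sort(np.argsort(-scores, kind="stable")[:m])
    keep = [layer.feature_ids[i] for i in top]
    return layer.subset_features(keep)


def standardize_cohort(cohort: LabeledCohort,
                       log2_first: dict | None = None) -> LabeledCohort:
    """Apply the modality-appropriate transform to every layer.

    SNV layers are binarized; all other layers are min-max normalized,
    with an optional per-modality log2(x+1) first (``log2_first`` maps
    modality -> bool, e.g. miRNA counts).
    """
    log2_first = log2_first or {}
    out = {}
    for mod, layer in cohort.layers.items():
        if mod == "SNV":
            out[mod] = binarize_snv(layer)
        else:
            out[mod] = normalize_expression(layer,
                                            log2_first=log2_first.get(mod, False))
    return LabeledCohort(layers=out, labels=cohort.labels)


def assemble_cohort(layers, labels: pd.Series) -> LabeledCohort:
    """Align layers and labels on the intersection of their sample ids.

    Samples missing from any layer (or unlabeled) are dropped with a
    logged count; the surviving order follows the label table.
    """
    layer_map = {l.modality: l for l in layers} if not isinstance(layers, dict) else dict(layers)
    common = [s for s in labels.index
              if all(s in set(l.sample_ids) for l in layer_map.values())]
    if not common:
        raise ValueError("no sample id is shared by all layers and the labels")
    dropped = len(labels) - len(common)
    if dropped:
        logger.info("assemble_cohort: dropped %d samples without matched "
                    "data in every layer", dropped)
    return LabeledCohort(
        layers={m: l.subset_samples(common) for m, l in layer_map.items()},
        labels=labels.loc[common].to_numpy(),
    )
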