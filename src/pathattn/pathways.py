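"""Pathway gene/miRNA sets and the binary membership matrices they induce.

A pathway collection is an ordered list of named feature sets (KEGG-style).
From a collection and an ordered feature list we build the binary
feature x pathway membership matrix M, with M[k, p] = 1 iff feature k
belongs to pathway p.  M defines the sparse connectivity of the network's
first layer and the out-degrees used to redistribute feature importance
onto pathways.

Identifier matching is exact, case-sensitive string equality; alias
resolution is an upstream concern.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pathway",
    "PathwayCollection",
    "MembershipMatrix",
    "read_gmt",
    "filter_pathways",
    "build_membership_matrix",
]


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    pathway_name: str
    members: frozenset

    def __len__(self):
        return len(self.members)


@dataclass
class PathwayCollection:
    """Ordered collection of pathways with unique identifiers."""

    pathways: list = field(default_factory=list)

    def __post_init__(self):
        ids = [p.pathway_id for p in self.pathways]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate pathway ids in collection: {sorted(dupes)}")
        for p in self.pathways:
            if not p.members:
                raise ValueError(f"pathway {p.pathway_id!r} has no members")

    def __len__(self):
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    @property
    def ids(self) -> list:
        return [p.pathway_id for p in self.pathways]

    def members_of(self, pathway_id: str) -> frozenset:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p.members
        raise KeyError(pathway_id)

    def all_members(self) -> set:
        out: set = set()
        for p in self.pathways:
            out |= p.members
        return out


def read_gmt(path) -> PathwayCollection:
    """Parse a GMT file (tab-separated: id, description, member ids...).

    Member lists are deduplicated per line.  Lines with fewer than three
    fields, empty member lists, duplicate pathway ids, or an empty file
    are errors.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        source = "<stream>"
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        source = str(path)

    pathways: list = []
    seen_ids: set = set()
    n_parsed = 0
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{source}: line {lineno}: expected >=3 tab-separated fields "
                f"(id, description, members...), got {len(fields)}"
            )
        pid, name = fields[0], fields[1]
        # dedupe while preserving nothing: membership is a set
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ValueError(f"{source}: line {lineno}: pathway {pid!r} has no members")
        if pid in seen_ids:
            raise ValueError(f"{source}: line {lineno}: duplicate pathway id {pid!r}")
        seen_ids.add(pid)
        pathways.append(Pathway(pid, name, members))
        n_parsed += 1

    if n_parsed == 0:
        raise ValueError(f"{source}: no pathways found (empty file)")
    return PathwayCollection(pathways)


def filter_pathways(coll: PathwayCollection, exclude_names) -> PathwayCollection:
    """Drop pathways whose *name* contains any exclusion pattern.

    Matching is case-insensitive substring; survivor order is preserved.
    The conventional default pattern for recurrence modelling is
    ``["cancer"]``, removing disease-specific pathways whose membership
    would leak the outcome definition into the connectivity prior.
    """
    if not exclude_names:
        return PathwayCollection(list(coll.pathways))
    patterns = [p.lower() for p in exclude_names]
    keep = [
        p for p in coll.pathways
        if not any(pat in p.pathway_name.lower() for pat in patterns)
    ]
    return PathwayCollection(keep)


@dataclass
class MembershipMatrix:
    """Binary feature x pathway connectivity for one omics modality."""

    feature_ids: list
    pathway_ids: list
    values: np.ndarray  # (k, p) of {0.0, 1.0}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.feature_ids), len(self.pathway_ids)):
            raise ValueError("membership matrix shape does not match id lists")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("membership entries must be exactly 0 or 1")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    def out_degrees(self) -> np.ndarray:
        """Number of pathways each feature connects to (row sums)."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.astype(int),
                            index=self.feature_ids, columns=self.pathway_ids)

    def write(self, path, sep: str = "\t"):
        self.to_frame().to_csv(path, sep=sep)


def build_membership_matrix(
    features,
    coll: PathwayCollection,
    drop_unannotated: bool = True,
):
    """Build M[k, p] = 1 iff feature k is a member of pathway p.

    With ``drop_unannotated`` (default) features connected to no pathway are
    removed, mirroring the convention that only features matching the
    pathway gene set are retained; otherwise they are attached to a
    synthetic ``__unannotated__`` catch-all column.  Pathways with no
    retained member are always dropped.

    Returns ``(MembershipMatrix, retained_feature_ids)`` with retained
    features in original order.
    """
    features = list(features)
    if not features:
        raise ValueError("feature list is empty")
    if len(set(features)) != len(features):
        raise ValueError("feature ids are not unique")

    member_sets = [p.members for p in coll.pathways]
    M = np.zeros((len(features), len(coll)), dtype=np.float64)
    for i, f in enumerate(features):
        for j, members in enumerate(member_sets):
            if f in members:
                M[i, j] = 1.0

    row_deg = M.sum(axis=1)
    if drop_unannotated:
        keep_rows = row_deg > 0
        if not keep_rows.any():
            raise ValueError("no overlap between features and pathway collection")
        M = M[keep_rows]
        retained = [f for f, k in zip(features, keep_rows) if k]
        pathway_ids = list(coll.ids)
    else:
        catchall = (row_deg == 0).astype(np.float64)[:, None]
        M = np.hstack([M, catchall])
        retained = features
        pathway_ids = list(coll.ids) + ["__unannotated__"]

    keep_cols = M.sum(axis=0) > 0
    M = M[:, keep_cols]
    pathway_ids = [p for p, k in zip(pathway_ids, keep_cols) if k]

    return MembershipMatrix(retained, pathway_ids, M), retained
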