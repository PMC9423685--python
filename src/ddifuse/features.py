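"""Inputs of the fusion model: similarity features and the graph operator.

Drugs arrive as binary descriptor matrices (one per feature view, e.g. chemical
substructure / target / enzyme bit vectors) plus a labeled interaction table of
``(drug_i, drug_j, event_class)`` triples.  This module turns them into the two
model inputs:

* ``X`` — the drug feature table, a column-wise concatenation of per-view
  Jaccard similarity matrices, so each drug is described by its similarity to
  every other drug under every view;
* ``A_hat`` — the symmetrically normalized, self-looped adjacency operator
  ``D̃^{-1/2} (A + I) D̃^{-1/2}`` of the (binary, undirected) interaction graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BinaryDescriptorMatrix",
    "SimilarityMatrix",
    "DrugFeatureTable",
    "DDIEventTable",
    "NormalizedAdjacency",
    "jaccard_matrix",
    "concat_features",
    "build_adjacency",
    "read_descriptor_csv",
    "read_interaction_csv",
]


@dataclass(frozen=True)
class BinaryDescriptorMatrix:
    """One feature view: drugs × binary descriptors (0/1 presence bits)."""

    view_name: str
    values: np.ndarray
    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError(f"view {self.view_name!r}: expected 2-D matrix, got {values.ndim}-D")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"view {self.view_name!r}: non-binary entry {values[r, c]!r} at row {r} "
                f"(drug {self.drug_ids[r] if r < len(self.drug_ids) else r!r}), column {c}"
            )
        if len(self.drug_ids) != values.shape[0]:
            raise ValueError(
                f"view {self.view_name!r}: {len(self.drug_ids)} drug ids for {values.shape[0]} rows"
            )
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError(f"view {self.view_name!r}: duplicate drug ids")
        object.__setattr__(self, "values", values.astype(np.int8, copy=False))

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Drug × drug similarity in [0, 1]; symmetric."""

    view_name: str
    values: np.ndarray

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DrugFeatureTable:
    """Concatenated similarity feature matrix X, with per-view column ranges."""

    X: np.ndarray
    view_offsets: dict[str, tuple[int, int]]
    drug_ids: tuple[str, ...] = ()

    @property
    def n_drugs(self) -> int:
        return self.X.shape[0]

    def view(self, name: str) -> np.ndarray:
        """Recover a single view's similarity block from X."""
        lo, hi = self.view_offsets[name]
        return self.X[:, lo:hi]

    def mean_similarity(self) -> np.ndarray:
        """Average of the per-view similarity matrices (n_drugs × n_drugs).

        Serves as the default target of the inner-product decoder.
        """
        blocks = [self.view(name) for name in self.view_offsets]
        return np.mean(blocks, axis=0)


@dataclass(frozen=True)
class DDIEventTable:
    """Labeled interaction list: canonical (i, j, event_class) with i < j.

    Event classes are 1-based (class labels 1..C as they appear on disk).
    """

    pairs: np.ndarray  # (n_pairs, 3) int array: i, j, event_class
    n_classes: int

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 3)
        if len(pairs):
            i, j, y = pairs.T
            if (i == j).any():
                k = int(np.argwhere(i == j)[0, 0])
                raise ValueError(f"self-interaction at row {k}: drug index {i[k]}")
            lo, hi = np.minimum(i, j), np.maximum(i, j)
            pairs = np.column_stack([lo, hi, y])
            key = pairs[:, 0] * (pairs[:, 1].max() + 1) + pairs[:, 1]
            if len(np.unique(key)) != len(key):
                raise ValueError("duplicate drug pair after canonicalization")
            if (y < 1).any() or (y > self.n_classes).any():
                raise ValueError(f"event classes must lie in 1..{self.n_classes}")
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        """0-based class labels (internal encoding)."""
        return self.pairs[:, 2] - 1

    def edge_list(self) -> np.ndarray:
        return self.pairs[:, :2]


@dataclass(frozen=True)
class NormalizedAdjacency:
    """The propagation operator A_hat = D̃^{-1/2}(A + I)D̃^{-1/2}."""

    A_hat: sp.csr_matrix
    n_drugs: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_drugs", self.A_hat.shape[0])

    def dense(self) -> np.ndarray:
        return np.asarray(self.A_hat.todense())


def jaccard_matrix(descriptors: BinaryDescriptorMatrix) -> SimilarityMatrix:
    """All-pairs Jaccard similarity J(d_i, d_j) = |d_i ∩ d_j| / |d_i ∪ d_j|.

    Rows are treated as bit sets.  For an all-zero row the ratio is 0/0; such a
    drug carries no similarity evidence and every pair involving it (including
    its own diagonal) is assigned similarity 0, with a warning.
    """
    B = descriptors.values.astype(np.float64)
    inter = B @ B.T
    row_sums = B.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    empty = row_sums == 0
    if empty.any():
        warnings.warn(
            f"view {descriptors.view_name!r}: {int(empty.sum())} all-zero descriptor row(s); "
            "their similarities are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    J[empty, :] = 0.0
    J[:, empty] = 0.0
    return SimilarityMatrix(view_name=descriptors.view_name, values=J)


def concat_features(
    sims: Sequence[SimilarityMatrix], drug_ids: Sequence[str] = ()
) -> DrugFeatureTable:
    """Column-wise concatenation of per-view similarity matrices into X."""
    if not sims:
        raise ValueError("at least one similarity view is required")
    n = sims[0].n_drugs
    for s in sims:
        if s.values.shape != (n, n):
            raise ValueError(
                f"view {s.view_name!r} has shape {s.values.shape}, expected ({n}, {n})"
            )
    X = np.concatenate([s.values for s in sims], axis=1)
    offsets: dict[str, tuple[int, int]] = {}
    lo = 0
    for s in sims:
        offsets[s.view_name] = (lo, lo + n)
        lo += n
    return DrugFeatureTable(X=X, view_offsets=offsets, drug_ids=tuple(drug_ids))


def build_adjacency(
    events: DDIEventTable,
    n_drugs: int,
    edge_subset: np.ndarray | Sequence[tuple[int, int]] | None = None,
) -> NormalizedAdjacency:
    """Normalized self-looped adjacency over the (optionally restricted) edges.

    Event classes are ignored: the propagation graph is binary and undirected.
    ``edge_subset`` restricts A to the given pairs (e.g. the training fold),
    so that held-out interactions never enter the propagation operator; drugs
    with no included edge keep only their self-loop.
    """
    if edge_subset is None:
        edges = events.edge_list()
    else:
        edges = np.asarray(edge_subset, dtype=np.int64).reshape(-1, 2)
        lo = np.minimum(edges[:, 0], edges[:, 1])
        hi = np.maximum(edges[:, 0], edges[:, 1])
        edges = np.column_stack([lo, hi])
    if len(edges):
        if (edges < 0).any() or (edges >= n_drugs).any():
            bad = edges[(edges < 0).any(axis=1) | (edges >= n_drugs).any(axis=1)][0]
            raise ValueError(f"drug index out of range for n_drugs={n_drugs}: pair {tuple(bad)}")
        if (edges[:, 0] == edges[:, 1]).any():
            raise ValueError("self-pairs are not valid interaction edges")
        key = edges[:, 0] * n_drugs + edges[:, 1]
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate pair after canonicalization")
    rows = np.concatenate([edges[:, 0], edges[:, 1]]) if len(edges) else np.empty(0, int)
    cols = np.concatenate([edges[:, 1], edges[:, 0]]) if len(edges) else np.empty(0, int)
    A = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_drugs, n_drugs)
    ).tocsr()
    A_tilde = A + sp.identity(n_drugs, format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return NormalizedAdjacency(A_hat=(D @ A_tilde @ D).tocsr())


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_descriptor_csv(path, view_name: str | None = None, sep: str = ",") -> BinaryDescriptorMatrix:
    """Read a descriptor view: first column drug id, remaining columns 0/1 bits."""
    df = pd.read_csv(path, sep=sep)
    drug_ids = tuple(df.iloc[:, 0].astype(str))
    values = df.iloc[:, 1:].to_numpy()
    name = view_name if view_name is not None else str(getattr(path, "stem", path))
    return BinaryDescriptorMatrix(view_name=name, values=values, drug_ids=drug_ids)


def read_interaction_csv(
    path, drug_ids: Sequence[str], n_classes: int | None = None, sep: str = ","
) -> DDIEventTable:
    """Read interactions with columns drug_a, drug_b, event_class (1-based)."""
    df = pd.read_csv(path, sep=sep)
    index = {d: k for k, d in enumerate(drug_ids)}
    try:
        i = df.iloc[:, 0].astype(str).map(index).to_numpy()
        j = df.iloc[:, 1].astype(str).map(index).to_numpy()
    except Exception as exc:  # pragma: no cover - pandas detail
        raise ValueError(f"could not map drug identifiers: {exc}") from exc
    if np.isnan(i.astype(float)).any() or np.isnan(j.astype(float)).any():
        missing = set(df.iloc[:, 0].astype(str)) | set(df.iloc[:, 1].astype(str))
        missing -= set(drug_ids)
        raise ValueError(f"interaction table names unknown drugs: {sorted(missing)[:5]}")
    y = df.iloc[:, 2].to_numpy(dtype=np.int64)
    C = int(n_classes if n_classes is not None else y.max())
    return DDIEventTable(pairs=np.column_stack([i, j, y]), n_classes=C)
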