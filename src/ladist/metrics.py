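"""Integration benchmark: bio-conservation and batch-mixing scores.

Four scores in [0, 1], plus their arithmetic mean:

* ``silhouette_label`` — mean silhouette width over cell-type labels,
  rescaled from [-1, 1] to [0, 1] by (s + 1) / 2. High when types form
  compact, separated clusters.
* ``isolated_label_silhouette`` — the same rescaled width restricted to
  "isolated" labels (types present in the fewest batches), scored one label
  vs the rest. High when rare, batch-confined types remain distinguishable.
* ``batch_silhouette`` — within each cell-type group, silhouette width with
  batches as labels, per-cell score 1 - |s|, averaged over cells. 1 means
  batches are perfectly mixed within every type.
* ``graph_connectivity`` — per type, the fraction of its cells inside the
  largest connected component of the kNN subgraph induced by that type,
  averaged over types. 1 means no type is fragmented.

The first two reward biological structure, the last two reward batch removal;
their arithmetic mean is the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import kneighbors_graph

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "BenchmarkReport",
    "silhouette_label",
    "isolated_label_silhouette",
    "batch_silhouette",
    "graph_connectivity",
    "benchmark",
]

#: Above this cell count the silhouette metrics score a deterministic subsample.
SILHOUETTE_SUBSAMPLE = 20_000


def _as_embedding(embedding) -> np.ndarray:
    values = np.asarray(getattr(embedding, "values", embedding), dtype=float)
    if values.ndim != 2:
        raise InvalidInputError("embedding must be a 2-D cells x dims matrix")
    return values


def _check_lengths(embedding: np.ndarray, *label_arrays) -> list[np.ndarray]:
    out = []
    for arr in label_arrays:
        arr = np.asarray(arr)
        if len(arr) != embedding.shape[0]:
            raise InvalidInputError(
                f"{len(arr)} labels for {embedding.shape[0]} cells"
            )
        out.append(arr)
    return out


def _maybe_subsample(embedding: np.ndarray, *label_arrays):
    n = embedding.shape[0]
    if n <= SILHOUETTE_SUBSAMPLE:
        return embedding, label_arrays
    idx = np.sort(
        np.random.default_rng(0).choice(n, size=SILHOUETTE_SUBSAMPLE, replace=False)
    )
    return embedding[idx], tuple(arr[idx] for arr in label_arrays)


def silhouette_label(embedding, type_labels) -> float:
    """Rescaled mean silhouette width of the cell-type labelling."""
    X = _as_embedding(embedding)
    (labels,) = _check_lengths(X, type_labels)
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("silhouette needs at least 2 distinct labels")
    X, (labels,) = _maybe_subsample(X, labels)
    s = silhouette_samples(X, labels, metric="euclidean").mean()
    return float((s + 1.0) / 2.0)


def isolated_labels(type_labels, batch_labels) -> list:
    """Labels present in the fewest batches (ties keep all such labels)."""
    frame = pd.DataFrame({"label": np.asarray(type_labels), "batch": np.asarray(batch_labels)})
    per_label = frame.groupby("label", sort=True)["batch"].nunique()
    return list(per_label.index[per_label == per_label.min()])


def isolated_label_silhouette(embedding, type_labels, batch_labels) -> float:
    """Mean, over isolated labels, of the rescaled silhouette width of that
    label against all other cells (one-vs-rest labelling)."""
    X = _as_embedding(embedding)
    labels, batches = _check_lengths(X, type_labels, batch_labels)
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("silhouette needs at least 2 distinct labels")
    X, (labels, batches) = _maybe_subsample(X, labels, batches)
    scores = []
    for lab in isolated_labels(labels, batches):
        binary = np.where(labels == lab, "in", "rest")
        s = silhouette_samples(X, binary, metric="euclidean")
        scores.append((s[labels == lab].mean() + 1.0) / 2.0)
    return float(np.mean(scores))


def batch_silhouette(embedding, batch_labels, type_labels) -> float:
    """Batch-mixing score: within each cell-type group, 1 - |silhouette|
    with batches as labels, averaged over all scoreable cells.

    Type groups containing a single batch carry no mixing information and are
    skipped; if every group is skipped the score is undefined.
    """
    X = _as_embedding(embedding)
    batches, types = _check_lengths(X, batch_labels, type_labels)
    if len(np.unique(batches)) < 2:
        raise InvalidInputError("batch silhouette needs at least 2 batches")
    per_cell = []
    for lab in np.unique(types):
        mask = types == lab
        group_batches = batches[mask]
        n_group = int(mask.sum())
        n_batches = len(np.unique(group_batches))
        if n_batches < 2:
            continue
        if n_batches >= n_group:  # all singleton clusters: silhouette 0 by convention
            s = np.zeros(n_group)
        else:
            s = silhouette_samples(X[mask], group_batches, metric="euclidean")
        per_cell.append(1.0 - np.abs(s))
    if not per_cell:
        raise InvalidInputError("no cell-type group contains more than one batch")
    return float(np.concatenate(per_cell).mean())


def graph_connectivity(embedding, type_labels, k_neighbors: int = 15) -> float:
    """Mean, over cell types, of the largest-connected-component fraction of
    the kNN subgraph induced by that type's cells."""
    if k_neighbors < 1:
        raise InvalidParameterError("k_neighbors must be >= 1")
    X = _as_embedding(embedding)
    (labels,) = _check_lengths(X, type_labels)
    scores = []
    for lab in np.unique(labels):
        mask = labels == lab
        sub = X[mask]
        n = sub.shape[0]
        if n == 1:
            scores.append(1.0)
            continue
        k = min(k_neighbors, n - 1)
        adj = kneighbors_graph(sub, n_neighbors=k, mode="connectivity")
        adj = adj.maximum(adj.T)
        n_comp, assignment = connected_components(adj, directed=False)
        largest = np.bincount(assignment).max()
        scores.append(largest / n)
    return float(np.mean(scores))


@dataclass
class BenchmarkReport:
    """The four benchmark scores and their arithmetic-mean aggregate."""

    silhouette_label: float
    isolated_label_silhouette: float
    batch_silhouette: float
    graph_connectivity: float
    aggregate: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_row(self, method: str, seed: int | None = None) -> pd.DataFrame:
        row = {"method": method}
        if seed is not None:
            row["seed"] = seed
        row.update(self.to_dict())
        return pd.DataFrame([row])


def benchmark(embedding, type_labels, batch_labels, k_neighbors: int = 15) -> BenchmarkReport:
    """Score one embedding against type and batch labels."""
    scores = {
        "silhouette_label": silhouette_label(embedding, type_labels),
        "isolated_label_silhouette": isolated_label_silhouette(
            embedding, type_labels, batch_labels
        ),
        "batch_silhouette": batch_silhouette(embedding, batch_labels, type_labels),
        "graph_connectivity": graph_connectivity(embedding, type_labels, k_neighbors),
    }
    aggregate = float(np.mean(list(scores.values())))
    return BenchmarkReport(aggregate=aggregate, **scores)
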