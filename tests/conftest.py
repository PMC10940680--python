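"""Shared fixtures and independent brute-force oracles.

The oracles deliberately take the slowest, most literal route (double loops,
explicit matrix inverses, union-find) so they share no code path with the
implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from ladist import BatchDesign, ExpressionMatrix


# ---------------------------------------------------------------------------
# Oracles


def sigma_tilde_bruteforce(values, batch_idx, weights):
    """Literal double loop over (cell, other-batch) pairs."""
    values = np.asarray(values, dtype=float)
    batch_idx = np.asarray(batch_idx)
    B = weights.shape[0]
    k = values.shape[1]
    means = [values[batch_idx == b].mean(axis=0) for b in range(B)]
    sigma = np.zeros((k, k))
    for i in range(values.shape[0]):
        for b in range(B):
            if b == batch_idx[i]:
                continue
            d = values[i] - means[b]
            sigma += weights[batch_idx[i], b] * np.outer(d, d)
    return sigma


def mahalanobis_explicit(x_i, x_j, matrix):
    """Quadratic form through an explicit inverse (test-only path)."""
    d = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
    return float(np.sqrt(d @ np.linalg.inv(matrix) @ d))


def silhouette_bruteforce(X, labels):
    """O(n^2) textbook silhouette widths; singleton clusters get 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    widths = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            widths[i] = 0.0
            continue
        a = dist[i, same].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        widths[i] = (b - a) / max(a, b)
    return widths


def connectivity_bruteforce(X, labels, k_neighbors):
    """Largest-component fraction per label via dense kNN adjacency and
    union-find."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    scores = []
    for lab in np.unique(labels):
        sub = X[labels == lab]
        n = sub.shape[0]
        if n == 1:
            scores.append(1.0)
            continue
        k = min(k_neighbors, n - 1)
        dist = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in np.argsort(dist[i], kind="stable")[:k]:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[ri] = rj
        roots = [find(i) for i in range(n)]
        largest = max(np.bincount(np.unique(roots, return_inverse=True)[1]))
        scores.append(largest / n)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, n=30, k=4, B=3, label_span=3.0):
    """A random expression matrix + batch design (every batch non-empty)."""
    values = rng.normal(size=(n, k))
    batch_idx = np.concatenate([np.arange(B), rng.integers(0, B, size=n - B)])
    rng.shuffle(batch_idx)
    labels = rng.uniform(0, label_span, size=B)
    X = ExpressionMatrix(values)
    design = BatchDesign(
        batch_of_cell=np.array([f"b{i}" for i in batch_idx]),
        batch_labels=labels,
        batch_ids=[f"b{i}" for i in range(B)],
    )
    return X, design, batch_idx


@pytest.fixture
def small_instance(rng):
    return random_instance(rng)
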