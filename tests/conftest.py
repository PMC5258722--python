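"""Shared fixtures and the independent brute-force silhouette oracle."""

import numpy as np
import pytest


def oracle_silhouette(D, labels, classical_a=False):
    """Literal double-loop silhouette: for each item, average distances to
    every cluster explicitly and take (b - a) / max(a, b).

    Kept deliberately naive and independent of the package's vectorized path.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels, dtype=int)
    N = labels.size
    clusters = sorted(set(labels.tolist()))
    s = np.zeros(N)
    if len(clusters) == 1:
        return s
    for q in range(N):
        own = labels[q]
        members = [y for y in range(N) if labels[y] == own]
        if len(members) == 1:
            s[q] = 0.0
            continue
        if classical_a:
            a = sum(D[q, y] for y in members if y != q) / (len(members) - 1)
        else:
            a = sum(D[q, y] for y in members) / len(members)
        b = min(
            sum(D[q, y] for y in range(N) if labels[y] == c)
            / sum(1 for y in range(N) if labels[y] == c)
            for c in clusters
            if c != own
        )
        s[q] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def random_dissimilarity(rng, n, scale=1.0):
    """Random symmetric nonnegative matrix with zero diagonal."""
    A = rng.uniform(0.0, scale, size=(n, n))
    D = (A + A.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def random_labels(rng, n, r):
    """Random 1-based labels guaranteed to use all r clusters."""
    lab = rng.integers(1, r + 1, size=n)
    lab[rng.choice(n, size=r, replace=False)] = np.arange(1, r + 1)
    return lab


@pytest.fixture
def rng():
    return np.random.default_rng(42)
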