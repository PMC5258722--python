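"""Spectral clustering with a k-medoids inner step, and cluster-number estimation.

The clustering route used throughout the package is the normalized
spectral embedding of Ng, Jordan & Weiss: the dissimilarity matrix is
mapped to an affinity ``W``, the symmetric normalized Laplacian
``L = I - Dw^{-1/2} W Dw^{-1/2}`` is formed, the eigenvectors of its ``k``
smallest eigenvalues are stacked, the rows are normalized to unit length,
and the embedded rows are clustered with k-medoids (PAM) rather than
k-means for robustness to outliers.

Two affinity constructions are offered: a parameter-free linear map
``W = 1 - D / max(D)`` (default) and a Gaussian kernel
``exp(-D^2 / (2 sigma^2))`` with ``sigma`` the median off-diagonal
distance.

The number of clusters can be estimated by maximizing the average
silhouette over candidate ``k``, or by the slope criterion
``-(sbar(k+1) - sbar(k)) * sbar(k)^p``, which is more reliable when
within-cluster spreads are unequal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist

from .silhouette import average_silhouette, validate_dissimilarity

__all__ = ["ClusterCountEstimate", "kmedoids", "spectral_clustering", "estimate_k"]

#: degree assigned to isolated items (zero affinity rows) before normalization
ISOLATED_DEGREE = 1e-12


@dataclass
class ClusterCountEstimate:
    """Result of :func:`estimate_k`.

    Attributes
    ----------
    k_best : chosen number of clusters (arg-max of the criterion, ties to
        the smallest k).
    criterion_values : mapping candidate k -> criterion score.
    criterion_name : "silhouette" or "slope".
    """

    k_best: int
    criterion_values: dict[int, float] = field(repr=False)
    criterion_name: str = "silhouette"


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase: pick medoids one by one, each minimizing total cost."""
    n = dist.shape[0]
    first = int(np.argmin(dist.sum(axis=1)))
    medoids = [first]
    nearest = dist[:, first].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum of max(nearest - d(:, c), 0)
        gains = np.maximum(nearest[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))  # argmax ties -> lowest index
        medoids.append(cand)
        nearest = np.minimum(nearest, dist[:, cand])
    return medoids


def _pam_swap(dist: np.ndarray, medoids: list[int], max_swaps: int) -> tuple[list[int], float]:
    """Best-improvement SWAP iterations; returns (medoids, objective)."""
    n = dist.shape[0]
    for _ in range(max_swaps):
        cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in med_set:
                    continue
                delta = cost - np.minimum(base, dist[:, h]).sum()
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    return medoids, dist[:, medoids].min(axis=1).sum()


def kmedoids(
    points_or_distances,
    k: int,
    seed: int = 0,
    *,
    precomputed: bool = False,
    n_starts: int = 5,
    max_swaps: int = 200,
) -> np.ndarray:
    """PAM (build + swap) k-medoids; returns 1-based labels.

    ``points_or_distances`` is an (n, d) coordinate array (Euclidean
    distances are used) or, with ``precomputed=True``, an (n, n) distance
    matrix.  The first start uses the classical greedy BUILD; additional
    starts draw random medoid sets from ``seed`` (only the build phase is
    randomized).  Each start runs best-improvement SWAP iterations until
    no swap lowers the total within-medoid dissimilarity; the lowest
    objective wins.  Ties break toward the lowest object index.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if precomputed:
        dist = np.asarray(points_or_distances, dtype=float)
        if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
            raise ValueError("precomputed distances must form a square matrix")
    else:
        pts = np.asarray(points_or_distances, dtype=float)
        if pts.ndim != 2:
            raise ValueError("points must be a 2-D array")
        dist = squareform(pdist(pts))
    n = dist.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of objects n={n}")

    rng = np.random.default_rng(seed)
    best_medoids, best_cost = None, np.inf
    for start in range(max(1, n_starts)):
        if start == 0:
            init = _pam_build(dist, k)
        else:
            init = sorted(rng.choice(n, size=k, replace=False).tolist())
        medoids, cost = _pam_swap(dist, init, max_swaps)
        if cost < best_cost - 1e-12:
            best_medoids, best_cost = medoids, cost

    medoids = sorted(best_medoids)
    labels = np.argmin(dist[:, medoids], axis=1) + 1
    return labels.astype(int)


def _affinity(D: np.ndarray, kind: str, sigma: float | None = None) -> np.ndarray:
    off = D[~np.eye(D.shape[0], dtype=bool)]
    if kind == "linear":
        mx = D.max()
        if mx <= 0:
            raise ValueError("degenerate dissimilarity matrix: all entries zero")
        W = 1.0 - D / mx
    elif kind == "gaussian":
        if sigma is None:
            sigma = float(np.median(off))
        if sigma <= 0:
            raise ValueError("Gaussian affinity needs a positive bandwidth")
        W = np.exp(-(D**2) / (2.0 * sigma**2))
    else:
        raise ValueError(f"unknown affinity {kind!r}; use 'linear' or 'gaussian'")
    np.fill_diagonal(W, 0.0)
    if W.max() <= 0:
        raise ValueError("degenerate affinity matrix: all entries zero")
    return W


def spectral_clustering(
    D,
    k: int,
    seed: int = 0,
    *,
    affinity: str = "linear",
    sigma: float | None = None,
    validate: bool = True,
) -> np.ndarray:
    """Cluster the items of a dissimilarity matrix into ``k`` groups.

    Returns 1-based labels.  ``k = 1`` short-circuits to a single cluster.
    Deterministic for a given input (the k-medoids step is deterministic;
    ``seed`` is part of the interface contract).
    """
    if validate:
        D = validate_dissimilarity(D)
    else:
        D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    if k == 1:
        return np.ones(n, dtype=int)

    W = _affinity(D, affinity, sigma)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        warnings.warn("isolated items in affinity graph; assigning tiny degree", stacklevel=2)
        deg = np.where(deg <= 0, ISOLATED_DEGREE, deg)
    dinv = 1.0 / np.sqrt(deg)
    L = np.eye(n) - dinv[:, None] * W * dinv[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vecs / norms
    return kmedoids(emb, k, seed=seed)


def estimate_k(
    D,
    k_max: int,
    criterion: str = "silhouette",
    slope_p: float = 1.0,
    seed: int = 0,
    *,
    affinity: str = "linear",
    classical_a: bool = False,
) -> ClusterCountEstimate:
    """Estimate the number of clusters from the average-silhouette curve.

    For each candidate ``k`` in ``2..k_max`` the matrix is clustered by
    :func:`spectral_clustering` and the average silhouette ``sbar(k)``
    recorded.  The silhouette criterion scores ``sbar(k)`` directly; the
    slope criterion scores ``-(sbar(k+1) - sbar(k)) * sbar(k)**slope_p``
    for ``k`` in ``2..k_max-1``, rewarding a high silhouette followed by a
    drop.  The arg-max wins; ties go to the smallest ``k``.
    """
    D = validate_dissimilarity(D)
    n = D.shape[0]
    if k_max < 2:
        raise ValueError(f"k_max must be >= 2, got {k_max}")
    if k_max > n - 1:
        raise ValueError(f"k_max must be <= N-1 = {n - 1}, got {k_max}")
    if criterion not in ("silhouette", "slope"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "slope" and k_max < 3:
        raise ValueError("slope criterion needs k_max >= 3")

    sbar = {}
    for k in range(2, k_max + 1):
        labels = spectral_clustering(D, k, seed=seed, affinity=affinity, validate=False)
        sbar[k] = average_silhouette(D, labels, classical_a=classical_a, validate=False)

    if criterion == "silhouette":
        scores = sbar
    else:
        scores = {
            k: -(sbar[k + 1] - sbar[k]) * sbar[k] ** slope_p
            for k in range(2, k_max)
        }
    k_best = min(scores, key=lambda k: (-scores[k], k))
    return ClusterCountEstimate(k_best=k_best, criterion_values=scores, criterion_name=criterion)
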