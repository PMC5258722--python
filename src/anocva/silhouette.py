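"""Per-item silhouette statistics on dissimilarity matrices.

The silhouette of item ``q`` measures how well it sits in its assigned
cluster: with ``a_q`` the average dissimilarity of ``q`` to the members of
its own cluster and ``b_q`` the smallest average dissimilarity of ``q`` to
any other cluster,

    s_q = (b_q - a_q) / max(a_q, b_q),        s_q in [-1, +1],

with ``s_q = 0`` when ``q`` is alone in its cluster.  By default ``a_q``
averages over all ``|C|`` members of the cluster, i.e. it includes the
item's own zero self-distance (dividing by ``|C|``); the classical
Rousseeuw convention, which divides by ``|C| - 1``, is available via
``classical_a=True``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "validate_dissimilarity",
    "validate_labels",
    "silhouette_per_item",
    "average_silhouette",
]

#: relative tolerance above which an asymmetric input is considered suspect
SYMMETRY_RTOL = 1e-8


def validate_dissimilarity(values, *, copy: bool = False) -> np.ndarray:
    """Validate (and mildly repair) a square dissimilarity matrix.

    Checks squareness and nonnegativity; symmetrizes as ``(D + D.T) / 2``,
    warning if the asymmetry exceeds ``SYMMETRY_RTOL`` relative to the
    largest entry; forces a zero diagonal.

    Returns a float64 array.
    """
    D = np.array(values, dtype=float, copy=True) if copy else np.asarray(values, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"dissimilarity matrix must be square, got shape {D.shape}")
    if not np.all(np.isfinite(D)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    if np.any(D < 0):
        q, qp = np.argwhere(D < 0)[0]
        raise ValueError(f"dissimilarity matrix has negative entry at ({q}, {qp}): {D[q, qp]}")
    scale = D.max() if D.size else 0.0
    asym = np.abs(D - D.T).max() if D.size else 0.0
    if scale > 0 and asym > SYMMETRY_RTOL * scale:
        warnings.warn(
            f"asymmetry {asym:.3g} exceeds tolerance; symmetrizing as (D + D.T)/2",
            stacklevel=2,
        )
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def validate_labels(labels, n_items: int) -> np.ndarray:
    """Validate a 1-based cluster label vector against a matrix dimension."""
    lab = np.asarray(labels, dtype=int)
    if lab.ndim != 1 or lab.shape[0] != n_items:
        raise ValueError(
            f"labels must be a length-{n_items} vector, got shape {lab.shape}"
        )
    if lab.min(initial=1) < 1:
        raise ValueError("cluster labels must be integers >= 1")
    return lab


def _mean_dissimilarity_to_clusters(D: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (M, uniq, sizes): M[q, c] = mean_{y in cluster uniq[c]} D[q, y]."""
    uniq, inv = np.unique(labels, return_inverse=True)
    r = uniq.size
    n = D.shape[0]
    # one-hot membership (n, r); sums via a single matmul
    member = np.zeros((n, r))
    member[np.arange(n), inv] = 1.0
    sizes = member.sum(axis=0)
    M = (D @ member) / sizes
    return M, inv, sizes


def silhouette_per_item(D, labels, *, classical_a: bool = False, validate: bool = True) -> np.ndarray:
    """Per-item silhouette vector for a dissimilarity matrix under fixed labels.

    Parameters
    ----------
    D
        N x N symmetric nonnegative dissimilarity matrix.
    labels
        Length-N vector of integer cluster labels (1-based).
    classical_a
        If True, the within dissimilarity excludes the item itself
        (divides by ``|C| - 1``); default follows the ``1/|C|`` convention.
    validate
        Skip input validation when False (trusted internal callers).

    Returns
    -------
    numpy.ndarray
        Length-N vector with entries in [-1, 1]; exactly 0 for items in
        singleton clusters, and all-zero when only one cluster exists.
    """
    if validate:
        D = validate_dissimilarity(D)
        labels = validate_labels(labels, D.shape[0])
    else:
        D = np.asarray(D, dtype=float)
        labels = np.asarray(labels, dtype=int)
    n = D.shape[0]
    M, inv, sizes = _mean_dissimilarity_to_clusters(D, labels)
    r = sizes.size
    if r == 1:
        warnings.warn("only one cluster: silhouette is 0 for every item", stacklevel=2)
        return np.zeros(n)

    own_size = sizes[inv]
    a = M[np.arange(n), inv]
    if classical_a:
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(own_size > 1, a * own_size / np.maximum(own_size - 1, 1), a)

    # b_q: smallest mean dissimilarity to any *other* cluster
    M_other = M.copy()
    M_other[np.arange(n), inv] = np.inf
    b = M_other.min(axis=1)

    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[own_size == 1] = 0.0  # singleton rule
    return s


def average_silhouette(D, labels, *, classical_a: bool = False, validate: bool = True) -> float:
    """Arithmetic mean of :func:`silhouette_per_item`; a value in [-1, 1]."""
    return float(np.mean(silhouette_per_item(D, labels, classical_a=classical_a, validate=validate)))
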