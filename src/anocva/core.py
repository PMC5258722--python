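"""The ANOCVA test: do k populations of subjects share one clustering structure?

Each subject contributes an N x N dissimilarity matrix over a common set of
items (e.g. brain regions whose pairwise functional-connectivity distances
were measured).  Population averages ``Abar_j`` and the grand weighted
average ``Adbar = (1/n) sum_j n_j Abar_j`` are formed; ``Adbar`` is
clustered once to obtain pooled labels ``l``.  With ``S`` the silhouette
vector of ``Adbar`` under ``l`` and ``S_j`` that of ``Abar_j`` under the
same labels, the statistics are

    DeltaS   = sum_j || S - S_j ||^2                (global)
    Delta s_q = ( S_q - (1/k) sum_j S_{j,q} )^2     (per item)

Under the null that the populations are equally clustered, every ``S_j``
tracks ``S`` and both statistics are small.  The null distribution is
estimated by resampling subjects with replacement from the pooled set of
all n subjects (group labels exchangeable under the null), recomputing the
averages, labels and statistics per replicate; p-values are the fraction
of replicates at least as large as the observed statistic.  Per-item
p-values are Bonferroni-adjusted, optionally after a robustness filter
that drops items whose p-value is unstable (> 0.05 apart) across two
preprocessing variants of the same study.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import estimate_k, spectral_clustering
from .silhouette import silhouette_per_item, validate_dissimilarity

__all__ = [
    "PopulationSet",
    "AveragedMatrices",
    "AnocvaResult",
    "average_dissimilarity",
    "anocva_statistics",
    "anocva_test",
    "pvalue_from_replicates",
    "bonferroni_adjust",
    "robustness_filter",
]

#: retries for a degenerate bootstrap replicate before giving up
MAX_REPLICATE_RETRIES = 10


@dataclass
class PopulationSet:
    """Per-subject dissimilarity matrices grouped into k >= 2 populations.

    Attributes
    ----------
    matrices : (n, N, N) array, one matrix per subject.
    group : length-n integer vector of population codes 1..k.
    group_names : optional population names, index j-1 -> name of group j.
    """

    matrices: np.ndarray
    group: np.ndarray
    group_names: list[str] | None = None

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.group = np.asarray(self.group, dtype=int)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError(
                f"matrices must stack to (n, N, N), got shape {self.matrices.shape}"
            )
        if self.group.shape != (self.matrices.shape[0],):
            raise ValueError("group vector length must equal the number of subjects")
        codes = np.unique(self.group)
        if not np.array_equal(codes, np.arange(1, codes.size + 1)):
            raise ValueError("group codes must be consecutive integers 1..k")
        if codes.size < 2:
            raise ValueError("at least two populations are required")

    @classmethod
    def from_matrices(cls, matrices, group_labels) -> "PopulationSet":
        """Build from a list of matrices and arbitrary hashable group labels.

        Each matrix is validated (symmetry, nonnegativity, zero diagonal).
        Group labels are coded 1..k in order of first appearance.
        """
        mats = [validate_dissimilarity(m, copy=True) for m in matrices]
        if len({m.shape for m in mats}) > 1:
            raise ValueError("all subjects must share the same number of items")
        names: list = []
        codes = []
        for g in group_labels:
            if g not in names:
                names.append(g)
            codes.append(names.index(g) + 1)
        return cls(np.stack(mats), np.asarray(codes), group_names=[str(x) for x in names])

    @property
    def n(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_items(self) -> int:
        return self.matrices.shape[1]

    @property
    def k(self) -> int:
        return int(self.group.max())

    @property
    def n_j(self) -> np.ndarray:
        return np.bincount(self.group, minlength=self.k + 1)[1:]


@dataclass
class AveragedMatrices:
    """Per-population averages Abar_j and the grand weighted average Adbar."""

    A_bar_j: np.ndarray  # (k, N, N)
    A_doublebar: np.ndarray  # (N, N)
    n_j: np.ndarray  # (k,)


@dataclass
class AnocvaResult:
    """Observed statistics, bootstrap p-values and metadata of one test run."""

    delta_S: float
    delta_s: np.ndarray
    p_global: float
    p_items: np.ndarray
    p_items_adjusted: np.ndarray
    k_clusters: int
    labels: np.ndarray
    n_bootstrap: int
    seed: int
    S: np.ndarray = field(repr=False)
    S_j: np.ndarray = field(repr=False)
    options: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "delta_S": self.delta_S,
            "delta_s": self.delta_s.tolist(),
            "p_global": self.p_global,
            "p_items": self.p_items.tolist(),
            "p_items_adjusted": self.p_items_adjusted.tolist(),
            "k_clusters": self.k_clusters,
            "labels": self.labels.tolist(),
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "S": self.S.tolist(),
            "S_j": self.S_j.tolist(),
            "options": self.options,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def items_table(self, item_ids=None, keep_mask=None) -> pd.DataFrame:
        """Per-item table: id, cluster, delta_s, p, adjusted p, filter flag."""
        n = self.delta_s.size
        if item_ids is None:
            item_ids = [f"item_{q + 1}" for q in range(n)]
        df = pd.DataFrame(
            {
                "item_id": item_ids,
                "cluster": self.labels,
                "delta_s": self.delta_s,
                "p": self.p_items,
                "p_adjusted": self.p_items_adjusted,
            }
        )
        df["kept_by_robustness_filter"] = True if keep_mask is None else np.asarray(keep_mask)
        return df


def average_dissimilarity(pop: PopulationSet) -> AveragedMatrices:
    """Entrywise per-population means and their n_j-weighted grand mean."""
    k = pop.k
    A_bar = np.stack([pop.matrices[pop.group == j + 1].mean(axis=0) for j in range(k)])
    n_j = pop.n_j
    A_dd = np.tensordot(n_j, A_bar, axes=1) / pop.n
    return AveragedMatrices(A_bar_j=A_bar, A_doublebar=A_dd, n_j=n_j)


def anocva_statistics(
    avg: AveragedMatrices,
    labels: np.ndarray,
    *,
    classical_a: bool = False,
    validate: bool = True,
):
    """Observed DeltaS and per-item Delta s_q under fixed pooled labels.

    Returns ``(delta_S, delta_s, S, S_j)`` where ``S_j`` is a (k, N)
    array of per-population silhouette vectors, all computed under the
    SAME labeling derived from the grand average.
    """
    S = silhouette_per_item(avg.A_doublebar, labels, classical_a=classical_a, validate=validate)
    S_j = np.stack(
        [
            silhouette_per_item(A, labels, classical_a=classical_a, validate=validate)
            for A in avg.A_bar_j
        ]
    )
    diff = S[None, :] - S_j
    delta_S = float((diff**2).sum())
    delta_s = (S - S_j.mean(axis=0)) ** 2
    return delta_S, delta_s, S, S_j


def pvalue_from_replicates(observed: float, replicates, add_one: bool = False) -> float:
    """Bootstrap p-value: fraction of replicates at least as large as observed.

    Ties count toward the numerator.  With ``add_one`` the estimator is
    ``(1 + #{>= observed}) / (B + 1)``, which cannot return zero.
    """
    rep = np.asarray(replicates, dtype=float)
    if rep.size == 0:
        raise ValueError("replicates must be nonempty")
    count = int(np.sum(rep >= observed))
    if add_one:
        return (1 + count) / (rep.size + 1)
    return count / rep.size


def bonferroni_adjust(p) -> np.ndarray:
    """Bonferroni adjustment min(1, m * p) with m the number of tests."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)


def robustness_filter(p_variant_a, p_variant_b, max_abs_diff: float = 0.05) -> np.ndarray:
    """Keep items whose p-values agree across two analysis variants.

    Returns a boolean mask: True where ``|p_a - p_b| <= max_abs_diff``.
    Intended for comparing two preprocessing variants of the same study
    (e.g. motion-scrubbed vs not); unstable items are dropped before the
    Bonferroni step.
    """
    pa = np.asarray(p_variant_a, dtype=float)
    pb = np.asarray(p_variant_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("p-value vectors must have equal length")
    for v in (pa, pb):
        if np.any((v < 0) | (v > 1)):
            raise ValueError("p-values must lie in [0, 1]")
    return np.abs(pa - pb) <= max_abs_diff


def _replicate_averages(matrices: np.ndarray, idx_per_group: list[np.ndarray]) -> AveragedMatrices:
    A_bar = np.stack([matrices[idx].mean(axis=0) for idx in idx_per_group])
    n_j = np.array([idx.size for idx in idx_per_group])
    A_dd = np.tensordot(n_j, A_bar, axes=1) / n_j.sum()
    return AveragedMatrices(A_bar_j=A_bar, A_doublebar=A_dd, n_j=n_j)


def anocva_test(
    pop: PopulationSet,
    k_clusters: int | str = "auto",
    n_bootstrap: int = 1000,
    seed: int = 0,
    criterion: str = "silhouette",
    recluster_bootstrap: bool = True,
    *,
    slope_p: float = 1.0,
    k_max: int | None = None,
    affinity: str = "linear",
    classical_a: bool = False,
    add_one: bool = False,
) -> AnocvaResult:
    """Run the full test on a :class:`PopulationSet`.

    Parameters
    ----------
    k_clusters
        Number of clusters for the pooled matrix, or ``"auto"`` to estimate
        it with :func:`anocva.clustering.estimate_k` (the estimate is then
        held fixed across bootstrap replicates).
    n_bootstrap
        Number of bootstrap replicates B.
    criterion, slope_p, k_max
        Passed to the cluster-number estimator when ``k_clusters="auto"``;
        ``k_max`` defaults to ``min(10, N - 1)``.
    recluster_bootstrap
        Recompute pooled labels on each replicate's grand average (default,
        matching the starred bootstrap quantities); ``False`` reuses the
        observed labels, which is faster but conditions on them.
    add_one
        Use the ``(1 + count)/(B + 1)`` p-value estimator, which never
        returns zero (recommended when p-values feed a Bonferroni step).

    Notes
    -----
    Deterministic for a fixed ``seed``: the only randomness is the pooled
    resampling of subject indices.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    N = pop.n_items
    if N < 3:
        raise ValueError("need at least 3 items for a meaningful silhouette")

    avg = average_dissimilarity(pop)
    if k_clusters == "auto":
        est = estimate_k(
            avg.A_doublebar,
            k_max=k_max if k_max is not None else min(10, N - 1),
            criterion=criterion,
            slope_p=slope_p,
            seed=seed,
            affinity=affinity,
            classical_a=classical_a,
        )
        k = est.k_best
    else:
        k = int(k_clusters)
        if not 1 <= k <= N:
            raise ValueError(f"k_clusters must lie in 1..{N}")

    labels = spectral_clustering(avg.A_doublebar, k, seed=seed, affinity=affinity, validate=False)
    dS_obs, ds_obs, S, S_j = anocva_statistics(avg, labels, classical_a=classical_a, validate=False)

    rng = np.random.default_rng(seed)
    n, n_j = pop.n, pop.n_j
    mats = pop.matrices
    dS_star = np.empty(n_bootstrap)
    ds_star = np.empty((n_bootstrap, N))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate-level symmetry/degree warnings
        for b in range(n_bootstrap):
            for attempt in range(MAX_REPLICATE_RETRIES + 1):
                idx = [rng.integers(0, n, size=int(m)) for m in n_j]
                try:
                    avg_b = _replicate_averages(mats, idx)
                    if recluster_bootstrap:
                        lab_b = spectral_clustering(
                            avg_b.A_doublebar, k, seed=seed, affinity=affinity, validate=False
                        )
                    else:
                        lab_b = labels
                    if np.unique(lab_b).size < min(k, N):
                        raise ValueError("empty cluster in bootstrap replicate")
                    dS_star[b], ds_star[b], _, _ = anocva_statistics(
                        avg_b, lab_b, classical_a=classical_a, validate=False
                    )
                    break
                except ValueError:
                    if attempt == MAX_REPLICATE_RETRIES:
                        raise
    p_global = pvalue_from_replicates(dS_obs, dS_star, add_one=add_one)
    count_items = (ds_star >= ds_obs[None, :]).sum(axis=0)
    if add_one:
        p_items = (1 + count_items) / (n_bootstrap + 1)
    else:
        p_items = count_items / n_bootstrap
    return AnocvaResult(
        delta_S=dS_obs,
        delta_s=ds_obs,
        p_global=p_global,
        p_items=p_items,
        p_items_adjusted=bonferroni_adjust(p_items),
        k_clusters=k,
        labels=labels,
        n_bootstrap=n_bootstrap,
        seed=seed,
        S=S,
        S_j=S_j,
        options={
            "criterion": criterion,
            "slope_p": slope_p,
            "recluster_bootstrap": recluster_bootstrap,
            "affinity": affinity,
            "classical_a": classical_a,
            "add_one": add_one,
            "k_fixed_during_bootstrap": True,
        },
    )
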