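"""Synthetic populations of dissimilarity matrices with planted cluster structure.

The generator emulates the statistical setting the test assumes: every
subject measures distances among the same N items, the items share a
population-level block (cluster) structure, and subjects deviate from the
population mean by exchangeable noise.  A between-group difference, if
any, is confined to a chosen subset of items whose cluster membership is
reassigned in the second group — so an empty ``effect_items`` set yields
an exact null in which all subjects are i.i.d. regardless of group.

Noise is additive symmetric Gaussian on the dissimilarity scale, clipped
at zero (clipping preserves the exchangeability the null tests rely on).
A companion generator emits item-by-time tables in which items of one
cluster share a latent signal, for exercising the correlation-based
dissimilarity route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PopulationSet

__all__ = ["SyntheticSpec", "generate_population_set", "generate_timeseries_population"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Attributes
    ----------
    n_items : number of items N.
    planted_k : number of planted clusters.
    mu_within : mean within-cluster dissimilarity; a scalar, or one value
        per planted cluster to model unequal within-cluster spreads.
    mu_between : mean between-cluster dissimilarity (> every mu_within).
    noise_sd : standard deviation of the subject-level Gaussian noise.
    n_subjects_per_group : subject counts, one per population.
    effect_items : 1-based item indices whose cluster membership is
        reassigned in group 2; empty means exact null.
    planted_labels : optional explicit length-N 1-based labels for group 1;
        defaults to N items split into planted_k contiguous near-equal blocks.
    seed : generator seed.
    """

    n_items: int = 20
    planted_k: int = 3
    mu_within: float | tuple = 0.3
    mu_between: float = 0.7
    noise_sd: float = 0.05
    n_subjects_per_group: tuple = (15, 15)
    effect_items: tuple = ()
    planted_labels: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        mw = np.atleast_1d(np.asarray(self.mu_within, dtype=float))
        if mw.size not in (1, self.planted_k):
            raise ValueError("mu_within must be scalar or one value per planted cluster")
        if np.any(mw < 0) or self.mu_between <= mw.max():
            raise ValueError("require mu_between > mu_within >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.n_subjects_per_group) < 2 or any(m < 1 for m in self.n_subjects_per_group):
            raise ValueError("need >= 2 groups with >= 1 subject each")
        if not 1 <= self.planted_k <= self.n_items:
            raise ValueError("planted_k must lie in 1..n_items")
        eff = set(self.effect_items)
        if eff and not eff <= set(range(1, self.n_items + 1)):
            raise ValueError("effect_items must be 1-based item indices")

    def labels_for_group(self, group: int) -> np.ndarray:
        """Planted 1-based labels for a group; group >= 2 differs on effect_items."""
        if self.planted_labels is not None:
            base = np.asarray(self.planted_labels, dtype=int)
            if base.shape != (self.n_items,):
                raise ValueError("planted_labels must have length n_items")
        else:
            base = 1 + (np.arange(self.n_items) * self.planted_k) // self.n_items
        if group == 1 or not self.effect_items:
            return base
        lab = base.copy()
        idx = np.asarray(sorted(self.effect_items)) - 1
        lab[idx] = base[idx] % self.planted_k + 1  # deterministic shift to another cluster
        return lab


def _base_matrix(spec: SyntheticSpec, labels: np.ndarray) -> np.ndarray:
    mw = np.broadcast_to(np.atleast_1d(np.asarray(spec.mu_within, dtype=float)), (spec.planted_k,))
    same = labels[:, None] == labels[None, :]
    base = np.where(same, mw[labels - 1][:, None], spec.mu_between)
    np.fill_diagonal(base, 0.0)
    return base


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    z = rng.normal(0.0, sd, size=(n, n))
    upper = np.triu(z, 1)
    return upper + upper.T


def generate_population_set(spec: SyntheticSpec) -> PopulationSet:
    """Draw one synthetic study as a :class:`~anocva.core.PopulationSet`.

    Each subject's matrix is ``clip(base(group) + noise, 0)`` with zero
    diagonal, where ``base`` is the block matrix implied by the group's
    planted labels.  Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mats, group = [], []
    for j, m in enumerate(spec.n_subjects_per_group, start=1):
        base = _base_matrix(spec, spec.labels_for_group(j))
        for _ in range(m):
            D = np.clip(base + _symmetric_noise(rng, spec.n_items, spec.noise_sd), 0.0, None)
            np.fill_diagonal(D, 0.0)
            mats.append(D)
            group.append(j)
    return PopulationSet(np.stack(mats), np.asarray(group))


def generate_timeseries_population(
    spec: SyntheticSpec,
    n_timepoints: int,
    *,
    latent_weight: float = 1.0,
    idiosyncratic_sd: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject item-by-time tables with shared within-cluster signal.

    Each planted cluster carries a standard-normal latent series; item
    ``q`` of a subject observes ``latent_weight * z_{cluster(q)} +
    idiosyncratic_sd * eps_q``, so the expected within-cluster correlation
    is ``latent_weight^2 / (latent_weight^2 + idiosyncratic_sd^2)`` and
    between-cluster correlations are zero in expectation.

    Returns ``(tables, group)`` with ``tables`` of shape (n, N, T).
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")
    rng = np.random.default_rng(spec.seed)
    tables, group = [], []
    for j, m in enumerate(spec.n_subjects_per_group, start=1):
        lab = spec.labels_for_group(j)
        for _ in range(m):
            latents = rng.normal(size=(spec.planted_k, n_timepoints))
            eps = rng.normal(size=(spec.n_items, n_timepoints))
            tables.append(latent_weight * latents[lab - 1] + idiosyncratic_sd * eps)
            group.append(j)
    return np.stack(tables), np.asarray(group)
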