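"""File ingestion, dissimilarity from time series, and the end-to-end pipeline.

Matrix files are dense delimited text (TSV or CSV, autodetected), one per
subject, with an optional header row/column of item ids; all subjects in
a study must share item ids and ordering.  Group membership comes from a
two-column table (subject_id, group).  When subjects arrive as item-by-
time tables instead, pairwise Pearson correlation ``r`` is mapped to a
dissimilarity by one of three metrics — ``1 - |r|`` (default; treats
anticorrelation as similarity, the usual convention for functional
connectivity), ``1 - r``, or ``sqrt(1 - r)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnocvaResult, PopulationSet, anocva_test
from .silhouette import validate_dissimilarity

__all__ = [
    "StudyManifest",
    "read_matrix_file",
    "write_matrix_file",
    "read_group_file",
    "dissimilarity_from_timeseries",
    "load_population_set",
    "run_pipeline",
    "METRICS",
]

logger = logging.getLogger("anocva")

METRICS = ("one_minus_abs_corr", "one_minus_corr", "sqrt_one_minus_corr")


@dataclass
class StudyManifest:
    """The inputs of one study: per-subject files, groups and options.

    ``options`` are forwarded to :func:`anocva.core.anocva_test` (plus
    ``timeseries``/``metric`` controlling ingestion).
    """

    subject_ids: list[str]
    file_paths: list[Path]
    group_labels: list[str]
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.subject_ids) == len(self.file_paths) == len(self.group_labels)):
            raise ValueError("one file and one group label required per subject")
        if len(set(self.group_labels)) < 2:
            raise ValueError("at least two distinct groups are required")


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text ({exc})") from exc


def read_matrix_file(path) -> tuple[np.ndarray, list[str] | None]:
    """Read one dense dissimilarity matrix; returns (values, item_ids).

    Header row and/or id column are detected by non-numeric first cells.
    ``item_ids`` is None when the file carries no ids.  Asymmetry within
    tolerance is repaired silently by ``(D + D.T)/2``; beyond tolerance a
    warning is issued; negative entries are rejected.
    """
    raw = _read_table(path)

    def _numeric(cell) -> bool:
        try:
            float(cell)
            return True
        except (TypeError, ValueError):
            return False

    item_ids = None
    if not _numeric(raw.iloc[0, raw.shape[1] - 1]):  # header row present
        item_ids = [str(x) for x in raw.iloc[0, :]]
        raw = raw.iloc[1:, :]
    if not _numeric(raw.iloc[raw.shape[0] - 1, 0]):  # id column present
        col_ids = [str(x) for x in raw.iloc[:, 0]]
        raw = raw.iloc[:, 1:]
        if item_ids is not None:
            item_ids = item_ids[-raw.shape[1]:]
            if item_ids != col_ids:
                raise ValueError(f"{path}: row and column item ids disagree")
        else:
            item_ids = col_ids

    for i, row in enumerate(raw.itertuples(index=False), start=1):
        for cell in row:
            if not _numeric(cell):
                raise ValueError(f"{path}: non-numeric cell {cell!r} in data row {i}")
    values = raw.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square, shape {values.shape}")
    try:
        return validate_dissimilarity(values), item_ids
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_matrix_file(path, values: np.ndarray, item_ids=None) -> None:
    """Write a matrix as TSV, with an id header row/column when ids are given."""
    values = np.asarray(values, dtype=float)
    if item_ids is not None:
        df = pd.DataFrame(values, index=item_ids, columns=item_ids)
        df.to_csv(path, sep="\t", index=True, header=True, index_label="")
    else:
        pd.DataFrame(values).to_csv(path, sep="\t", index=False, header=False)


def read_group_file(path) -> tuple[list[str], list[str]]:
    """Two-column table (subject_id, group); header optional. Returns (ids, groups)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (subject_id, group)")
    first = str(df.iloc[0, 0]).lower()
    if first in ("subject_id", "subject", "id"):
        df = df.iloc[1:, :]
    return list(df.iloc[:, 0]), list(df.iloc[:, 1])


def dissimilarity_from_timeseries(table, metric: str = "one_minus_abs_corr") -> np.ndarray:
    """Map an item-by-time table to a correlation-based dissimilarity matrix."""
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need an item x time table with >= 3 time points")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0)) + 1
        raise ValueError(f"item {bad} has a constant time series (zero variance)")
    r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    if metric == "one_minus_abs_corr":
        D = 1.0 - np.abs(r)
    elif metric == "one_minus_corr":
        D = 1.0 - r
    elif metric == "sqrt_one_minus_corr":
        D = np.sqrt(np.clip(1.0 - r, 0.0, None))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose one of {METRICS}")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def load_population_set(manifest: StudyManifest) -> tuple[PopulationSet, list[str] | None]:
    """Ingest all subject files of a manifest; returns (population, item_ids)."""
    timeseries = bool(manifest.options.get("timeseries", False))
    metric = manifest.options.get("metric", "one_minus_abs_corr")
    matrices, ref_ids = [], None
    for sid, path in zip(manifest.subject_ids, manifest.file_paths):
        if timeseries:
            raw = _read_table(path)
            ids = None
            try:
                X = raw.to_numpy(dtype=float)
            except ValueError:
                ids = [str(x) for x in raw.iloc[:, 0]]
                X = raw.iloc[:, 1:].to_numpy(dtype=float)
            D = dissimilarity_from_timeseries(X, metric=metric)
        else:
            D, ids = read_matrix_file(path)
        if ref_ids is None:
            ref_ids = ids
        elif ids is not None and ids != ref_ids:
            raise ValueError(f"subject {sid}: item ids disagree with the first subject")
        matrices.append(D)
    return PopulationSet.from_matrices(matrices, manifest.group_labels), ref_ids


def run_pipeline(manifest: StudyManifest) -> AnocvaResult:
    """Ingest -> (optional) dissimilarity computation -> test -> result.

    Logs the chosen number of clusters and the seed; errors from any
    stage propagate with the stage named in the message.
    """
    try:
        pop, item_ids = load_population_set(manifest)
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"ingestion: {exc}") from exc
    opts = manifest.options
    test_kwargs = {
        key: opts[key]
        for key in (
            "k_clusters", "n_bootstrap", "seed", "criterion", "recluster_bootstrap",
            "slope_p", "k_max", "affinity", "classical_a", "add_one",
        )
        if key in opts
    }
    logger.info(
        "running test: n=%d subjects, N=%d items, k groups=%d, seed=%s",
        pop.n, pop.n_items, pop.k, test_kwargs.get("seed", 0),
    )
    try:
        result = anocva_test(pop, **test_kwargs)
    except ValueError as exc:
        raise RuntimeError(f"test: {exc}") from exc
    logger.info("chosen k=%d, p_global=%.4g", result.k_clusters, result.p_global)
    result.options["item_ids"] = item_ids
    return result
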