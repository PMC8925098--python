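"""Morphology clustering: range normalization, Ward tree, 2D embedding.

Cells are clustered on their 16-feature vectors after per-feature range
normalization to [0, 1] over the complete analyzed set (so no feature
dominates through its units). Ward minimum-variance agglomeration under
Euclidean distance is cut at k clusters (default 7); a seeded UMAP embedding
is provided strictly for visualization and never enters statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ClusterModel",
    "normalize_by_range",
    "ward_cut",
    "embed_2d",
    "cluster_abundances",
    "DEFAULT_K",
]

DEFAULT_K = 7


@dataclass
class ClusterModel:
    """Fitted normalization ranges, Ward merge tree and cluster labels.

    Labels are renumbered 1..k by descending cluster size, so cluster 1 is
    always the most abundant morphology.
    """

    feature_names: list[str]
    ranges: pd.DataFrame  # columns: min, max per feature
    merge_tree: np.ndarray  # scipy linkage matrix
    k: int
    labels: np.ndarray  # 1..k per cell
    embedding: np.ndarray | None = None
    embedding_seed: int | None = None


def normalize_by_range(matrix: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each feature to [0, 1] by its min/max over the complete set.

    Constant features map to 0. Returns (normalized matrix, ranges).
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if matrix.shape[0] < 1:
        raise ValueError("need at least one cell")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    mins = values.min(axis=0)
    maxs = values.max(axis=0)
    span = maxs - mins
    normalized = np.zeros_like(values)
    nz = span > 0
    normalized[:, nz] = (values[:, nz] - mins[nz]) / span[nz]
    ranges = pd.DataFrame({"min": mins, "max": maxs}, index=matrix.columns)
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns), ranges


def ward_cut(normalized: pd.DataFrame | np.ndarray, k: int = DEFAULT_K) -> ClusterModel:
    """Ward agglomeration of the normalized matrix, cut at k clusters."""
    if isinstance(normalized, pd.DataFrame):
        names = [str(c) for c in normalized.columns]
        X = normalized.to_numpy(dtype=float)
    else:
        X = np.asarray(normalized, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells n={n}")
    tree = linkage(X, method="ward")
    raw = fcluster(tree, t=k, criterion="maxclust")
    labels = _relabel_by_size(raw)
    ranges = pd.DataFrame(
        {"min": X.min(axis=0), "max": X.max(axis=0)}, index=names
    )
    return ClusterModel(feature_names=names, ranges=ranges, merge_tree=tree, k=k, labels=labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by descending cluster size (ties by old label)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[l] for l in labels], dtype=int)


def embed_2d(normalized: pd.DataFrame | np.ndarray, seed: int = 17) -> np.ndarray:
    """Seeded 2D UMAP embedding of the normalized matrix (plots only)."""
    X = (
        normalized.to_numpy(dtype=float)
        if isinstance(normalized, pd.DataFrame)
        else np.asarray(normalized, dtype=float)
    )
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells for a meaningful embedding")
    import umap  # deferred: numba compilation is slow at import

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(X), dtype=float)


def cluster_abundances(
    labels: np.ndarray, metadata: pd.DataFrame, k: int | None = None
) -> pd.DataFrame:
    """Per (case, subfield) cluster composition in percent.

    ``metadata`` must carry one row per cell with columns ``case_id``,
    ``subfield`` and optionally ``condition``. Each output row sums to 100.
    """
    labels = np.asarray(labels)
    required = {"case_id", "subfield"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    if metadata[list(required)].isna().any().any():
        raise ValueError("missing case/subfield metadata")
    if len(labels) != len(metadata):
        raise ValueError("labels and metadata length mismatch")
    if k is None:
        k = int(labels.max())
    df = metadata.copy()
    df["cluster"] = labels
    counts = (
        df.groupby(["case_id", "subfield"])["cluster"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(1, k + 1), fill_value=0)
    )
    percents = counts.div(counts.sum(axis=1), axis=0) * 100.0
    percents.columns = [f"cluster_{c}" for c in percents.columns]
    if "condition" in metadata.columns:
        cond = df.groupby(["case_id", "subfield"])["condition"].first()
        percents = percents.join(cond)
    return percents.reset_index()
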