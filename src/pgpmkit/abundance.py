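"""Normalized recruitment counts and clustered abundance matrices.

The recruited-read count R of a genome in a sample is put on a common
per-billion-read scale,

    N = R * 1e9 / T,

with T the sample's total read count, so samples of very different sequencing
depth become comparable ("normalized to a total of 1000 million reads").
Environment-level values pool counts before normalizing: the soil value of a
genome is (sum of R over soil samples) * 1e9 / (sum of T over soil samples),
a ratio of sums rather than a mean of ratios, i.e. the normalized count the
pooled environment-wide read set would give.

For heatmap display, rows can be autoscaled (unit-variance scaling: subtract
the row mean, divide by the row population SD) and rows/columns ordered by
average-linkage (UPGMA) hierarchical clustering on Euclidean distances.  The
UPGMA here is the textbook O(n^3) agglomeration with a fixed tie-break (merge
the lexicographically smallest cluster-id pair among minimal distances), which
makes leaf orders reproducible; matrices at this scale are tiny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NORMALIZATION_SCALE",
    "normalize_counts",
    "per_sample_matrix",
    "aggregate_by_environment",
    "autoscale_rows",
    "ClusterResult",
    "cluster_matrix",
    "plot_heatmap",
]

NORMALIZATION_SCALE = 1_000_000_000


def normalize_counts(recruited: float, total_reads: float) -> float:
    """Per-billion-read normalized count N = R * 1e9 / T."""
    if total_reads <= 0:
        raise ValueError("total_reads T must be positive")
    if recruited < 0:
        raise ValueError("recruited count R must be non-negative")
    if recruited > total_reads:
        raise ValueError(f"recruited count R={recruited} exceeds total reads T={total_reads}")
    return recruited * NORMALIZATION_SCALE / total_reads


def _totals_by_sample(metadata) -> dict[str, int]:
    return {m.sample_id: m.total_reads for m in metadata}


def per_sample_matrix(counts: pd.DataFrame, metadata) -> pd.DataFrame:
    """Normalize a genomes x samples matrix of raw counts R column-wise.

    ``metadata`` supplies T per sample; every column of ``counts`` must have
    metadata.
    """
    totals = _totals_by_sample(metadata)
    missing = [s for s in counts.columns if s not in totals]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    out = counts.astype(float).copy()
    for sample in out.columns:
        out[sample] = [normalize_counts(r, totals[sample]) for r in counts[sample]]
    return out


def aggregate_by_environment(counts: pd.DataFrame, metadata) -> pd.DataFrame:
    """Pool raw counts per environment and normalize the pooled totals.

    For environment e and genome g:  N = (sum_s R_sg) * 1e9 / (sum_s T_s)
    over samples s assigned to e.  Input must be *raw* counts (the pooled
    formula is not recoverable from per-sample N values with unequal T).
    """
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in counts.columns if s not in meta]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    environments = sorted({meta[s].environment for s in counts.columns})
    out = pd.DataFrame(0.0, index=counts.index, columns=environments)
    for env in environments:
        samples = [s for s in counts.columns if meta[s].environment == env]
        pooled_r = counts[samples].sum(axis=1)
        pooled_t = sum(meta[s].total_reads for s in samples)
        out[env] = [normalize_counts(r, pooled_t) for r in pooled_r]
    return out


def autoscale_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Unit-variance scale each row: (x - row mean) / row population SD.

    Constant rows have no variance to scale by and map to all-zero, with a
    warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("autoscaling needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=0, keepdims=True)
    flat = sds[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"constant rows mapped to zero: {list(matrix.index[flat])}", stacklevel=2
        )
    sds[flat] = 1.0
    return pd.DataFrame((values - means) / sds, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterResult:
    """Deterministic UPGMA result: leaf orders and scipy-style merge trees."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray  # (n-1, 4): child a, child b, height, size
    col_linkage: np.ndarray


def _upgma(values: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Average-linkage agglomeration on Euclidean distances, O(n^3).

    Tie-break: among all minimal-distance pairs, merge the one whose
    (smaller id, larger id) cluster-id pair is lexicographically smallest.
    Returns a scipy-convention linkage matrix and the left-to-right leaf
    order of the resulting tree (children of a merge ordered small id first).
    """
    n = values.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 observations")
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(values[i] - values[j]))
    active = {i: 1 for i in range(n)}  # cluster id -> size
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), height = best
        size = active[a] + active[b]
        linkage[step] = [a, b, height, size]
        members[next_id] = members[a] + members[b]
        for c in list(active):
            if c in (a, b):
                continue
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d_new = (active[a] * dist[key_a] + active[b] * dist[key_b]) / size
            del dist[key_a], dist[key_b]
            dist[(min(c, next_id), max(c, next_id))] = d_new
        del dist[(a, b)], active[a], active[b], members[a], members[b]
        active[next_id] = size
        next_id += 1

    def leaves(cluster_id: int) -> list[int]:
        if cluster_id < n:
            return [cluster_id]
        a, b = int(linkage[cluster_id - n, 0]), int(linkage[cluster_id - n, 1])
        return leaves(a) + leaves(b)

    return linkage, leaves(next_id - 1)


def cluster_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """Cluster rows and columns independently (UPGMA, Euclidean distance)."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    values = matrix.to_numpy(dtype=float)
    row_linkage, row_leaves = _upgma(values)
    col_linkage, col_leaves = _upgma(values.T)
    return ClusterResult(
        row_order=[matrix.index[i] for i in row_leaves],
        col_order=[matrix.columns[i] for i in col_leaves],
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )


def plot_heatmap(matrix: pd.DataFrame, path, cluster: bool = True, **heatmap_kwargs) -> None:
    """Render the (optionally clustered) matrix as a heatmap PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if cluster and matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
        result = cluster_matrix(matrix)
        matrix = matrix.loc[result.row_order, result.col_order]
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.5 * matrix.shape[1], 1.0 + 0.3 * matrix.shape[0])
    )
    sns.heatmap(matrix, ax=ax, **heatmap_kwargs)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
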