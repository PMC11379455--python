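"""Unsupervised subclustering of an extracted population.

After the main lineages are annotated, a population of interest is
usually dissected further with whatever clustering tool the analyst
trusts. The interface here is therefore pluggable: built-in backends
("kmeans", a seeded multi-restart Lloyd's k-means, and "som_meta", a
self-organizing map whose node codebooks are merged into k metaclusters
by average-linkage hierarchical clustering) keep the pipeline
self-contained, while :func:`external_labels` adopts any label vector
produced elsewhere so its clusters flow into medians, merging and
differential analysis. Seeds are mandatory -- repeated runs must agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .classify import CellAnnotation
from .errors import DataError, ParameterError, ValidationError
from .experiment import Experiment

KMEANS_RESTARTS = 20
SOM_GRID = (10, 10)
SOM_EPOCHS = 10


@dataclass
class ClusterResult:
    """Per-cell integer cluster ids (contiguous 0..k-1, none empty) with
    the per-cluster marker medians used for annotation heatmaps."""

    labels: np.ndarray
    k: int
    method: str
    seed: int
    medians: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValidationError(
                f"cluster ids must be contiguous 0..{self.k - 1} and nonempty"
            )
        if self.medians.shape[0] != self.k:
            raise ValidationError("medians row count must equal k")

    @property
    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def cluster_medians(experiment: Experiment, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster per-marker medians (transformed scale), cluster-ordered.

    Invariant to cell order; suitable for heatmap export.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != experiment.n_cells:
        raise DataError("labels do not align with experiment")
    df = pd.DataFrame(experiment.intensities, columns=experiment.marker_names)
    df["__cluster"] = labels
    med = df.groupby("__cluster").median()
    med.index.name = "cluster"
    return med


def _relabel_contiguous(labels: np.ndarray) -> tuple[np.ndarray, int]:
    ids = np.unique(labels)
    lut = {old: new for new, old in enumerate(ids)}
    return np.asarray([lut[v] for v in labels], dtype=np.int64), len(ids)


def _som_fit(
    data: np.ndarray, grid: tuple[int, int], seed: int, epochs: int = SOM_EPOCHS
) -> np.ndarray:
    """Train a rectangular SOM; returns node codebooks (rows*cols x dims).

    Batch-style online updates with a fixed linear decay of learning rate
    (0.5 -> 0.02) and neighbourhood radius (max(grid)/2 -> 0.5), Gaussian
    neighbourhood on the grid, seeded sampling order. Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    rows, cols = grid
    n_nodes = rows * cols
    grid_xy = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    init_idx = rng.choice(data.shape[0], size=n_nodes, replace=data.shape[0] < n_nodes)
    codebook = data[init_idx].astype(float).copy()
    n_steps = epochs * data.shape[0]
    order = rng.integers(0, data.shape[0], size=n_steps)
    radius0, radius1 = max(grid) / 2.0, 0.5
    lr0, lr1 = 0.5, 0.02
    for step, idx in enumerate(order):
        frac = step / max(n_steps - 1, 1)
        radius = radius0 + (radius1 - radius0) * frac
        lr = lr0 + (lr1 - lr0) * frac
        x = data[idx]
        bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
        dist2 = ((grid_xy - grid_xy[bmu]) ** 2).sum(axis=1)
        h = np.exp(-dist2 / (2.0 * radius * radius))
        codebook += (lr * h)[:, None] * (x - codebook)
    return codebook


def cluster_subset(
    experiment: Experiment,
    method: str,
    k: int,
    seed: int,
    som_grid: tuple[int, int] = SOM_GRID,
) -> ClusterResult:
    """Cluster an (extracted) experiment's cells into k groups.

    "kmeans": Lloyd's algorithm with k-means++ seeding, 20 restarts, best
    within-cluster sum of squares kept. "som_meta": SOM training followed
    by average-linkage merging of node codebooks into exactly k
    metaclusters; cells adopt their best-matching node's metacluster, and
    any metacluster left empty is repopulated with its nearest cell so the
    requested k is honoured. Both are deterministic given the seed.
    """
    if not experiment.transformed:
        raise ParameterError("cluster_subset expects transformed intensities")
    n = experiment.n_cells
    if k < 1 or k > n:
        raise ParameterError(f"k must be in [1, n_cells={n}], got {k}")
    data = experiment.intensities

    if method == "kmeans":
        if k == 1:
            labels = np.zeros(n, dtype=np.int64)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=KMEANS_RESTARTS,
                random_state=int(seed) % (2**32),
            ).fit(data)
            labels = km.labels_.astype(np.int64)
    elif method == "som_meta":
        grid = som_grid
        if grid[0] * grid[1] > n:  # shrink the map for tiny populations
            side = max(1, int(np.sqrt(n)))
            grid = (side, side)
        if grid[0] * grid[1] < k:
            raise ParameterError(
                f"SOM grid {grid} has fewer nodes than k={k}"
            )
        codebook = _som_fit(data, grid, seed)
        bmu = np.argmin(cdist(data, codebook), axis=1)
        # drop unoccupied nodes: they interpolate between populations and
        # chain otherwise-separate metaclusters together
        occupied = np.unique(bmu)
        codebook = codebook[occupied]
        bmu = np.searchsorted(occupied, bmu)
        if k > codebook.shape[0]:
            raise ParameterError(
                f"SOM collapsed to {codebook.shape[0]} occupied nodes < k={k}; "
                "use a larger grid or smaller k"
            )
        if k == 1:
            meta_of_node = np.zeros(codebook.shape[0], dtype=np.int64)
        else:
            z = linkage(codebook, method="average")
            meta_of_node = fcluster(z, t=k, criterion="maxclust") - 1
        labels = meta_of_node[bmu].astype(np.int64)
        labels = _fill_empty_metaclusters(labels, data, codebook, meta_of_node, k)
    else:
        raise ParameterError(
            f"unknown method {method!r}; choose 'kmeans' or 'som_meta'"
        )

    labels, k_eff = _relabel_contiguous(labels)
    medians = cluster_medians(experiment, labels)
    return ClusterResult(
        labels=labels, k=k_eff, method=method, seed=int(seed), medians=medians
    )


def _fill_empty_metaclusters(
    labels: np.ndarray,
    data: np.ndarray,
    codebook: np.ndarray,
    meta_of_node: np.ndarray,
    k: int,
) -> np.ndarray:
    """Move the nearest cell into any metacluster that ended up empty."""
    labels = labels.copy()
    for meta in range(k):
        if (labels == meta).any():
            continue
        centroid = codebook[meta_of_node == meta].mean(axis=0)
        dists = ((data - centroid) ** 2).sum(axis=1)
        # never steal from a singleton cluster
        sizes = np.bincount(labels, minlength=k)
        for cand in np.argsort(dists, kind="stable"):
            if sizes[labels[cand]] > 1:
                sizes[labels[cand]] -= 1
                labels[cand] = meta
                break
    return labels


def external_labels(experiment: Experiment, labels: np.ndarray) -> ClusterResult:
    """Adopt a label vector produced by an external clustering tool."""
    labels = np.asarray(labels)
    if labels.shape[0] != experiment.n_cells:
        raise DataError("external labels do not align with experiment")
    contiguous, k = _relabel_contiguous(labels)
    return ClusterResult(
        labels=contiguous,
        k=k,
        method="external",
        seed=-1,
        medians=cluster_medians(experiment, contiguous),
    )


def merge_clusters(result: ClusterResult, mapping: dict[int, str]) -> CellAnnotation:
    """Name and merge clusters into a lineage-style annotation.

    ``mapping`` must cover every cluster id 0..k-1; several ids may share
    a name, which merges them. The output plugs directly into abundance
    tables, metrics and differential analysis.
    """
    missing = [i for i in range(result.k) if i not in mapping]
    if missing:
        raise ValidationError(f"mapping misses cluster ids {missing}")
    unknown = [i for i in mapping if i not in range(result.k)]
    if unknown:
        raise ValidationError(f"mapping names nonexistent cluster ids {unknown}")
    names = np.asarray([mapping[i] for i in range(result.k)], dtype=object)
    return CellAnnotation(
        labels=names[result.labels],
        match_counts=np.ones(result.labels.size, dtype=np.int64),
    )
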