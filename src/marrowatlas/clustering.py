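"""kNN-graph Louvain clustering of the reference embedding and
one-vs-rest Wilcoxon marker detection per cluster."""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._stats import bh_adjust, group_log_fold_change, rank_sum_de
from .dataset import CellDataset


@dataclass
class ClusterResult:
    assignments: pd.Series      # index: cell position or id, value: cluster id
    modularity: float
    markers: Optional[pd.DataFrame] = None


def knn_graph(embedding: np.ndarray, k: int = 20) -> ig.Graph:
    """Undirected, unweighted k-nearest-neighbour graph (Euclidean)."""
    n = len(embedding)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    idx = nn.kneighbors(embedding, return_distance=False)[:, 1:]  # drop self
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_louvain(embedding: np.ndarray, k: int = 20, seed: int = 0,
                    cell_ids=None) -> ClusterResult:
    """Louvain community detection on the kNN graph; deterministic per seed."""
    g = knn_graph(embedding, k=k)
    ig.set_random_number_generator(random.Random(seed))
    try:
        part = g.community_multilevel()
    finally:
        ig.set_random_number_generator(random)
    index = cell_ids if cell_ids is not None else np.arange(len(embedding))
    assignments = pd.Series(part.membership, index=index, name="cluster")
    return ClusterResult(assignments=assignments,
                         modularity=float(part.modularity))


def partition_modularity(embedding: np.ndarray, membership, k: int = 20) -> float:
    """Modularity of an arbitrary partition on the same kNN graph."""
    g = knn_graph(embedding, k=k)
    return float(g.modularity(list(membership)))


def cluster_markers(ds: CellDataset, assignments: pd.Series,
                    min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    Returns a long table (cluster, gene_id, logFC, p, p_adj) where logFC
    is the natural-log fold change of de-logged mean normalised
    expression with pseudocount 1, and p_adj is BH-adjusted within each
    cluster.  Clusters with fewer than ``min_cells`` cells are skipped.
    """
    if ds.normalized is None:
        raise ValueError("cluster_markers requires normalized expression")
    labels = np.asarray(assignments)
    if np.unique(labels).size < 2:
        raise ValueError("cluster_markers requires at least 2 clusters")
    norm = ds.normalized.tocsc()
    frames = []
    for cluster in np.unique(labels):
        mask = labels == cluster
        if mask.sum() < min_cells:
            warnings.warn(
                f"cluster {cluster!r} has {int(mask.sum())} cells "
                f"(< {min_cells}); skipped"
            )
            continue
        in_c = norm[:, mask]
        out_c = norm[:, ~mask]
        p = rank_sum_de(in_c, out_c)
        lfc = group_log_fold_change(in_c, out_c)
        frames.append(pd.DataFrame({
            "cluster": cluster,
            "gene_id": ds.gene_ids,
            "logFC": lfc,
            "p": p,
            "p_adj": bh_adjust(p),
        }))
    if not frames:
        return pd.DataFrame(columns=["cluster", "gene_id", "logFC", "p", "p_adj"])
    return pd.concat(frames, ignore_index=True)


def annotate_clusters_by_majority(assignments: pd.Series,
                                  true_labels: Dict) -> Dict:
    """Map each cluster to the modal true label of its members."""
    df = pd.DataFrame({
        "cluster": np.asarray(assignments),
        "label": [true_labels[c] for c in assignments.index],
    })
    return (
        df.groupby("cluster")["label"]
        .agg(lambda s: s.value_counts().idxmax())
        .to_dict()
    )
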