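"""Reference embedding: consensus HVG selection, scaling + PCA, and a
mutual-nearest-neighbour batch correction in PC space.

The embedding is a frozen transform: highly variable genes, per-gene
scaling statistics and PCA loadings are learned once on the reference and
later applied unchanged to query data, so queries can be projected into
the reference space without touching the reference itself.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from .dataset import CellDataset


# ---------------------------------------------------------------------
# consensus highly variable genes
# ---------------------------------------------------------------------

def _per_gene_moments(norm: sp.spmatrix, cols: np.ndarray
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and (population) variance per gene over the selected cells."""
    sub = norm[:, cols]
    n = sub.shape[1]
    mean = np.asarray(sub.mean(axis=1)).ravel()
    sq = np.asarray(sub.multiply(sub).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    return mean, var


def consensus_hvg(ds: CellDataset, per_sample_n: int = 3000,
                  consensus_n: int = 3000,
                  return_table: bool = False):
    """Consensus highly variable genes across samples.

    Per sample, genes are ranked by the variance of their log-normalised
    expression (the log transform is the variance stabiliser), with ties
    broken by higher mean expression, then lexicographic gene id, and the
    top ``per_sample_n`` genes taken.  Genes are then ranked by how many
    samples' lists contain them (ties: higher mean variance across
    samples, then gene id) and the top ``consensus_n`` returned.
    """
    if ds.normalized is None:
        raise ValueError("consensus_hvg requires normalized expression; "
                         "run normalize_total first")
    norm = ds.normalized.tocsc()
    gene_ids = ds.gene_ids
    sample_ids = ds.cell_table["sample_id"].to_numpy()
    samples = list(ds.sample_table["sample_id"])
    if not samples:
        raise ValueError("dataset has no samples")

    counts_in_top = np.zeros(ds.n_genes, dtype=int)
    var_sum = np.zeros(ds.n_genes)
    for sid in samples:
        cols = np.nonzero(sample_ids == sid)[0]
        if cols.size == 0:
            continue
        mean, var = _per_gene_moments(norm, cols)
        var_sum += var
        order = np.lexsort((gene_ids, -mean, -var))  # primary key last
        top = order[:per_sample_n]
        counts_in_top[top] += 1

    mean_var = var_sum / len(samples)
    order = np.lexsort((gene_ids, -mean_var, -counts_in_top))
    if consensus_n > ds.n_genes:
        warnings.warn(
            f"consensus_n={consensus_n} exceeds the {ds.n_genes} genes "
            "available; returning all genes"
        )
    chosen = order[:consensus_n]
    hvg = list(gene_ids[chosen])
    if return_table:
        table = pd.DataFrame({
            "gene_id": gene_ids,
            "n_samples_in_top": counts_in_top,
            "mean_variance": mean_var,
        })
        return hvg, table
    return hvg


# ---------------------------------------------------------------------
# scaling + PCA as a frozen, queryable transform
# ---------------------------------------------------------------------

class ReferenceEmbedding(BaseEstimator, TransformerMixin):
    """Frozen scale-and-PCA transform over a fixed HVG list.

    ``fit`` standardises each HVG to zero mean / unit variance on the
    reference (values clipped at ``+/- clip_value``) and computes a
    truncated SVD; ``transform`` projects any dataset into the same PC
    space using the *reference* scaling statistics and loadings, imputing
    genes absent from the query as zero expression.

    Attributes (after fit)
    ----------------------
    hvg_genes_ : list of gene ids used as features
    scale_means_, scale_sds_ : per-gene scaling statistics
    loadings_ : (n_hvg, n_components) orthonormal PCA loadings
    embedding_ : (n_cells, n_components) reference embedding
    explained_variance_ : per-component variance (non-increasing)
    """

    def __init__(self, n_components: int = 30, clip_value: float = 10.0,
                 min_gene_overlap: float = 0.5, random_state: int = 0):
        self.n_components = n_components
        self.clip_value = clip_value
        self.min_gene_overlap = min_gene_overlap
        self.random_state = random_state

    # -- helpers ------------------------------------------------------
    def _dense_hvg(self, ds: CellDataset, genes: Sequence[str]) -> np.ndarray:
        """Cells x genes dense matrix over ``genes``, zeros where absent."""
        if ds.normalized is None:
            raise ValueError("dataset lacks normalized expression")
        index = pd.Index(ds.gene_ids)
        pos = index.get_indexer(genes)
        present = pos >= 0
        out = np.zeros((ds.n_cells, len(genes)))
        if present.any():
            sub = ds.normalized[pos[present], :].toarray().T
            out[:, present] = sub
        return out

    def fit(self, ds: CellDataset, hvg_genes: Sequence[str] = None
            ) -> "ReferenceEmbedding":
        if hvg_genes is None:
            hvg_genes = consensus_hvg(ds)
        hvg_genes = list(hvg_genes)
        if self.n_components > min(ds.n_cells, len(hvg_genes)):
            raise ValueError(
                f"n_components={self.n_components} exceeds "
                f"min(n_cells={ds.n_cells}, n_hvg={len(hvg_genes)})"
            )
        X = self._dense_hvg(ds, hvg_genes)
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        zero_sd = sds == 0
        if zero_sd.any():
            warnings.warn(f"{zero_sd.sum()} constant genes among HVGs; "
                          "their scaled values are set to 0")
            sds = np.where(zero_sd, 1.0, sds)
        Xs = np.clip((X - means) / sds, -self.clip_value, self.clip_value)
        U, S, Vt = randomized_svd(Xs, n_components=self.n_components,
                                  random_state=self.random_state)
        # deterministic sign convention: largest-|.| loading entry positive
        signs = np.sign(Vt[np.arange(Vt.shape[0]),
                           np.argmax(np.abs(Vt), axis=1)])
        signs[signs == 0] = 1.0
        Vt = Vt * signs[:, None]
        self.hvg_genes_ = hvg_genes
        self.scale_means_ = means
        self.scale_sds_ = sds
        self.loadings_ = Vt.T
        self.embedding_ = Xs @ self.loadings_
        n = max(ds.n_cells - 1, 1)
        self.explained_variance_ = (S**2) / n
        self.cell_ids_ = list(ds.cell_ids)
        return self

    def transform(self, ds: CellDataset) -> np.ndarray:
        """Project a (query) dataset with the frozen reference transform."""
        if not hasattr(self, "loadings_"):
            raise ValueError("ReferenceEmbedding is not fitted")
        present = pd.Index(ds.gene_ids).get_indexer(self.hvg_genes_) >= 0
        overlap = float(present.mean())
        if overlap < self.min_gene_overlap:
            raise ValueError(
                f"only {overlap:.0%} of the model's {len(self.hvg_genes_)} "
                f"feature genes are present in the query (< "
                f"{self.min_gene_overlap:.0%} required)"
            )
        X = self._dense_hvg(ds, self.hvg_genes_)
        Xs = np.clip((X - self.scale_means_) / self.scale_sds_,
                     -self.clip_value, self.clip_value)
        return Xs @ self.loadings_

    def fit_transform(self, ds: CellDataset, hvg_genes=None) -> np.ndarray:
        return self.fit(ds, hvg_genes=hvg_genes).embedding_


# ---------------------------------------------------------------------
# MNN batch correction in PC space
# ---------------------------------------------------------------------

def batch_correct_mnn(embedding: np.ndarray, studies: Sequence,
                      k_mnn: int = 20, sigma: Optional[float] = None
                      ) -> Tuple[np.ndarray, Dict]:
    """Correct per-study shifts via mutual nearest neighbours in PC space.

    Studies are merged in decreasing size order into a growing corrected
    pool.  For each incoming study, mutual nearest neighbour pairs against
    the pool define correction vectors; each incoming cell receives a
    Gaussian-kernel-weighted average of the pair vectors (bandwidth
    ``sigma``, default the median distance of incoming cells to their
    nearest paired cell).  A single study is returned unchanged.
    """
    embedding = np.asarray(embedding, dtype=float)
    studies = np.asarray(studies)
    uniq, counts = np.unique(studies, return_counts=True)
    info: Dict = {"order": [], "n_pairs": {}, "sigma": {}}
    if len(uniq) <= 1:
        return embedding.copy(), info

    order = [u for _, u in sorted(zip(-counts, uniq.tolist()))]
    info["order"] = order
    corrected = embedding.copy()
    pool_mask = studies == order[0]
    for study in order[1:]:
        batch_mask = studies == study
        pool = corrected[pool_mask]
        batch = corrected[batch_mask]
        k = min(k_mnn, len(pool), len(batch))
        if k < k_mnn:
            warnings.warn(
                f"study {study!r} or pool smaller than k_mnn={k_mnn}; "
                f"using k={k}"
            )
        nn_pool = NearestNeighbors(n_neighbors=k).fit(pool)
        nn_batch = NearestNeighbors(n_neighbors=k).fit(batch)
        b2p = nn_pool.kneighbors(batch, return_distance=False)
        p2b = nn_batch.kneighbors(pool, return_distance=False)
        # mutual pairs: (i in batch, j in pool)
        pool_nn_sets = [set(row) for row in p2b]
        pairs = [
            (i, j)
            for i in range(len(batch))
            for j in b2p[i]
            if i in pool_nn_sets[j]
        ]
        info["n_pairs"][study] = len(pairs)
        if not pairs:
            warnings.warn(f"no MNN pairs found for study {study!r}; "
                          "left uncorrected")
            pool_mask = pool_mask | batch_mask
            continue
        pi = np.array([p[0] for p in pairs])
        pj = np.array([p[1] for p in pairs])
        vectors = pool[pj] - batch[pi]  # correction toward the pool
        anchors = batch[pi]
        # Gaussian smoothing of pair vectors over the incoming batch
        d2 = cdist(batch, anchors, metric="sqeuclidean")
        if sigma is None:
            nearest = np.sqrt(d2.min(axis=1))
            s = max(float(np.median(nearest)), 1e-8)
        else:
            s = float(sigma)
        info["sigma"][study] = s
        w = np.exp(-d2 / (2.0 * s * s))
        w_sum = w.sum(axis=1, keepdims=True)
        # cells far from every anchor fall back to the mean pair vector
        mean_vec = vectors.mean(axis=0)
        corr = np.where(
            w_sum > 1e-12, (w @ vectors) / np.maximum(w_sum, 1e-12), mean_vec
        )
        corrected[batch_mask] = batch + corr
        pool_mask = pool_mask | batch_mask
    return corrected, info
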