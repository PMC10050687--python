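"""Query-to-reference mapping: kNN label transfer, confidence scoring,
two-component Gaussian-mixture gating, and disease-vs-healthy DE.

Each query cell receives the modal cell-type label of its 30 nearest
reference neighbours in PC space, and a confidence score: the inverse of
its mean neighbour distance, min-max normalised to [0, 1] over the query
dataset.  Low confidence marks cell states absent from the healthy
reference (candidate diseased cells).  A two-component 1-D Gaussian
mixture fitted to the scores separates confidently mapped cells (the
higher-mean component) from the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from ._stats import bh_adjust, group_log_fold_change, rank_sum_de
from .dataset import CellDataset


# ---------------------------------------------------------------------
# label transfer
# ---------------------------------------------------------------------

def transfer_labels(ref_embedding: np.ndarray, ref_labels: Sequence,
                    query_embedding: np.ndarray, k: int = 30,
                    epsilon: float = 1e-12):
    """kNN label transfer from reference to query cells.

    Per query cell the transferred label is the most prevalent among its
    ``k`` Euclidean nearest reference cells; ties are broken by the
    larger summed inverse distance, then lexicographically.

    Returns (labels, neighbor_indices, neighbor_distances).
    """
    ref_labels = np.asarray(ref_labels)
    n_ref = len(ref_embedding)
    k_eff = min(k, n_ref)
    if k_eff < k:
        warnings.warn(f"reference has only {n_ref} cells; using k={k_eff}")
    nn = NearestNeighbors(n_neighbors=k_eff).fit(ref_embedding)
    dist, idx = nn.kneighbors(query_embedding)
    labels = np.empty(len(query_embedding), dtype=object)
    inv = 1.0 / (dist + epsilon)
    for i in range(len(query_embedding)):
        neigh = ref_labels[idx[i]]
        uniq, counts = np.unique(neigh, return_counts=True)
        best = counts.max()
        tied = uniq[counts == best]
        if len(tied) == 1:
            labels[i] = tied[0]
        else:
            weight = {
                lab: inv[i][neigh == lab].sum() for lab in tied
            }
            top = max(weight.values())
            cands = sorted(lab for lab, w in weight.items()
                           if np.isclose(w, top, rtol=1e-12, atol=0.0))
            labels[i] = cands[0]
    return labels, idx, dist


def confidence_scores(neighbor_distances: np.ndarray,
                      epsilon: float = 1e-12,
                      stat: str = "mean") -> np.ndarray:
    """Normalised inverse-distance confidence in [0, 1].

    raw_i = 1 / (mean_k distance_i + epsilon); scores are min-max
    normalised over the query dataset (min -> 0, max -> 1).  If all raw
    scores are equal, every cell gets confidence 1 with a warning.
    """
    d = np.asarray(neighbor_distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    agg = d.mean(axis=1) if stat == "mean" else np.median(d, axis=1)
    raw = 1.0 / (agg + epsilon)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("all raw confidence scores equal; returning 1 for all")
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


# ---------------------------------------------------------------------
# two-component Gaussian mixture gate
# ---------------------------------------------------------------------

@dataclass
class GateModel:
    """Fitted 1-D two-component Gaussian mixture over confidence scores."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    confident_component: int            # index of the higher-mean component
    responsibilities: np.ndarray        # (n_cells, 2)
    log_likelihoods: np.ndarray         # per EM iteration (non-decreasing)
    degenerate: bool = False


def gate_confident(confidences: np.ndarray, seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-8,
                   min_var: float = 1e-6):
    """Fit the two-component mixture and flag confident cells.

    EM with k-means initialisation (fixed seed); convergence when the
    log-likelihood improves by less than ``tol`` or after ``max_iter``
    iterations.  ``confident`` = posterior probability of the higher-mean
    component >= 0.5.  Degenerate input (all scores equal) yields a
    flagged GateModel with every cell confident.

    Returns (GateModel, confident boolean array).
    """
    x = np.asarray(confidences, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("gate_confident requires at least 10 cells")
    if np.ptp(x) == 0:
        gm = GateModel(
            means=np.array([x[0], x[0]]),
            variances=np.array([min_var, min_var]),
            weights=np.array([0.5, 0.5]),
            confident_component=1,
            responsibilities=np.full((n, 2), 0.5),
            log_likelihoods=np.array([]),
            degenerate=True,
        )
        return gm, np.ones(n, dtype=bool)

    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x[:, None])
    assign = km.labels_
    means = np.array([x[assign == c].mean() for c in (0, 1)])
    var = np.array([
        max(x[assign == c].var(), min_var) for c in (0, 1)
    ])
    weights = np.array([(assign == c).mean() for c in (0, 1)])

    def log_pdf(x, m, v):
        return -0.5 * (np.log(2 * np.pi * v) + (x - m) ** 2 / v)

    lls = []
    resp = np.full((n, 2), 0.5)
    for _ in range(max_iter):
        log_comp = np.stack(
            [np.log(weights[c]) + log_pdf(x, means[c], var[c]) for c in (0, 1)],
            axis=1,
        )
        m = log_comp.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[:, None])
        if lls and ll - lls[-1] < tol:
            lls.append(ll)
            break
        lls.append(ll)
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, min_var)

    hi = int(np.argmax(means))
    gm = GateModel(
        means=means, variances=var, weights=weights,
        confident_component=hi, responsibilities=resp,
        log_likelihoods=np.array(lls), degenerate=False,
    )
    confident = resp[:, hi] >= 0.5
    return gm, confident


# ---------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------

@dataclass
class MappingResult:
    """Per-query-cell mapping outcome."""

    table: pd.DataFrame           # cell_id, transferred_label, raw_score,
                                  # confidence, confident
    neighbor_ids: np.ndarray      # (n_query, k) reference cell ids
    gate: GateModel

    def confident_cells(self) -> np.ndarray:
        return self.table.loc[self.table["confident"], "cell_id"].to_numpy()


class ReferenceMapper(BaseEstimator):
    """Map query cells onto a frozen reference embedding.

    ``fit`` stores the reference embedding and labels; ``predict`` runs
    label transfer, confidence scoring and the mixture gate on a query
    embedding produced by the same :class:`ReferenceEmbedding` transform.
    """

    def __init__(self, n_neighbors: int = 30, epsilon: float = 1e-12,
                 distance_stat: str = "mean", random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.epsilon = epsilon
        self.distance_stat = distance_stat
        self.random_state = random_state

    def fit(self, ref_embedding: np.ndarray, ref_labels: Sequence,
            ref_cell_ids: Optional[Sequence] = None) -> "ReferenceMapper":
        self.ref_embedding_ = np.asarray(ref_embedding, dtype=float)
        self.ref_labels_ = np.asarray(ref_labels)
        self.ref_cell_ids_ = (
            np.asarray(ref_cell_ids) if ref_cell_ids is not None
            else np.arange(len(self.ref_labels_))
        )
        return self

    def predict(self, query_embedding: np.ndarray,
                query_cell_ids: Optional[Sequence] = None) -> MappingResult:
        if not hasattr(self, "ref_embedding_"):
            raise ValueError("ReferenceMapper is not fitted")
        labels, idx, dist = transfer_labels(
            self.ref_embedding_, self.ref_labels_, query_embedding,
            k=self.n_neighbors, epsilon=self.epsilon,
        )
        agg = dist.mean(axis=1) if self.distance_stat == "mean" \
            else np.median(dist, axis=1)
        raw = 1.0 / (agg + self.epsilon)
        conf = confidence_scores(dist, epsilon=self.epsilon,
                                 stat=self.distance_stat)
        gate, confident = gate_confident(conf, seed=self.random_state)
        ids = (np.asarray(query_cell_ids) if query_cell_ids is not None
               else np.arange(len(query_embedding)))
        table = pd.DataFrame({
            "cell_id": ids,
            "transferred_label": labels,
            "raw_score": raw,
            "confidence": conf,
            "confident": confident,
        })
        return MappingResult(table=table,
                             neighbor_ids=self.ref_cell_ids_[idx],
                             gate=gate)


# ---------------------------------------------------------------------
# disease vs healthy differential expression
# ---------------------------------------------------------------------

def disease_de(query: CellDataset, ref: CellDataset, cell_type: str,
               query_labels: Mapping = None, ref_labels: Mapping = None,
               p_threshold: float = 0.05, lfc_threshold: float = 0.5
               ) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between query and reference cells of one type.

    logFC = ln((mean expm1 query + 1) / (mean expm1 ref + 1)) on the
    normalised scale; a gene is significant when p < ``p_threshold`` and
    |logFC| > ``lfc_threshold``; BH-adjusted p is reported alongside.
    """
    if query.normalized is None or ref.normalized is None:
        raise ValueError("disease_de requires normalized expression")

    def mask_for(ds, labels):
        if labels is None:
            lab = ds.cell_table["label"].to_numpy()
        else:
            lab = np.array([labels[c] for c in ds.cell_ids])
        return lab == cell_type

    qm = mask_for(query, query_labels)
    rm = mask_for(ref, ref_labels)
    for name, m in (("query", qm), ("reference", rm)):
        if not m.any():
            raise ValueError(f"cell type {cell_type!r} absent from {name}")
        if m.sum() < 3:
            raise ValueError(
                f"cell type {cell_type!r} has fewer than 3 {name} cells"
            )
    shared = sorted(set(query.gene_ids) & set(ref.gene_ids))
    qpos = pd.Index(query.gene_ids).get_indexer(shared)
    rpos = pd.Index(ref.gene_ids).get_indexer(shared)
    qn = query.normalized[qpos][:, qm]
    rn = ref.normalized[rpos][:, rm]
    p = rank_sum_de(qn, rn)
    lfc = group_log_fold_change(qn, rn)
    out = pd.DataFrame({
        "gene_id": shared,
        "logFC": lfc,
        "p": p,
        "p_adj": bh_adjust(p),
    })
    out["significant"] = (out["p"] < p_threshold) & \
        (out["logFC"].abs() > lfc_threshold)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
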