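"""End-to-end conveniences tying the stages together.

``build_reference`` runs consensus HVG selection, scaling + PCA, MNN
batch correction and Louvain clustering on a QC'd, normalised reference
dataset; ``map_query`` projects a query dataset with the frozen
transform and runs label transfer plus confidence gating against the
corrected reference embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterResult, cluster_louvain
from .dataset import CellDataset
from .embedding import ReferenceEmbedding, batch_correct_mnn, consensus_hvg
from .mapping import MappingResult, ReferenceMapper


@dataclass
class ReferenceAtlas:
    """Frozen reference: embedding transform, corrected embedding,
    clusters, and per-cell labels used for transfer."""

    embedding_model: ReferenceEmbedding
    corrected_embedding: np.ndarray
    clusters: ClusterResult
    cell_ids: np.ndarray
    labels: np.ndarray

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        m = self.embedding_model
        pd.DataFrame({
            "gene_id": m.hvg_genes_,
            "scale_mean": m.scale_means_,
            "scale_sd": m.scale_sds_,
        }).to_csv(path / "scaling.tsv", sep="\t", index=False)
        pd.DataFrame(
            m.loadings_, index=m.hvg_genes_,
            columns=[f"PC{i+1}" for i in range(m.loadings_.shape[1])],
        ).to_csv(path / "loadings.tsv", sep="\t")
        emb = pd.DataFrame(
            self.corrected_embedding, index=self.cell_ids,
            columns=[f"PC{i+1}" for i in range(self.corrected_embedding.shape[1])],
        )
        emb.insert(0, "label", self.labels)
        emb.insert(1, "cluster", np.asarray(self.clusters.assignments))
        emb.to_csv(path / "reference_embedding.tsv", sep="\t",
                   index_label="cell_id")


def build_reference(ds: CellDataset, labels: Optional[Dict] = None,
                    per_sample_n: int = 3000, consensus_n: int = 3000,
                    n_components: int = 30, knn_k: int = 20,
                    mnn_k: int = 20, seed: int = 0) -> ReferenceAtlas:
    """Build the frozen reference atlas from a normalised dataset."""
    hvg = consensus_hvg(ds, per_sample_n=per_sample_n,
                        consensus_n=consensus_n)
    model = ReferenceEmbedding(n_components=n_components,
                               random_state=seed).fit(ds, hvg_genes=hvg)
    corrected, _ = batch_correct_mnn(
        model.embedding_, ds.cell_table["study_id"].to_numpy(), k_mnn=mnn_k,
    )
    clusters = cluster_louvain(corrected, k=knn_k, seed=seed,
                               cell_ids=ds.cell_ids)
    if labels is not None:
        lab = np.array([labels[c] for c in ds.cell_ids])
    elif "label" in ds.cell_table.columns:
        lab = ds.cell_table["label"].to_numpy()
    else:
        lab = np.asarray(clusters.assignments).astype(str)
    return ReferenceAtlas(
        embedding_model=model, corrected_embedding=corrected,
        clusters=clusters, cell_ids=ds.cell_ids, labels=lab,
    )


def map_query(atlas: ReferenceAtlas, query: CellDataset,
              n_neighbors: int = 30, seed: int = 0
              ) -> tuple[np.ndarray, MappingResult]:
    """Project ``query`` with the frozen transform and map it."""
    q_emb = atlas.embedding_model.transform(query)
    mapper = ReferenceMapper(n_neighbors=n_neighbors, random_state=seed).fit(
        atlas.corrected_embedding, atlas.labels, ref_cell_ids=atlas.cell_ids,
    )
    return q_emb, mapper.predict(q_emb, query_cell_ids=query.cell_ids)
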