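"""Pseudobulk aggregation: per-(sample, cell type) mean expression with
eligibility filters, plus study-effect removal at the pseudobulk level.

Eligibility follows the screening rules: a cell type enters the analysis
only if it appears with at least ``min_cells`` cells in at least
``min_samples`` samples, and within a cell type only genes detected in
more than ``detect_fraction`` of that type's cells are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import CellDataset


@dataclass
class PseudobulkTable:
    """(sample, cell type) x gene mean expression plus eligibility."""

    values: pd.DataFrame                  # MultiIndex (sample_id, cell_type)
    cells_per_entry: pd.Series            # same index, cell counts
    eligible_cell_types: List[str]
    eligible_genes: Dict[str, List[str]]
    min_cells: int = 20

    def entries_for(self, cell_type: str, require_min_cells: bool = True
                    ) -> pd.DataFrame:
        """Rows (samples) for one cell type, restricted to entries with
        at least ``min_cells`` cells when ``require_min_cells``."""
        sub = self.values.xs(cell_type, level="cell_type")
        if require_min_cells:
            n = self.cells_per_entry.xs(cell_type, level="cell_type")
            sub = sub.loc[n[n >= self.min_cells].index]
        return sub

    def subset_samples(self, sample_ids: Sequence[str]) -> "PseudobulkTable":
        keep = self.values.index.get_level_values("sample_id").isin(sample_ids)
        return PseudobulkTable(
            values=self.values.loc[keep],
            cells_per_entry=self.cells_per_entry.loc[keep],
            eligible_cell_types=list(self.eligible_cell_types),
            eligible_genes={k: list(v) for k, v in self.eligible_genes.items()},
            min_cells=self.min_cells,
        )


def pseudobulk(ds: CellDataset, labels: Optional[Dict] = None,
               min_cells: int = 20, min_samples: int = 20,
               detect_fraction: float = 0.10,
               min_cells_mode: str = "per_sample",
               layer: str = "normalized") -> PseudobulkTable:
    """Average expression of each cell type in each sample.

    ``min_cells_mode='per_sample'`` (default): a sample supports a cell
    type only when it holds >= ``min_cells`` cells of it, and the type is
    eligible when >= ``min_samples`` samples support it.  With
    ``'total'``, the cell count is pooled over all samples instead.
    Gene eligibility (> ``detect_fraction`` of the type's cells with a
    nonzero count, strict) is evaluated per cell type on the count
    matrix.
    """
    if layer == "normalized":
        if ds.normalized is None:
            raise ValueError("pseudobulk requires normalized expression")
        mat = ds.normalized.tocsc()
    elif layer == "counts":
        mat = ds.counts.tocsc().astype(float)
    else:
        raise ValueError("layer must be 'normalized' or 'counts'")

    cell_labels = (
        np.array([labels[c] for c in ds.cell_ids])
        if labels is not None
        else ds.cell_table["label"].to_numpy()
    )
    sample_ids = ds.cell_table["sample_id"].to_numpy()
    detected = ds.counts.tocsc() > 0

    rows, index, n_cells = [], [], []
    for (sid, ct), cols in pd.DataFrame(
        {"sample_id": sample_ids, "cell_type": cell_labels}
    ).groupby(["sample_id", "cell_type"], sort=True).groups.items():
        cols = np.asarray(cols)
        rows.append(np.asarray(mat[:, cols].mean(axis=1)).ravel())
        index.append((sid, ct))
        n_cells.append(len(cols))
    if not rows:
        warnings.warn("no (sample, cell type) entries; empty pseudobulk")
        empty = pd.DataFrame(
            columns=ds.gene_ids,
            index=pd.MultiIndex.from_tuples([], names=["sample_id", "cell_type"]),
        )
        return PseudobulkTable(empty, pd.Series(dtype=int), [], {}, min_cells)

    midx = pd.MultiIndex.from_tuples(index, names=["sample_id", "cell_type"])
    values = pd.DataFrame(np.vstack(rows), index=midx, columns=ds.gene_ids)
    cells_per_entry = pd.Series(n_cells, index=midx, name="n_cells")

    eligible_types, eligible_genes = [], {}
    for ct in sorted(set(cell_labels)):
        n = cells_per_entry.xs(ct, level="cell_type")
        if min_cells_mode == "per_sample":
            ok = (n >= min_cells).sum() >= min_samples
        elif min_cells_mode == "total":
            ok = (n.sum() >= min_cells) and (len(n) >= min_samples)
        else:
            raise ValueError("min_cells_mode must be 'per_sample' or 'total'")
        if not ok:
            continue
        eligible_types.append(ct)
        mask = cell_labels == ct
        frac = np.asarray(detected[:, mask].mean(axis=1)).ravel()
        eligible_genes[ct] = list(ds.gene_ids[frac > detect_fraction])
    if not eligible_types:
        warnings.warn("no eligible cell types after pseudobulk filters")
    return PseudobulkTable(values, cells_per_entry, eligible_types,
                           eligible_genes, min_cells)


def remove_study_effects(pb: PseudobulkTable, sample_table: pd.DataFrame
                         ) -> PseudobulkTable:
    """Remove additive per-study effects from pseudobulk values.

    Per cell type and gene, fits value ~ intercept + age + study
    (sum-to-zero study contrasts, age protected) by least squares and
    subtracts the fitted study component — the usual removeBatchEffect
    construction, applied at the pseudobulk level where this pipeline's
    per-gene batch estimates live.
    """
    meta = sample_table.set_index("sample_id")
    corrected = pb.values.copy()
    for ct in corrected.index.get_level_values("cell_type").unique():
        mask = corrected.index.get_level_values("cell_type") == ct
        sub = corrected.loc[mask]
        samples = sub.index.get_level_values("sample_id")
        study = meta.loc[samples, "study_id"].astype(str).to_numpy()
        levels = sorted(set(study))
        if len(levels) < 2:
            continue
        age = meta.loc[samples, "age_years"].to_numpy(dtype=float)
        age = np.where(np.isnan(age), np.nanmean(age), age)
        n = len(sub)
        # design: intercept + age + sum-coded study dummies
        D = np.zeros((n, len(levels) - 1))
        for j, lev in enumerate(levels[:-1]):
            D[study == lev, j] = 1.0
            D[study == levels[-1], j] = -1.0
        X = np.column_stack([np.ones(n), age, D])
        beta, *_ = np.linalg.lstsq(X, sub.to_numpy(), rcond=None)
        corrected.loc[mask] = sub.to_numpy() - D @ beta[2:]
    return PseudobulkTable(
        values=corrected,
        cells_per_entry=pb.cells_per_entry.copy(),
        eligible_cell_types=list(pb.eligible_cell_types),
        eligible_genes={k: list(v) for k, v in pb.eligible_genes.items()},
        min_cells=pb.min_cells,
    )
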