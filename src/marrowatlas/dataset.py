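"""Multi-sample single-cell count data container and on-disk format.

A :class:`CellDataset` holds a sparse genes x cells count matrix together
with three aligned annotation tables (cells, genes, samples).  On disk a
dataset is a directory with ``matrix.mtx`` (Matrix Market coordinate,
genes x cells, integer counts), ``cells.tsv``, ``genes.tsv`` and
``samples.tsv``; an optional ``normalized.mtx`` carries log-normalised
expression aligned to the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class DatasetFormatError(ValueError):
    """Raised when on-disk files are missing or mutually inconsistent."""


MITO_PREFIXES = ("MT-",)
RIBO_PREFIXES = ("RPL", "RPS")


def _as_csr(m) -> sp.csr_matrix:
    return sp.csr_matrix(m)


@dataclass
class CellDataset:
    """Sparse counts plus aligned cell / gene / sample annotation tables.

    Parameters
    ----------
    counts : scipy.sparse matrix, genes x cells
        Nonnegative integer UMI counts.
    cell_table : DataFrame with columns ``cell_id``, ``sample_id``,
        ``study_id`` and optionally ``label``.
    gene_table : DataFrame with columns ``gene_id``, ``symbol`` and
        optionally boolean ``mito`` / ``ribo`` flags (inferred from symbol
        prefixes when absent).
    sample_table : DataFrame with columns ``sample_id``, ``study_id`` and
        optionally ``age_years``, ``sex``, ``sorted``.
    normalized : optional sparse matrix aligned to ``counts`` holding
        log-normalised expression (see :func:`marrowatlas.qc.normalize_total`).
    """

    counts: sp.spmatrix
    cell_table: pd.DataFrame
    gene_table: pd.DataFrame
    sample_table: pd.DataFrame
    normalized: Optional[sp.spmatrix] = None

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        if self.normalized is not None:
            self.normalized = _as_csr(self.normalized)
        self.cell_table = self.cell_table.reset_index(drop=True)
        self.gene_table = self.gene_table.reset_index(drop=True)
        self.sample_table = self.sample_table.reset_index(drop=True)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.cell_table) != n_cells:
            raise DatasetFormatError(
                f"matrix has {n_cells} columns but cells table has "
                f"{len(self.cell_table)} rows"
            )
        if len(self.gene_table) != n_genes:
            raise DatasetFormatError(
                f"matrix has {n_genes} rows but genes table has "
                f"{len(self.gene_table)} rows"
            )
        missing = set(self.cell_table["sample_id"]) - set(
            self.sample_table["sample_id"]
        )
        if missing:
            raise DatasetFormatError(
                f"cells reference samples absent from samples table: "
                f"{sorted(missing)[:5]}"
            )
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise DatasetFormatError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise DatasetFormatError("counts contain non-integral entries")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise DatasetFormatError("normalized matrix shape differs from counts")

    # -- basic accessors ----------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_table["gene_id"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_table["cell_id"].to_numpy()

    def gene_flags(self, kind: str) -> np.ndarray:
        """Boolean per-gene flag for ``kind`` in {'mito', 'ribo'}.

        Uses an explicit boolean column in ``gene_table`` when present,
        otherwise falls back to symbol-prefix matching (MT- / RPL / RPS).
        """
        if kind in self.gene_table.columns:
            return self.gene_table[kind].to_numpy(dtype=bool)
        prefixes = MITO_PREFIXES if kind == "mito" else RIBO_PREFIXES
        symbols = self.gene_table["symbol"].astype(str)
        return symbols.str.upper().str.startswith(prefixes).to_numpy()

    # -- per-cell QC metrics ------------------------------------------
    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def fraction_per_cell(self, kind: str) -> np.ndarray:
        flags = self.gene_flags(kind)
        total = self.umi_per_cell()
        sub = np.asarray(self.counts[flags].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, sub / np.maximum(total, 1), 0.0)
        return frac

    # -- subsetting ----------------------------------------------------
    def subset_cells(self, mask: np.ndarray, drop_empty_samples: bool = False
                     ) -> "CellDataset":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_cells, dtype=bool)
            idx[mask] = True
            mask = idx
        cell_table = self.cell_table.loc[mask].reset_index(drop=True)
        sample_table = self.sample_table
        if drop_empty_samples:
            keep = sample_table["sample_id"].isin(cell_table["sample_id"])
            sample_table = sample_table.loc[keep].reset_index(drop=True)
        return CellDataset(
            counts=self.counts[:, mask],
            cell_table=cell_table,
            gene_table=self.gene_table.copy(),
            sample_table=sample_table.copy(),
            normalized=None if self.normalized is None else self.normalized[:, mask],
        )

    def subset_genes(self, mask: np.ndarray) -> "CellDataset":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_genes, dtype=bool)
            idx[mask] = True
            mask = idx
        return CellDataset(
            counts=self.counts[mask],
            cell_table=self.cell_table.copy(),
            gene_table=self.gene_table.loc[mask].reset_index(drop=True),
            sample_table=self.sample_table.copy(),
            normalized=None if self.normalized is None else self.normalized[mask],
        )

    # -- equality (used for round-trip and determinism checks) --------
    def equals(self, other: "CellDataset") -> bool:
        if self.counts.shape != other.counts.shape:
            return False
        if (self.counts != other.counts).nnz:
            return False
        for a, b in (
            (self.cell_table, other.cell_table),
            (self.gene_table, other.gene_table),
            (self.sample_table, other.sample_table),
        ):
            if list(a.columns) != list(b.columns) or not a.equals(b):
                return False
        if (self.normalized is None) != (other.normalized is None):
            return False
        if self.normalized is not None:
            if abs(self.normalized - other.normalized).max() > 1e-12:
                return False
        return True

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes) for interop."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_table.set_index("cell_id"),
            var=self.gene_table.set_index("gene_id"),
        )
        if self.normalized is not None:
            adata.layers["normalized"] = self.normalized.T.tocsr()
        meta = self.sample_table.set_index("sample_id")
        for col in meta.columns:
            adata.obs[f"sample_{col}"] = (
                adata.obs["sample_id"].map(meta[col]).to_numpy()
            )
        return adata


# ---------------------------------------------------------------------
# directory I/O
# ---------------------------------------------------------------------

_REQUIRED = ("matrix.mtx", "cells.tsv", "genes.tsv", "samples.tsv")


def write_dataset(ds: CellDataset, path) -> None:
    """Write ``ds`` to ``path`` as matrix.mtx + three TSV tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = ds.counts.tocoo()
    mmwrite(str(path / "matrix.mtx"), counts, field="integer")
    ds.cell_table.to_csv(path / "cells.tsv", sep="\t", index=False)
    ds.gene_table.to_csv(path / "genes.tsv", sep="\t", index=False)
    ds.sample_table.to_csv(path / "samples.tsv", sep="\t", index=False)
    if ds.normalized is not None:
        mmwrite(str(path / "normalized.mtx"), ds.normalized.tocoo())


def read_dataset(path) -> CellDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    for name in _REQUIRED:
        if not (path / name).exists():
            raise DatasetFormatError(f"missing required file: {path / name}")
    counts = sp.csr_matrix(mmread(str(path / "matrix.mtx")))
    cell_table = pd.read_csv(path / "cells.tsv", sep="\t",
                             float_precision="round_trip")
    gene_table = pd.read_csv(path / "genes.tsv", sep="\t",
                             float_precision="round_trip")
    sample_table = pd.read_csv(path / "samples.tsv", sep="\t",
                               float_precision="round_trip")
    normalized = None
    if (path / "normalized.mtx").exists():
        normalized = sp.csr_matrix(mmread(str(path / "normalized.mtx")))
    try:
        return CellDataset(counts, cell_table, gene_table, sample_table, normalized)
    except DatasetFormatError as err:
        raise DatasetFormatError(f"{path}: {err}") from err
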