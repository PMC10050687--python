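"""Cell-level quality control and total-count log normalisation.

QC removes cells outside configured bounds on UMI count, detected genes,
and mitochondrial / ribosomal fractions, then drops whole samples that
retain fewer than ``min_cells_per_sample`` cells (default 200).  Real
datasets come from heterogeneous experiments, so no universal numeric
cut-offs exist; thresholds are explicit configuration, with an optional
per-sample adaptive rule (median +/- k*MAD on log-scale metrics).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import CellDataset

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised for invalid threshold or generator configuration."""


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell bounds plus the minimum surviving cells per sample.

    ``None`` upper bounds mean unbounded.  Defaults follow common
    single-cell practice: at least 200 detected genes, at most 20%
    mitochondrial reads, and whole samples dropped below 200 cells.
    """

    min_umi: int = 0
    max_umi: Optional[int] = None
    min_genes: int = 200
    max_genes: Optional[int] = None
    max_mito_fraction: float = 0.2
    max_ribo_fraction: float = 1.0
    min_cells_per_sample: int = 200

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_umi, self.max_umi, "umi"),
            (self.min_genes, self.max_genes, "genes"),
        ):
            if hi is not None and lo > hi:
                raise ConfigurationError(f"min_{name} > max_{name}")
        for frac, name in (
            (self.max_mito_fraction, "max_mito_fraction"),
            (self.max_ribo_fraction, "max_ribo_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.min_cells_per_sample < 0:
            raise ConfigurationError("min_cells_per_sample must be >= 0")


# removal reasons, in the order they are attributed to a failing cell
_REASONS = (
    "low_umi",
    "high_umi",
    "low_genes",
    "high_genes",
    "high_mito",
    "high_ribo",
    "small_sample",
)


@dataclass
class QCReport:
    """Per-sample retention and per-cell removal reasons."""

    per_sample: pd.DataFrame
    cell_reasons: pd.Series  # index: removed cell_id, value: reason
    dropped_samples: list
    warning: Optional[str] = None

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


def qc_filter(ds: CellDataset, thr: QCThresholds = QCThresholds()
              ) -> tuple[CellDataset, QCReport]:
    """Apply per-cell bounds, then drop under-sized samples.

    Each removed cell is attributed a single reason (first failing bound
    in a fixed order), so reasons partition the removed set.  Thresholds
    that remove every cell yield an empty dataset with a report warning,
    not an error.
    """
    umi = ds.umi_per_cell()
    genes = ds.genes_per_cell()
    mito = ds.fraction_per_cell("mito")
    ribo = ds.fraction_per_cell("ribo")

    max_umi = np.inf if thr.max_umi is None else thr.max_umi
    max_genes = np.inf if thr.max_genes is None else thr.max_genes
    fails = {
        "low_umi": umi < thr.min_umi,
        "high_umi": umi > max_umi,
        "low_genes": genes < thr.min_genes,
        "high_genes": genes > max_genes,
        "high_mito": mito > thr.max_mito_fraction,
        "high_ribo": ribo > thr.max_ribo_fraction,
    }
    keep = np.ones(ds.n_cells, dtype=bool)
    reason = np.full(ds.n_cells, "", dtype=object)
    for name in _REASONS[:-1]:
        bad = fails[name] & keep
        reason[bad] = name
        keep &= ~fails[name]

    # whole-sample rule: samples with fewer than min_cells_per_sample
    # surviving cells are removed entirely
    sample_ids = ds.cell_table["sample_id"].to_numpy()
    surviving = pd.Series(sample_ids[keep]).value_counts()
    dropped_samples = sorted(
        s for s in ds.sample_table["sample_id"]
        if surviving.get(s, 0) < thr.min_cells_per_sample
    )
    small = np.isin(sample_ids, dropped_samples) & keep
    reason[small] = "small_sample"
    keep &= ~small

    before = pd.Series(sample_ids).value_counts()
    after = pd.Series(sample_ids[keep]).value_counts()
    per_sample = pd.DataFrame(
        {
            "sample_id": ds.sample_table["sample_id"],
            "cells_before": ds.sample_table["sample_id"].map(before).fillna(0).astype(int),
            "cells_after": ds.sample_table["sample_id"].map(after).fillna(0).astype(int),
        }
    )
    per_sample["dropped"] = per_sample["sample_id"].isin(dropped_samples)

    removed_ids = ds.cell_ids[~keep]
    cell_reasons = pd.Series(reason[~keep], index=removed_ids, name="reason")

    warning = None
    if not keep.any():
        warning = "all cells removed by QC thresholds"
        warnings.warn(warning)

    out = ds.subset_cells(keep)
    out.sample_table = out.sample_table[
        ~out.sample_table["sample_id"].isin(dropped_samples)
    ].reset_index(drop=True)
    for _, row in per_sample.iterrows():
        logger.info(
            "QC sample %s: %d -> %d cells%s",
            row.sample_id, row.cells_before, row.cells_after,
            " (dropped)" if row.dropped else "",
        )
    return out, QCReport(per_sample, cell_reasons, dropped_samples, warning)


def adaptive_thresholds(ds: CellDataset, n_mads: float = 3.0,
                        base: QCThresholds = QCThresholds()
                        ) -> Dict[str, QCThresholds]:
    """Per-sample thresholds at median +/- ``n_mads`` MADs of log1p(UMI)
    and log1p(genes); mito/ribo bounds and the sample-size rule come from
    ``base``.  Returns a mapping sample_id -> QCThresholds.
    """
    umi = np.log1p(ds.umi_per_cell())
    genes = np.log1p(ds.genes_per_cell())
    sample_ids = ds.cell_table["sample_id"].to_numpy()
    out: Dict[str, QCThresholds] = {}
    for sid in ds.sample_table["sample_id"]:
        m = sample_ids == sid
        if not m.any():
            out[sid] = base
            continue
        bounds = []
        for x in (umi[m], genes[m]):
            med = np.median(x)
            mad = np.median(np.abs(x - med)) * 1.4826
            bounds.append(
                (math.floor(np.expm1(med - n_mads * mad)),
                 math.ceil(np.expm1(med + n_mads * mad)))
            )
        out[sid] = QCThresholds(
            min_umi=max(0, bounds[0][0]), max_umi=bounds[0][1],
            min_genes=max(0, bounds[1][0]), max_genes=bounds[1][1],
            max_mito_fraction=base.max_mito_fraction,
            max_ribo_fraction=base.max_ribo_fraction,
            min_cells_per_sample=base.min_cells_per_sample,
        )
    return out


def normalize_total(ds: CellDataset, scale_factor: float = 1e4) -> CellDataset:
    """Total-count normalise and log-transform.

    normalized[g, c] = log(1 + counts[g, c] / total[c] * scale_factor).
    Zero-total cells are a QC failure, not a normalisation case.
    Returns a new dataset with ``normalized`` set; zero pattern is
    preserved.
    """
    if scale_factor <= 0:
        raise ConfigurationError("scale_factor must be positive")
    total = ds.umi_per_cell().astype(float)
    if ds.n_cells and (total == 0).any():
        raise ValueError(
            "dataset contains zero-total cells; run qc_filter before "
            "normalize_total"
        )
    norm = ds.counts.tocsc().astype(float)
    if ds.n_cells:
        # scale each column (cell) by scale_factor / total, then log1p
        scale = scale_factor / total
        norm = norm @ sp.diags(scale)
        norm.data = np.log1p(norm.data)
    return CellDataset(
        counts=ds.counts,
        cell_table=ds.cell_table.copy(),
        gene_table=ds.gene_table.copy(),
        sample_table=ds.sample_table.copy(),
        normalized=norm.tocsr(),
    )
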