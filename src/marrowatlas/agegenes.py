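"""Cell-type-specific age-correlated genes and local over-representation
analysis.

For each eligible cell type, pseudobulk expression of each eligible gene
is correlated with donor age (Pearson); two-sided p-values come from the
t-distribution with n-2 degrees of freedom, and genes with p below the
threshold (default 0.01) are retained as age genes.  Over-representation
against user-supplied gene sets (GMT) uses the hypergeometric upper tail
with BH adjustment.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

from ._stats import bh_adjust
from .pseudobulk import PseudobulkTable

AGE_GENE_COLUMNS = ["cell_type", "gene_id", "pearson_r", "p", "direction"]


def _pearson_with_age(X: np.ndarray, age: np.ndarray):
    """Vectorised Pearson r and two-sided t-test p for each column of X."""
    n = len(age)
    xc = X - X.mean(axis=0)
    ac = age - age.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sa = np.sqrt((ac**2).sum())
    zero_var = sx == 0
    denom = np.where(zero_var, 1.0, sx * sa)
    r = (xc * ac[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(t), df=n - 2)
    return r, np.clip(p, 0.0, 1.0), zero_var


def age_correlation(pb: PseudobulkTable, ages: Mapping[str, float],
                    p_threshold: float = 0.01, min_samples: int = 3,
                    keep_all: bool = False) -> pd.DataFrame:
    """Age-correlated genes per eligible cell type.

    ``ages`` maps sample_id -> years.  Only pseudobulk entries meeting
    the per-entry cell minimum contribute.  Returns the retained rows
    (p < ``p_threshold``) unless ``keep_all``; zero-variance genes are
    skipped with a warning.
    """
    rows = []
    for ct in pb.eligible_cell_types:
        sub = pb.entries_for(ct)
        samples = [s for s in sub.index if s in ages and pd.notna(ages[s])]
        if len(samples) < min_samples:
            warnings.warn(f"cell type {ct!r}: fewer than {min_samples} aged "
                          "samples; skipped")
            continue
        genes = pb.eligible_genes.get(ct, [])
        if not genes:
            continue
        X = sub.loc[samples, genes].to_numpy(dtype=float)
        age = np.array([ages[s] for s in samples], dtype=float)
        r, p, zero_var = _pearson_with_age(X, age)
        if zero_var.any():
            warnings.warn(
                f"cell type {ct!r}: {int(zero_var.sum())} zero-variance "
                "genes skipped"
            )
        for j, g in enumerate(genes):
            if zero_var[j]:
                continue
            if keep_all or p[j] < p_threshold:
                rows.append((ct, g, float(r[j]), float(p[j]),
                             "up" if r[j] >= 0 else "down"))
    out = pd.DataFrame(rows, columns=AGE_GENE_COLUMNS)
    if not keep_all:
        out = out[out["p"] < p_threshold].reset_index(drop=True)
    return out


def shared_gene_summary(age_gene_table: pd.DataFrame) -> pd.DataFrame:
    """Per gene: number of cell types retaining it + direction consistency."""
    if age_gene_table.empty:
        raise ValueError("shared_gene_summary requires a non-empty table")
    grp = age_gene_table.groupby("gene_id")
    out = pd.DataFrame({
        "n_cell_types": grp.size(),
        "direction_consistent": grp["direction"].agg(lambda s: s.nunique() == 1),
    }).reset_index()
    return out.sort_values(["n_cell_types", "gene_id"],
                           ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------

def read_gmt(path) -> Dict[str, Set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + sorted(set(genes))) + "\n")


def ora_enrichment(hits: Iterable[str], gene_sets: Mapping[str, Iterable[str]],
                   universe: Iterable[str], adj_threshold: float = 0.01
                   ) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    All sets are intersected with the universe; p is the upper-tail
    probability of an overlap at least as large as observed, BH-adjusted
    across sets; rows with adjusted p < ``adj_threshold`` are flagged.
    """
    universe = set(universe)
    hits = set(hits)
    outside = hits - universe
    if outside:
        raise ValueError(
            f"hit genes absent from universe: {sorted(outside)[:10]}"
        )
    if not gene_sets:
        raise ValueError("gene_sets must be non-empty")
    M, n = len(universe), len(hits)
    rows = []
    for name, genes in gene_sets.items():
        gset = set(genes) & universe
        K = len(gset)
        k = len(gset & hits)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < adj_threshold
    return out.sort_values("p", kind="stable").reset_index(drop=True)
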