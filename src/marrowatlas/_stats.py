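"""Small shared statistical helpers (rank-sum DE core, BH adjustment)."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in raw p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def group_log_fold_change(norm_a: sp.spmatrix, norm_b: sp.spmatrix,
                          pseudocount: float = 1.0) -> np.ndarray:
    """Natural-log fold change between two groups of cells.

    Means are taken on the de-logged (expm1) normalised scale with a
    pseudocount: lfc = ln((mean expm1 a + 1) / (mean expm1 b + 1)).
    """
    def mean_expm1(m):
        m = m.copy()
        m.data = np.expm1(m.data)
        return np.asarray(m.mean(axis=1)).ravel()

    a = mean_expm1(norm_a)
    b = mean_expm1(norm_b)
    return np.log((a + pseudocount) / (b + pseudocount))


def rank_sum_de(norm_a: sp.spmatrix, norm_b: sp.spmatrix) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene between cell groups a and b.

    Genes with identical values across both groups get p = 1 (no signal).
    Matrices are genes x cells on the normalised scale.
    """
    A = norm_a.toarray() if sp.issparse(norm_a) else np.asarray(norm_a)
    B = norm_b.toarray() if sp.issparse(norm_b) else np.asarray(norm_b)
    p = np.ones(A.shape[0])
    both = np.concatenate([A, B], axis=1)
    varying = np.ptp(both, axis=1) > 0
    if varying.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = mannwhitneyu(A[varying], B[varying], axis=1,
                               alternative="two-sided")
        pv = np.asarray(res.pvalue, dtype=float)
        pv = np.where(np.isnan(pv), 1.0, pv)
        p[varying] = np.clip(pv, 0.0, 1.0)
    return p
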