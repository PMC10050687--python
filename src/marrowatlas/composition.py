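"""Cell-type composition trends with age.

Per-sample cell-type proportions are regressed on donor age with study
as a categorical covariate:

    x_j = intercept + beta_age * Age_j + sum_s beta_study[s] * 1[study_j = s]

The combined evidence is the two-sided t-test on the age coefficient;
per-study Spearman correlations are reported alongside, and a Fisher
combination of the per-study Spearman p-values is optional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import combine_pvalues, spearmanr

from ._stats import bh_adjust
from .dataset import CellDataset


@dataclass
class CompositionResult:
    cell_type: str
    beta_age: float
    p_overall: float
    beta_project: Dict[str, float]
    per_study: pd.DataFrame       # study, n, spearman_rho, spearman_p
    n_samples: int
    fisher_p: Optional[float] = None


def sample_proportions(ds: CellDataset = None, labels: Dict = None,
                       unsorted_only: bool = False,
                       cell_table: pd.DataFrame = None) -> pd.DataFrame:
    """Per-sample cell-type proportions (rows sum to 1).

    ``labels`` maps cell_id -> cell type; defaults to the ``label``
    column of the cell table.  With ``unsorted_only`` samples flagged
    ``sorted`` in the sample table are excluded (sorting distorts
    composition).  Samples with zero cells are excluded with a warning.
    """
    if cell_table is None:
        cell_table = ds.cell_table
    df = cell_table[["cell_id", "sample_id"]].copy()
    if labels is not None:
        df["label"] = df["cell_id"].map(labels)
        if df["label"].isna().any():
            raise ValueError("labels must cover all cells of included samples")
    else:
        if "label" not in cell_table.columns:
            raise ValueError("no labels given and cell table has no 'label'")
        df["label"] = cell_table["label"].to_numpy()
    if unsorted_only and ds is not None and "sorted" in ds.sample_table.columns:
        keep = set(ds.sample_table.loc[~ds.sample_table["sorted"].astype(bool),
                                       "sample_id"])
        df = df[df["sample_id"].isin(keep)]
    counts = pd.crosstab(df["sample_id"], df["label"])
    if ds is not None:
        empty = set(ds.sample_table["sample_id"]) - set(counts.index)
        if empty and not unsorted_only:
            warnings.warn(f"samples with zero cells excluded: {sorted(empty)}")
    props = counts.div(counts.sum(axis=1), axis=0)
    props.index.name = "sample_id"
    props.columns.name = "cell_type"
    return props


def trend_test(proportions: pd.DataFrame, sample_table: pd.DataFrame,
               cell_type: str, transform: str = "identity",
               min_study_n: int = 3, fisher: bool = False
               ) -> CompositionResult:
    """Age trend of one cell type's proportion, with study covariates.

    OLS of the proportion on age plus study indicator covariates (with
    intercept; reference level = first study alphabetically).  p_overall
    is the two-sided t-test on the age coefficient.  Per-study Spearman
    rho/p are computed for studies with >= ``min_study_n`` samples.
    """
    if cell_type not in proportions.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    meta = sample_table.set_index("sample_id")
    samples = [s for s in proportions.index
               if s in meta.index and pd.notna(meta.loc[s, "age_years"])]
    if len(samples) < 3:
        raise ValueError("trend_test requires >= 3 samples with age")
    y = proportions.loc[samples, cell_type].to_numpy(dtype=float)
    if transform == "logit":
        eps = 1e-6
        y = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))
    elif transform != "identity":
        raise ValueError("transform must be 'identity' or 'logit'")
    age = meta.loc[samples, "age_years"].to_numpy(dtype=float)
    study = meta.loc[samples, "study_id"].astype(str).to_numpy()
    if np.ptp(age) == 0:
        raise ValueError("degenerate design: all sample ages identical")

    levels = sorted(set(study))
    X = pd.DataFrame({"age": age}, index=samples)
    for lev in levels[1:]:
        X[f"study[{lev}]"] = (study == lev).astype(float)
    X = sm.add_constant(X)

    if np.ptp(y) == 0:
        # constant response: zero slope, no evidence against the null
        beta_age, p_overall = 0.0, 1.0
        beta_project = {lev: 0.0 for lev in levels[1:]}
    else:
        fit = sm.OLS(y, X).fit()
        beta_age = float(fit.params["age"])
        p_overall = float(fit.pvalues["age"])
        beta_project = {
            lev: float(fit.params[f"study[{lev}]"]) for lev in levels[1:]
        }

    rows = []
    for lev in levels:
        m = study == lev
        if m.sum() < min_study_n:
            continue
        rho, p = spearmanr(age[m], y[m])
        rows.append((lev, int(m.sum()), float(rho), float(p)))
    per_study = pd.DataFrame(
        rows, columns=["study", "n", "spearman_rho", "spearman_p"]
    )
    fisher_p = None
    if fisher and len(per_study):
        ps = per_study["spearman_p"].dropna()
        if len(ps):
            fisher_p = float(combine_pvalues(ps, method="fisher").pvalue)
    return CompositionResult(
        cell_type=cell_type, beta_age=beta_age, p_overall=p_overall,
        beta_project=beta_project, per_study=per_study,
        n_samples=len(samples), fisher_p=fisher_p,
    )


def trend_test_all(proportions: pd.DataFrame, sample_table: pd.DataFrame,
                   **kwargs) -> pd.DataFrame:
    """Run :func:`trend_test` for every cell type; BH-adjust p_overall."""
    rows = []
    for ct in proportions.columns:
        res = trend_test(proportions, sample_table, ct, **kwargs)
        rows.append({
            "cell_type": ct,
            "beta_age": res.beta_age,
            "p_overall": res.p_overall,
            "n_samples": res.n_samples,
            "fisher_p": res.fisher_p,
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_overall"].to_numpy())
    return out
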