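"""Per-cell-type elastic-net age clock with median aggregation.

One penalised linear model is trained per eligible cell type, using that
type's age-correlated genes as features on pseudobulk expression.  The
penalty strength (lambda) is chosen by k-fold cross-validated MSE over a
log-spaced path (100 values spanning four decades below lambda_max, the
glmnet convention), with an optional one-standard-error rule.  A sample's
predicted age is the median of its per-cell-type predictions (even
counts: mean of the two central values).  Predictions are reported
untransformed; negative predicted ages are flagged, not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold

from .pseudobulk import PseudobulkTable


@dataclass
class CellTypeClock:
    """Fitted model for one cell type (standardised-feature scale)."""

    genes: list
    coef: np.ndarray          # on the standardised-feature scale
    intercept: float
    lambda_: float
    l1_ratio: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    n_samples: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_means) / self.feature_sds
        return Z @ self.coef + self.intercept


def _lambda_path(Z: np.ndarray, yc: np.ndarray, l1_ratio: float,
                 n_lambdas: int, min_ratio: float) -> np.ndarray:
    n = len(yc)
    lam_max = np.abs(Z.T @ yc).max() / (n * max(l1_ratio, 1e-3))
    lam_max = max(lam_max, 1e-10)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio),
                       n_lambdas)


def _fit_enet(Z: np.ndarray, y: np.ndarray, lam: float, l1_ratio: float
              ) -> tuple[np.ndarray, float]:
    if lam == 0:
        ols = LinearRegression().fit(Z, y)
        return ols.coef_, float(ols.intercept_)
    en = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        en.fit(Z, y)
    return en.coef_, float(en.intercept_)


class AgeClock(BaseEstimator, RegressorMixin):
    """Per-cell-type elastic-net age predictor, aggregated by the median.

    Parameters
    ----------
    l1_ratio : L1/L2 mixing (glmnet's alpha), default 0.5.
    lambda_ : fixed penalty; ``None`` selects by cross-validation.
    n_lambdas, lambda_min_ratio : the lambda path (100 values over four
        decades below lambda_max by default).
    cv : number of folds for lambda selection (default 10).
    lambda_rule : 'min' (lowest CV MSE) or '1se'.
    random_state : seed for the CV fold shuffle.
    """

    def __init__(self, l1_ratio: float = 0.5, lambda_: Optional[float] = None,
                 n_lambdas: int = 100, lambda_min_ratio: float = 1e-4,
                 cv: int = 10, lambda_rule: str = "min",
                 random_state: Optional[int] = None):
        self.l1_ratio = l1_ratio
        self.lambda_ = lambda_
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.lambda_rule = lambda_rule
        self.random_state = random_state

    def fit(self, pb: PseudobulkTable, ages: Mapping[str, float],
            age_genes: Optional[pd.DataFrame] = None) -> "AgeClock":
        """Fit one model per eligible cell type.

        ``age_genes`` is an age-gene table (columns cell_type, gene_id);
        ``None`` uses all of each type's eligible genes.  Cell types with
        fewer aged samples than folds are skipped with a warning.
        """
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        self.models_: Dict[str, CellTypeClock] = {}
        for ct in pb.eligible_cell_types:
            if age_genes is not None:
                genes = list(
                    age_genes.loc[age_genes["cell_type"] == ct, "gene_id"]
                )
                genes = [g for g in genes if g in set(pb.eligible_genes.get(ct, []))]
            else:
                genes = list(pb.eligible_genes.get(ct, []))
            if not genes:
                warnings.warn(f"cell type {ct!r}: no feature genes; skipped")
                continue
            sub = pb.entries_for(ct)
            samples = [s for s in sub.index
                       if s in ages and pd.notna(ages[s])]
            if len(samples) < self.cv:
                warnings.warn(
                    f"cell type {ct!r}: {len(samples)} samples < {self.cv} "
                    "folds; skipped"
                )
                continue
            X = sub.loc[samples, genes].to_numpy(dtype=float)
            y = np.array([ages[s] for s in samples], dtype=float)
            means = X.mean(axis=0)
            sds = X.std(axis=0, ddof=0)
            sds = np.where(sds == 0, 1.0, sds)
            Z = (X - means) / sds
            lam = self.lambda_
            if lam is None:
                lam = self._select_lambda(Z, y)
            coef, intercept = _fit_enet(Z, y, lam, self.l1_ratio)
            self.models_[ct] = CellTypeClock(
                genes=genes, coef=coef, intercept=intercept, lambda_=float(lam),
                l1_ratio=self.l1_ratio, feature_means=means, feature_sds=sds,
                n_samples=len(samples),
            )
        if not self.models_:
            raise ValueError("no cell type could be fitted")
        return self

    def _select_lambda(self, Z: np.ndarray, y: np.ndarray) -> float:
        path = _lambda_path(Z, y - y.mean(), self.l1_ratio,
                            self.n_lambdas, self.lambda_min_ratio)
        kf = KFold(n_splits=self.cv, shuffle=True,
                   random_state=self.random_state)
        mse = np.zeros((self.cv, len(path)))
        for f, (tr, te) in enumerate(kf.split(Z)):
            for j, lam in enumerate(path):
                coef, b0 = _fit_enet(Z[tr], y[tr], lam, self.l1_ratio)
                pred = Z[te] @ coef + b0
                mse[f, j] = np.mean((pred - y[te]) ** 2)
        mean_mse = mse.mean(axis=0)
        j_min = int(np.argmin(mean_mse))
        if self.lambda_rule == "min":
            return float(path[j_min])
        se = mse[:, j_min].std(ddof=1) / np.sqrt(self.cv)
        ok = np.nonzero(mean_mse <= mean_mse[j_min] + se)[0]
        return float(path[ok.min()])  # path is decreasing: largest lambda

    # -- prediction ---------------------------------------------------
    def predict_table(self, pb: PseudobulkTable) -> pd.DataFrame:
        """Per-sample table: per-cell-type predictions, the median
        (``predicted_age``), ``n_cell_types_used`` and a negative-age
        flag."""
        if not hasattr(self, "models_"):
            raise ValueError("AgeClock is not fitted")
        overlap = [ct for ct in self.models_
                   if ct in set(pb.values.index.get_level_values("cell_type"))]
        if not overlap:
            raise ValueError("no cell type shared between model and pseudobulk")
        per_type: Dict[str, pd.Series] = {}
        for ct in overlap:
            model = self.models_[ct]
            sub = pb.entries_for(ct)
            X = sub.reindex(columns=model.genes, fill_value=0.0).to_numpy(float)
            per_type[ct] = pd.Series(model.predict(X), index=sub.index)
        table = pd.DataFrame(per_type)
        preds = table.median(axis=1, skipna=True)
        out = table.copy()
        out["predicted_age"] = preds
        out["n_cell_types_used"] = table.notna().sum(axis=1)
        out["negative_prediction"] = preds < 0
        out.index.name = "sample_id"
        return out[out["n_cell_types_used"] > 0]

    def predict(self, pb: PseudobulkTable) -> pd.Series:
        """Median predicted age per sample (years)."""
        return self.predict_table(pb)["predicted_age"]


def evaluate_clock(pb: PseudobulkTable, ages: Mapping[str, float],
                   age_genes: Optional[pd.DataFrame] = None,
                   n_folds: int = 10, random_state: Optional[int] = None,
                   **clock_params) -> dict:
    """Out-of-fold evaluation with sample-level folds.

    Folds are drawn over samples, so every cell type of a sample sits in
    the same fold and no sample contributes to its own prediction.
    Returns overall Pearson correlation and median absolute error plus
    the out-of-fold prediction table.
    """
    samples = sorted(
        {s for s in pb.values.index.get_level_values("sample_id")
         if s in ages and pd.notna(ages[s])}
    )
    if n_folds > len(samples):
        raise ValueError(f"n_folds={n_folds} exceeds {len(samples)} samples")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    samples = np.array(samples)
    oof = {}
    fold_stats = []
    for f, (tr, te) in enumerate(kf.split(samples)):
        clock = AgeClock(random_state=random_state, **clock_params)
        clock.fit(pb.subset_samples(samples[tr]), ages, age_genes=age_genes)
        preds = clock.predict(pb.subset_samples(samples[te]))
        for s, v in preds.items():
            oof[s] = float(v)
        fold_true = np.array([ages[s] for s in preds.index])
        fold_stats.append({
            "fold": f,
            "n": len(preds),
            "mae": float(np.median(np.abs(preds.to_numpy() - fold_true))),
        })
    pred = np.array([oof[s] for s in samples if s in oof])
    true = np.array([ages[s] for s in samples if s in oof])
    if len(pred) >= 2 and np.std(pred) > 0:
        r = float(pearsonr(pred, true).statistic)
    else:
        r = float("nan")
    return {
        "correlation": r,
        "median_abs_error": float(np.median(np.abs(pred - true))),
        "per_fold": pd.DataFrame(fold_stats),
        "predictions": pd.Series(oof, name="predicted_age"),
        "n_samples": int(len(pred)),
    }


def median_age(per_cell_type_ages: Mapping[str, float]) -> float:
    """Median of per-cell-type ages (even counts: mean of central two)."""
    values = np.array(list(per_cell_type_ages.values()), dtype=float)
    if values.size == 0:
        raise ValueError("no per-cell-type predictions")
    return float(np.median(values))
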