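"""Phenotype prediction from top-ranked k-mers with nested CV.

With ~13 strains and up to 1,000 k-mer features, plain least squares is
unidentifiable, so the regression is L1-regularized (lasso).  Outer
3-fold cross-validation estimates out-of-sample performance; for each
outer training set an inner CV picks the regularization strength from a
log-spaced grid.  Each strain lands in exactly one outer test fold.

The out-of-sample R^2 reported per fold is computed against the
*training-mean* baseline, 1 - sum (y_test - yhat)^2 / sum (y_test -
mean(y_train))^2: with a handful of strains per test fold the test-set
mean is a noisy (and occasionally degenerate) reference, whereas the
training mean is the prediction an interceptonly model would actually
make.  A null model then scores <= 0 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold

DEFAULT_ALPHA_GRID = tuple(np.logspace(-3, 1, 9))


@dataclass
class ModelSpec:
    top_n: int = 1000
    outer_folds: int = 3
    inner_folds: int = 3
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID
    max_iter: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if any(a <= 0 for a in self.alpha_grid):
            raise ValueError("regularization strengths must be positive")


@dataclass
class ModelReport:
    fold_metrics: pd.DataFrame          # per-outer-fold rows
    mean_metrics: dict[str, float]
    fold_assignment: pd.Series          # strain -> outer fold index
    coefficients: pd.Series             # final refit model
    intercept: float
    alpha: float                        # modal inner-selected strength
    fold_coefficients: list[pd.Series] = field(default_factory=list)

    def nonzero_features(self, tol: float = 1e-8) -> list[str]:
        c = self.coefficients
        return list(c.index[c.abs() > tol])


def select_top(table: pd.DataFrame, top_n: int = 1000) -> list[str]:
    """First min(top_n, len) k-mers of an association table already
    sorted by ascending p (ties by |t| then k-mer)."""
    if len(table) == 0:
        raise ValueError("association table is empty")
    return list(table["kmer"].iloc[:top_n])


def _r2_vs_train_mean(y_test, y_pred, train_mean):
    denom = float(np.sum((y_test - train_mean) ** 2))
    num = float(np.sum((y_test - y_pred) ** 2))
    if denom == 0:
        return 1.0 if num == 0 else float("nan")
    return 1.0 - num / denom


def nested_cv(features: pd.DataFrame, phenotype: pd.Series,
              spec: ModelSpec | None = None) -> ModelReport:
    """Nested cross-validation of a lasso phenotype model.

    ``features`` is the binary strain x k-mer presence matrix restricted
    to the selected features; ``phenotype`` is indexed by strain.
    """
    spec = spec or ModelSpec()
    strains = list(features.index)
    if len(strains) < spec.outer_folds:
        raise ValueError("fewer strains than outer folds")
    y = phenotype.reindex(strains).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some strain")
    X = features.to_numpy(dtype=float)
    constant = np.ptp(y) == 0
    if constant:
        warnings.warn("constant phenotype: R^2 and Spearman are undefined")

    outer = KFold(n_splits=spec.outer_folds, shuffle=True,
                  random_state=spec.seed)
    assignment = pd.Series(index=strains, dtype=int, name="fold")
    rows = []
    fold_coefs = []
    chosen_alphas = []
    for fold, (tr, te) in enumerate(outer.split(X)):
        assignment.iloc[te] = fold
        inner = KFold(n_splits=min(spec.inner_folds, len(tr)), shuffle=True,
                      random_state=spec.seed + 1)
        search = GridSearchCV(
            Lasso(max_iter=spec.max_iter),
            {"alpha": list(spec.alpha_grid)},
            cv=inner, scoring="neg_mean_squared_error")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X[tr], y[tr])
        best = search.best_estimator_
        alpha = float(search.best_params_["alpha"])
        chosen_alphas.append(alpha)
        y_pred = best.predict(X[te])
        mse = float(np.mean((y[te] - y_pred) ** 2))
        r2 = (float("nan") if constant else
              _r2_vs_train_mean(y[te], y_pred, float(np.mean(y[tr]))))
        if len(te) > 1 and np.ptp(y[te]) > 0 and np.ptp(y_pred) > 0:
            rho = float(spearmanr(y[te], y_pred).statistic)
        else:
            rho = float("nan")
        rows.append({"fold": fold, "n_test": len(te), "alpha": alpha,
                     "mse": mse, "r2": r2, "spearman": rho})
        fold_coefs.append(pd.Series(best.coef_, index=features.columns))
    fold_metrics = pd.DataFrame(rows).set_index("fold")
    mean_metrics = {
        "mse": float(fold_metrics["mse"].mean()),
        "r2": float(fold_metrics["r2"].mean()),
        "spearman": float(fold_metrics["spearman"].mean(skipna=True))
        if fold_metrics["spearman"].notna().any() else float("nan"),
    }
    # final refit with the modal inner-selected strength (ties -> smallest)
    vals, counts = np.unique(chosen_alphas, return_counts=True)
    alpha_final = float(vals[np.argmax(counts)])
    final = Lasso(alpha=alpha_final, max_iter=spec.max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return ModelReport(
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        fold_assignment=assignment,
        coefficients=pd.Series(final.coef_, index=features.columns),
        intercept=float(final.intercept_),
        alpha=alpha_final,
        fold_coefficients=fold_coefs)


def report_to_json(report: ModelReport) -> dict:
    return {
        "alpha": report.alpha,
        "intercept": report.intercept,
        "mean_metrics": report.mean_metrics,
        "fold_metrics": report.fold_metrics.reset_index().to_dict("records"),
        "nonzero_features": {
            k: float(v) for k, v in
            report.coefficients[report.coefficients.abs() > 1e-8].items()},
    }
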