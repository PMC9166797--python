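"""Hyperparameter tuning: tenfold cross-validated grid search on R-squared,
plus a lambda-path selector for the penalized linear models.

The grid search mirrors the usual protocol for these learners: the
derivation sample is split once into K approximately equal folds; every
grid point is fit on K-1 folds and scored on the held-out fold by the
squared Pearson correlation between observed and predicted outcome; the
point with the highest K-fold mean wins (ties go to the earliest point in
declared grid order). Folds are fixed once per search so all grid points
see identical splits.

``select_lambda`` reproduces the usual coordinate-descent-path procedure:
a 100-point log-spaced path from lambda_max (the smallest penalty at which
every lasso slope is zero; a scaled analog for ridge) down to 1e-4 times
lambda_max, scored by tenfold cross-validated MSE. The minimum-CV-MSE rule
is the default; the one-standard-error rule is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from ._rng import substream
from .cohort import CovariateTable
from .learners import LearnerSpec, fit_learner, predict

__all__ = [
    "FoldAssignment",
    "GridResult",
    "make_folds",
    "cv_r2",
    "grid_search",
    "default_grid",
    "select_lambda",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Per-subject fold labels 1..K from a seeded random permutation."""

    labels: np.ndarray
    K: int
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.labels, minlength=self.K + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than 1")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels != fold)


@dataclass(frozen=True)
class GridResult:
    """Per-point CV results of one grid search; ``selected`` is the winner."""

    specs: tuple[LearnerSpec, ...]
    mean_r2: np.ndarray
    fold_r2: np.ndarray  # shape (n_points, K)
    selected: int
    fold_hash: int

    @property
    def best_spec(self) -> LearnerSpec:
        return self.specs[self.selected]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, spec in enumerate(self.specs):
            row = {"method": spec.method, **spec.hyperparameters}
            row.update(
                {f"fold{j + 1}_r2": self.fold_r2[i, j] for j in range(self.fold_r2.shape[1])}
            )
            row["mean_cv_r2"] = self.mean_r2[i]
            row["selected"] = i == self.selected
            rows.append(row)
        return pd.DataFrame(rows)


def make_folds(n: int, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly split n subjects into K approximately equal folds."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K:
        raise ValueError(f"cannot split n={n} subjects into K={K} folds")
    rng = substream(seed, "folds", n, K)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    # first (n mod K) folds get the extra subject
    base, extra = divmod(n, K)
    start = 0
    for fold in range(1, K + 1):
        size = base + (1 if fold <= extra else 0)
        labels[perm[start : start + size]] = fold
        start += size
    return FoldAssignment(labels=labels, K=K, seed=seed)


def _r2_fold(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.ptp(y) == 0.0 or np.ptp(yhat) == 0.0:
        warnings.warn(
            "held-out fold has zero variance in outcome or predictions; "
            "recording fold R^2 as 0",
            stacklevel=3,
        )
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r**2)


def cv_r2(
    spec: LearnerSpec,
    X: CovariateTable | pd.DataFrame,
    y: Sequence[float],
    folds: FoldAssignment,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """K-fold cross-validated squared-Pearson R^2 for one spec.

    Returns (mean over folds, per-fold values).
    """
    Xdf = X.data if isinstance(X, CovariateTable) else pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(Xdf) != folds.labels.size:
        raise ValueError("fold assignment does not cover the data")
    vals = np.empty(folds.K)
    for fold in range(1, folds.K + 1):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        fitted = fit_learner(spec, Xdf.iloc[tr], y[tr], seed=seed)
        yhat = predict(fitted, Xdf.iloc[te])
        vals[fold - 1] = _r2_fold(y[te], yhat)
    return float(vals.mean()), vals


def default_grid(method: str, p: int | None = None) -> list[LearnerSpec]:
    """The documented default search grid for each tunable method."""
    if method == "nnet1":
        return [
            LearnerSpec("nnet1", {"hidden_units": H, "weight_decay": d})
            for H in range(2, 16)
            for d in (0.0, 0.01, 0.05, 0.1, 0.5)
        ]
    if method == "boosted_trees":
        return [
            LearnerSpec(
                "boosted_trees", {"interaction_depth": depth, "learning_rate": lr}
            )
            for depth in range(1, 6)
            for lr in (0.005, 0.01, 0.035, 0.065, 0.1)
        ]
    if method == "random_forest":
        if p is None:
            raise ValueError("random_forest grid needs the predictor count p")
        lo, hi = max(1, p // 6), max(1, p // 2)
        return [
            LearnerSpec("random_forest", {"mtry": m, "min_node_size": s})
            for m in range(lo, hi + 1)
            for s in (5, 10, 20, 50)
        ]
    if method == "ols_rcs":
        return [LearnerSpec("ols_rcs", {"knots": k}) for k in (3, 4, 5, 6)]
    raise ValueError(f"no default grid for method {method!r}")


def grid_search(
    grid: Sequence[LearnerSpec],
    X: CovariateTable | pd.DataFrame,
    y: Sequence[float],
    seed: int = 0,
    K: int = 10,
) -> GridResult:
    """Evaluate ``cv_r2`` at every grid point with folds fixed once.

    The winner maximizes mean CV R^2; ties break to the earliest point in
    the declared grid order.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    Xdf = X.data if isinstance(X, CovariateTable) else pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    folds = make_folds(len(Xdf), K=K, seed=seed)
    mean_r2 = np.empty(len(grid))
    fold_r2 = np.empty((len(grid), K))
    for i, spec in enumerate(grid):
        mean_r2[i], fold_r2[i] = cv_r2(spec, Xdf, y, folds, seed=seed)
    selected = int(np.argmax(mean_r2))  # argmax takes the first maximizer
    return GridResult(
        specs=tuple(grid),
        mean_r2=mean_r2,
        fold_r2=fold_r2,
        selected=selected,
        fold_hash=int(np.uint32(np.sum(folds.labels * np.arange(1, folds.labels.size + 1)))),
    )


def _lambda_path(Z: np.ndarray, yc: np.ndarray, method: str, n_points: int = 100) -> np.ndarray:
    n = len(yc)
    lam_max_lasso = float(np.max(np.abs(Z.T @ yc)) / n)
    if lam_max_lasso <= 0:
        raise ValueError("constant outcome: lambda path undefined")
    # ridge slopes never hit zero exactly; the conventional analog scales
    # the lasso entry point up by 1000
    lam_max = lam_max_lasso if method == "lasso" else 1000.0 * lam_max_lasso
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n_points)


def _ridge_path_coefs(Z: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Closed-form ridge coefficients for every lambda via one SVD."""
    n = len(yc)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    Uty = U.T @ yc
    # beta(lam) = V diag(s / (s^2 + n*lam)) U' y
    shrink = s[None, :] / (s[None, :] ** 2 + n * lams[:, None])
    return (shrink * Uty[None, :]) @ Vt


def select_lambda(
    method: str,
    X: CovariateTable | pd.DataFrame,
    y: Sequence[float],
    seed: int = 0,
    K: int = 10,
    one_se: bool = False,
) -> float:
    """Select the penalty for lasso/ridge by K-fold cross-validated MSE.

    Predictors are standardized to unit variance; the path has 100
    log-spaced points from lambda_max down to 1e-4 * lambda_max. Returns
    the minimum-CV-MSE lambda (or the one-SE lambda when ``one_se``).
    """
    if method not in ("lasso", "ridge"):
        raise ValueError("select_lambda applies to lasso or ridge only")
    Xdf = X.data if isinstance(X, CovariateTable) else pd.DataFrame(X)
    if Xdf.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    y = np.asarray(y, dtype=float)
    Xm = Xdf.to_numpy(dtype=float)
    center = Xm.mean(axis=0)
    scale = Xm.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (Xm - center) / scale
    yc = y - y.mean()
    lams = _lambda_path(Z, yc, method)

    folds = make_folds(len(y), K=K, seed=seed)
    sq_err = np.zeros((len(lams), len(y)))
    for fold in range(1, K + 1):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        # re-standardize within the training folds
        c = Xm[tr].mean(axis=0)
        s = Xm[tr].std(axis=0)
        s = np.where(s > 0, s, 1.0)
        Ztr, Zte = (Xm[tr] - c) / s, (Xm[te] - c) / s
        ybar = y[tr].mean()
        ytr = y[tr] - ybar
        if method == "lasso":
            _, coefs, _ = lasso_path(Ztr, ytr, alphas=lams, max_iter=10_000)
            coefs = coefs.T  # (n_lams, p)
        else:
            coefs = _ridge_path_coefs(Ztr, ytr, lams)
        preds = ybar + coefs @ Zte.T  # (n_lams, n_test)
        sq_err[:, te] = (preds - y[te][None, :]) ** 2
    cv_mse = sq_err.mean(axis=1)
    i_min = int(np.argmin(cv_mse))
    if not one_se:
        return float(lams[i_min])
    se = sq_err.std(axis=1, ddof=1) / np.sqrt(sq_err.shape[1])
    threshold = cv_mse[i_min] + se[i_min]
    # largest lambda (earliest on the descending path) within one SE
    within = np.flatnonzero(cv_mse <= threshold)
    return float(lams[within[0]])
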