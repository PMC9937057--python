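"""Two-stage transfer prediction: lasso pre-selection, then OLS refit, under
leave-one-out cross-validation.

With n between 9 and 12 participants per practice group and p = 8 curve
features, plain OLS is barely determined and pure lasso is biased; the
post-lasso two-stage estimator addresses both. For one group and one
target:

1. hold out each participant in turn (outer LOO);
2. inside the training fold, pick the penalty ``lambda*`` by an inner LOO
   over a log grid spanning ``[1e-3 * lambda_max, lambda_max]``, where
   ``lambda_max`` is the smallest penalty that zeroes every coefficient on
   that fold — the score minimized is the inner-LOO squared error of the
   full two-stage predictor, with ties broken toward the larger (sparser)
   penalty;
3. run lasso at ``lambda*`` on the standardized training fold (STEP 1),
   cap the surviving features at (training size - 2) — keeping the largest
   |coefficient|, ties to the lower column index — so the refit stays
   determined, then refit ordinary least squares with intercept on the
   selected raw columns (STEP 2); an empty selection falls back to the
   intercept-only model;
4. predict the held-out participant and record the squared error
   ``err_pr = (yhat - y)^2``.

Design and response are re-standardized inside every training fold (at both
nesting levels), so no scaling information leaks from a held-out sample
into its own prediction. The per-group result carries the error vector,
its median (the prediction-stability summary), and the feature-selection
indicators computed once on the group's full data by the same procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from . import _kernels
from .constants import FEATURE_COLUMNS, TARGET_METRICS

__all__ = [
    "TwoStageConfig",
    "FoldResult",
    "TwoStageResult",
    "lasso_select",
    "select_lambda",
    "refit_ols",
    "loo_two_stage",
    "selection_summary",
]

_CD_TOL = 1e-10
_CD_MAX_ITER = 100_000


@dataclass(frozen=True)
class TwoStageConfig:
    """Penalty-grid geometry for the inner lambda search."""

    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3

    def __post_init__(self):
        if self.n_lambdas < 1:
            raise ValueError("n_lambdas must be >= 1")
        if not 0 < self.lambda_min_ratio <= 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1]")


def _standardize_cols(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / safe
    Xs[:, sd == 0] = 0.0
    return Xs, mu, sd


def lambda_grid(X_train: np.ndarray, y_train: np.ndarray, config: TwoStageConfig) -> np.ndarray:
    """Log-spaced grid up to the smallest all-zeroing penalty on this fold."""
    Xs, _, _ = _standardize_cols(np.asarray(X_train, dtype=float))
    yc = np.asarray(y_train, dtype=float)
    yc = yc - yc.mean()
    n = len(yc)
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n) if n else 0.0
    lam_max = max(lam_max, 1e-12)
    if config.n_lambdas == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max * config.lambda_min_ratio, lam_max, config.n_lambdas)


def lasso_select(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """L1-penalized least squares; returns (support mask, coefficients).

    ``X`` is expected column-standardized on the fold at hand; ``y`` is
    centered internally (the intercept is unpenalized). The objective is
    ``1/(2n) ||y - Xb||^2 + lam ||b||_1`` solved by cyclic coordinate
    descent. Any ``lam >= lambda_max`` leaves the mask empty.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the lasso inputs")
    if lam <= 0:
        raise ValueError("lam must be positive")
    n = len(y)
    yc = y - y.mean()
    G = np.ascontiguousarray(X.T @ X / n)
    r = np.ascontiguousarray(X.T @ yc / n)
    beta = _kernels.cd_lasso(G, r, lam, _CD_TOL, _CD_MAX_ITER)
    return beta != 0.0, beta


def select_lambda(
    X_train: np.ndarray, y_train: np.ndarray, config: TwoStageConfig | None = None
) -> float:
    """Penalty minimizing the inner-LOO error of the two-stage predictor.

    Exact ties (common when several large penalties all select nothing)
    resolve toward the larger penalty, i.e. the sparser model.
    """
    config = config or TwoStageConfig()
    X = np.ascontiguousarray(X_train, dtype=float)
    y = np.ascontiguousarray(y_train, dtype=float)
    if len(y) < 3:
        raise ValueError("training fold must have at least 3 samples")
    grid = lambda_grid(X, y, config)
    sse = _kernels.inner_loo_sse(X, y, grid, _CD_TOL, _CD_MAX_ITER)
    best = np.flatnonzero(sse == sse.min())[-1]
    return float(grid[best])


def refit_ols(
    X_selected: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """OLS with intercept on the selected columns; empty selection is allowed.

    Returns ``(intercept, coefficients)`` with coefficients aligned to the
    input columns. A rank-deficient design drops later-ordered collinear
    columns (their coefficients come back 0) with a warning.
    """
    X = np.asarray(X_selected, dtype=float)
    if X.ndim == 1:
        X = X.reshape(len(y), -1)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if k > n - 1:
        raise ValueError(f"{k} selected columns cannot be refit on {n} samples")
    if k == 0:
        return float(y.mean()), np.zeros(0)
    A = np.column_stack([np.ones(n), X])
    keep = list(range(k))
    if np.linalg.matrix_rank(A) < k + 1:
        warnings.warn("rank-deficient OLS design: dropping collinear columns",
                      stacklevel=2)
        keep = []
        basis = [np.ones(n)]
        for j in range(k):
            trial = np.column_stack(basis + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(basis) + 1:
                keep.append(j)
                basis.append(X[:, j])
        A = np.column_stack([np.ones(n)] + [X[:, j] for j in keep])
    sol = np.linalg.lstsq(A, y, rcond=1e-12)[0]
    coef = np.zeros(k)
    coef[keep] = sol[1:]
    return float(sol[0]), coef


def _fit_and_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_new: np.ndarray,
    lam: float,
    max_selected: int,
) -> tuple[float, np.ndarray]:
    """One two-stage fit on a training fold; returns (prediction, mask)."""
    Xs, mu, sd = _standardize_cols(X_train)
    _, beta = lasso_select(Xs, y_train, lam)
    sel = _kernels.cap_mask(beta, max_selected)
    intercept, coef = refit_ols(X_train[:, sel], y_train)
    yhat = intercept + float(x_new[sel] @ coef)
    return yhat, np.asarray(sel, dtype=bool)


@dataclass(frozen=True)
class FoldResult:
    participant: str
    lam: float
    mask: np.ndarray
    y_true: float
    y_pred: float

    @property
    def sq_error(self) -> float:
        return (self.y_pred - self.y_true) ** 2


@dataclass(frozen=True)
class TwoStageResult:
    """Per-group, per-target leave-one-out outcome of the two-stage model."""

    group: str
    target: str
    folds: tuple[FoldResult, ...]
    selection_mask: np.ndarray  # full-data selection, Table-style indicator
    selection_lambda: float

    @property
    def errors(self) -> np.ndarray:
        return np.array([f.sq_error for f in self.folds])

    @property
    def median_se(self) -> float:
        return float(np.median(self.errors))

    def errors_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "target": self.target,
                "participant": [f.participant for f in self.folds],
                "err_pr": self.errors,
            }
        )


def loo_two_stage(
    X: np.ndarray,
    y: np.ndarray,
    config: TwoStageConfig | None = None,
    participant_ids: Sequence[str] | None = None,
    group: str = "?",
    target: str = "?",
) -> TwoStageResult:
    """Leave-one-out two-stage prediction for one group and one target."""
    config = config or TwoStageConfig()
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError(f"group {group}: n={n} is too small for LOO two-stage (need >= 4)")
    ids = list(participant_ids) if participant_ids is not None else [str(i) for i in range(n)]

    folds = []
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        lam = select_lambda(Xtr, ytr, config)
        yhat, mask = _fit_and_predict(Xtr, ytr, X[i], lam, max_selected=len(ytr) - 2)
        folds.append(FoldResult(ids[i], lam, mask, float(y[i]), yhat))

    lam_full = select_lambda(X, y, config)
    _, full_mask = _fit_and_predict(X, y, X[0], lam_full, max_selected=n - 2)
    return TwoStageResult(
        group=group,
        target=target,
        folds=tuple(folds),
        selection_mask=full_mask,
        selection_lambda=lam_full,
    )


def selection_summary(masks_by_target: dict[str, np.ndarray]) -> pd.DataFrame:
    """Binary 3 x 8 indicator table of full-data lasso selections.

    Rows follow the target order (GE, JE, IM), columns the fixed feature
    order; a `row_sum` column reports how many features each target kept.
    """
    rows = {}
    for m in TARGET_METRICS:
        mask = np.asarray(masks_by_target.get(m, np.zeros(len(FEATURE_COLUMNS), bool)))
        rows[f"y_{m}"] = mask.astype(int)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_COLUMNS))
    table["row_sum"] = table.sum(axis=1)
    return table
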