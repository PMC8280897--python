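"""LASSO selection of WBC subtypes with unpenalized covariates.

The penalty is applied only to the candidate cell-count columns; covariates
(age, sex, height, ...) stay unpenalized.  That split is implemented by
residualizing the outcome and the penalized predictors on the covariates
(Frisch-Waugh) before the penalized solve, which gives the same optimum as
a joint fit with zero penalty factors on the covariates.  Penalized columns
are standardized to unit variance before penalization and coefficients are
reported back on the original count scale.

The penalty grid runs from lambda_max (the smallest penalty that zeroes
every penalized coefficient, from the stationarity bound max|X'r|/n on the
standardized residualized data) down four decades in 100 log-spaced steps.
lambda* is the minimizer of the 10-fold cross-validated mean squared error,
with ties broken toward the larger penalty (sparser model); no 1-SE rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .association import AssociationEstimate, fit_joint, _design_matrix

__all__ = ["LassoConfig", "SelectionResult", "select_lasso", "fit_multiple_marker"]


@dataclass
class LassoConfig:
    lambda_grid: Optional[np.ndarray] = None  # decreasing; auto if None
    n_folds: int = 10
    standardize: bool = True
    seed: int = 0
    grid_size: int = 100
    grid_ratio: float = 1e-4  # lambda_min = lambda_max * grid_ratio

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g <= 0):
                raise ValueError("lambda_grid must be strictly positive")
            if np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be strictly decreasing")


@dataclass
class SelectionResult:
    selected: list[str]
    lambda_star: float
    lambdas: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    coefficients: dict[str, float]  # original-scale coefficients at lambda*
    notice: Optional[str] = None


def _residualize(
    M: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project M off the column space of C; return residuals and the
    projection coefficients (for out-of-fold application)."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef, coef


def _lasso_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Coordinate-descent solution path over a decreasing penalty grid.

    Objective (scikit-learn convention): (1/2n)||y - Xb||^2 + lambda ||b||_1,
    no intercept (inputs are centred by residualization).  Non-convergence
    at any penalty raises with iteration diagnostics.
    """
    model = Lasso(alpha=lambdas[0], fit_intercept=False, warm_start=True,
                  max_iter=100_000, tol=1e-10)
    path = np.empty((lambdas.size, X.shape[1]))
    for i, lam in enumerate(lambdas):
        model.alpha = lam
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(X, y)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"coordinate descent failed to converge at lambda={lam:.4g} "
                    f"(max_iter={model.max_iter}, tol={model.tol}): {exc}"
                ) from None
        path[i] = model.coef_
    return path


def lambda_max(X_std: np.ndarray, r_y: np.ndarray) -> float:
    """Smallest penalty with all penalized coefficients zero (KKT bound)."""
    n = X_std.shape[0]
    return float(np.max(np.abs(X_std.T @ r_y)) / n)


def select_lasso(
    table: pd.DataFrame,
    outcome: str,
    penalized: Sequence[str],
    unpenalized: Sequence[str],
    config: Optional[LassoConfig] = None,
) -> SelectionResult:
    """Cross-validated LASSO over candidate exposures.

    ``penalized`` should already be restricted to candidates that passed the
    single-marker screen (p < .05); an empty candidate set returns an empty
    selection with a notice rather than an error.
    """
    config = config or LassoConfig()
    config.validate()
    if len(penalized) == 0:
        return SelectionResult(
            selected=[], lambda_star=float("nan"), lambdas=np.array([]),
            cv_mse_mean=np.array([]), cv_mse_se=np.array([]),
            coefficients={}, notice="empty candidate set: nothing to select",
        )
    data = table.dropna(subset=[outcome, *penalized, *unpenalized])
    C, _ = _design_matrix(data, list(unpenalized))  # includes the constant
    Xp = data[list(penalized)].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)

    r_X_full, _ = _residualize(Xp, C)
    r_y_full, _ = _residualize(y[:, None], C)
    r_y_full = r_y_full.ravel()
    sd_full = r_X_full.std(axis=0, ddof=0)
    if np.any(sd_full == 0):
        flat = [p for p, s in zip(penalized, sd_full) if s == 0]
        raise ValueError(f"penalized columns constant after residualization: {flat}")
    Xs_full = r_X_full / sd_full if config.standardize else r_X_full

    if config.lambda_grid is None:
        lmax = lambda_max(Xs_full, r_y_full)
        lambdas = np.logspace(
            np.log10(lmax), np.log10(lmax * config.grid_ratio), config.grid_size
        )
    else:
        lambdas = np.asarray(config.lambda_grid, dtype=float)

    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    fold_mse = np.empty((config.n_folds, lambdas.size))
    for f, (tr, te) in enumerate(kf.split(Xs_full)):
        # Residualize with training-fold covariate fits only.
        r_X_tr, cx = _residualize(Xp[tr], C[tr])
        r_y_tr, cy = _residualize(y[tr, None], C[tr])
        r_y_tr = r_y_tr.ravel()
        sd = r_X_tr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs_tr = r_X_tr / sd if config.standardize else r_X_tr
        path = _lasso_path(Xs_tr, r_y_tr, lambdas)
        Xs_te = (Xp[te] - C[te] @ cx)
        Xs_te = Xs_te / sd if config.standardize else Xs_te
        r_y_te = y[te] - (C[te] @ cy).ravel()
        resid = r_y_te[None, :] - path @ Xs_te.T
        fold_mse[f] = np.mean(resid**2, axis=1)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
    # Grid is decreasing, so argmin's first hit is the largest (sparsest) tie.
    i_star = int(np.argmin(cv_mean))
    lam_star = float(lambdas[i_star])

    coef_std = _lasso_path(Xs_full, r_y_full, lambdas[: i_star + 1])[-1]
    coef = coef_std / sd_full if config.standardize else coef_std
    coefficients = {p: float(b) for p, b in zip(penalized, coef)}
    selected = [p for p, b in coefficients.items() if b != 0.0]
    return SelectionResult(
        selected=selected, lambda_star=lam_star, lambdas=lambdas,
        cv_mse_mean=cv_mean, cv_mse_se=cv_se, coefficients=coefficients,
    )


def fit_multiple_marker(
    table: pd.DataFrame,
    selected: Sequence[str],
    outcome: str,
    covariates: Sequence[str],
    collinearity_limit: float = 0.999,
) -> list[AssociationEstimate]:
    """Mutually-adjusted OLS with all selected exposures entered jointly."""
    if len(selected) == 0:
        raise ValueError("no exposures selected for the multiple-marker model")
    data = table.dropna(subset=[*selected, outcome, *covariates])
    if len(selected) > 1:
        corr = np.corrcoef(data[list(selected)].to_numpy(dtype=float), rowvar=False)
        for i in range(len(selected)):
            for j in range(i + 1, len(selected)):
                if abs(corr[i, j]) > collinearity_limit:
                    raise ValueError(
                        f"exposures {selected[i]!r} and {selected[j]!r} are "
                        f"collinear (|r| = {abs(corr[i, j]):.4f})"
                    )
    return fit_joint(data, list(selected), outcome, covariates, model_tag="multiple")
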