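"""Per-cohort regression of lung function on white-blood-cell counts.

Implements the observational modelling stage: a single pass of total-WBC
outlier exclusion (mean +/- 3 SD), log10 transformation of the right-skewed
eosinophil and basophil counts, covariate-adjusted single-marker linear
models with either classical or complex-survey (stratified-PSU Taylor
linearization) variance, restricted cubic spline dose-response fits,
sensitivity-subset filters, and cross-product interaction tests.

Confidence intervals use beta -/+ 1.96 * se and p-values a normal reference,
so intervals round-trip exactly through the meta-analysis module's CI -> SE
reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta import Z95

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationEstimate",
    "InteractionResult",
    "RcsFit",
    "SurveyDesign",
    "exclude_wbc_outliers",
    "transform_counts",
    "fit_single_marker",
    "fit_rcs",
    "fit_interaction",
    "apply_sensitivity_filter",
    "rcs_basis",
    "default_knots",
]


@dataclass(frozen=True)
class AssociationEstimate:
    exposure: str
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    model: str = "single"  # "single" or "multiple"


@dataclass(frozen=True)
class InteractionResult:
    exposure: str
    outcome: str
    modifier: str
    p_interaction: float
    interaction_beta: float
    stratum_estimates: Mapping[int, AssociationEstimate]


@dataclass(frozen=True)
class RcsFit:
    exposure: str
    outcome: str
    knots: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    p_nonlinear: float
    coefs: np.ndarray
    n_used: int


@dataclass(frozen=True)
class SurveyDesign:
    """Column names describing a stratified multi-PSU weighted design."""

    stratum: str = "survey_stratum"
    psu: str = "survey_psu"
    weight: str = "survey_weight"


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def exclude_wbc_outliers(
    table: pd.DataFrame, column: str = "wbc_total", n_sd: float = 3.0
) -> tuple[pd.DataFrame, dict]:
    """Drop rows whose total WBC lies more than ``n_sd`` SDs from the mean.

    The mean and SD are computed once on the full input (no iteration).
    Returns the filtered table and a log dict with the bounds used and the
    identifiers of removed rows.
    """
    if column not in table.columns:
        raise KeyError(f"column {column!r} not present")
    if len(table) == 0:
        return table.copy(), {"lower": np.nan, "upper": np.nan, "removed": []}
    x = table[column].to_numpy(dtype=float)
    mean = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=1)) if len(table) > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("zero or undefined SD: no outlier exclusion applied")
        return table.copy(), {"lower": -np.inf, "upper": np.inf, "removed": []}
    lower, upper = mean - n_sd * sd, mean + n_sd * sd
    keep = (x >= lower) & (x <= upper)
    removed = table.loc[~keep]
    ids = (
        removed["subject_id"].tolist()
        if "subject_id" in removed.columns
        else removed.index.tolist()
    )
    logger.info("excluded %d of %d rows outside [%.4g, %.4g]",
                len(ids), len(table), lower, upper)
    return table.loc[keep].copy(), {"lower": lower, "upper": upper, "removed": ids}


def transform_counts(
    table: pd.DataFrame, columns: Sequence[str] = ("eosinophils", "basophils")
) -> pd.DataFrame:
    """Add log10 columns for the right-skewed subtypes.

    Zeros are shifted by half the smallest positive value observed in that
    column before taking logs; rows with negative counts are dropped with a
    diagnostic.  All other columns pass through untouched.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        x = out[col].to_numpy(dtype=float)
        neg = x < 0
        if neg.any():
            logger.warning(
                "dropping %d rows with negative %s counts", int(neg.sum()), col
            )
            out = out.loc[~neg].copy()
            x = out[col].to_numpy(dtype=float)
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError(f"column {col!r} has no positive values to transform")
        offset = 0.5 * float(positive.min())
        shifted = np.where(x == 0, offset, x)
        out[f"log10_{col}"] = np.log10(shifted)
    return out


def apply_sensitivity_filter(
    table: pd.DataFrame, rules: Mapping[str, object]
) -> tuple[pd.DataFrame, dict]:
    """Remove rows flagged by any exclusion rule ``{column: excluded value}``."""
    out = table
    counts: dict[str, int] = {}
    for col, flagged in rules.items():
        if col not in out.columns:
            raise KeyError(f"sensitivity rule refers to unknown column {col!r}")
        mask = out[col] == flagged
        counts[col] = int(mask.sum())
        out = out.loc[~mask]
    return out.copy(), {"removed_per_rule": counts, "n_out": len(out)}


# ---------------------------------------------------------------------------
# Design matrices and the OLS / survey-WLS engine
# ---------------------------------------------------------------------------

def _design_matrix(
    table: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Build [1, terms...] expanding `race` into drop-first dummies.

    A single-level categorical contributes nothing (constant), mirroring
    race adjustment only where more than one group is present.
    """
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["const"]
    for term in terms:
        if term not in table.columns:
            raise KeyError(f"model term {term!r} not in table")
        series = table[term]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{term}[{level}]")
        else:
            cols.append(series.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    return X, names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Name near-collinear pairs to make the error actionable.
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(X[:, sd > 0], rowvar=False)
        pairs = []
        active = [n for n, s in zip(names, sd) if s > 0]
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                if abs(c[i, j]) > 0.9999:
                    pairs.append((active[i], active[j]))
        const_cols = [n for n, s in zip(names, sd) if s == 0 and n != "const"]
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]}); "
            f"collinear pairs: {pairs or 'none found'}; "
            f"constant columns: {const_cols or 'none'}"
        )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Classical OLS: coefficients, covariance sigma^2 (X'X)^-1, residual df."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n ({n}) must exceed number of parameters ({p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    return beta, sigma2 * xtx_inv, n - p


def _survey_wls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray,
    strata: np.ndarray, psu: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted LS with stratified-PSU Taylor-linearization covariance.

    Point estimates solve X'WX b = X'Wy; the covariance is the sandwich
    A^-1 G A^-1 with A = X'WX and G built from between-PSU-within-stratum
    contrasts of the weighted score totals (no finite-population correction).
    """
    A = X.T @ (X * w[:, None])
    A_inv = np.linalg.inv(A)
    beta = A_inv @ (X.T @ (w * y))
    e = y - X @ beta
    z = X * (w * e)[:, None]  # per-row weighted score contributions
    G = np.zeros((X.shape[1], X.shape[1]))
    for h in np.unique(strata):
        in_h = strata == h
        psus = np.unique(psu[in_h])
        n_h = len(psus)
        if n_h < 2:
            continue  # single-PSU stratum contributes no variance
        totals = np.stack([z[in_h & (psu == j)].sum(axis=0) for j in psus])
        centered = totals - totals.mean(axis=0)
        G += n_h / (n_h - 1) * centered.T @ centered
    return beta, A_inv @ G @ A_inv


def _estimate_from_fit(
    exposure: str, outcome: str, beta: float, se: float, n_used: int, model: str
) -> AssociationEstimate:
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return AssociationEstimate(
        exposure=exposure, outcome=outcome, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        p=p, n_used=int(n_used), model=model,
    )


def _complete_cases(table: pd.DataFrame, needed: Sequence[str]) -> pd.DataFrame:
    return table.dropna(subset=[c for c in needed if c in table.columns])


def fit_single_marker(
    table: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: Sequence[str],
    design: Optional[SurveyDesign] = None,
) -> AssociationEstimate:
    """Covariate-adjusted linear model with one WBC exposure.

    Classical OLS without a survey design; design-based weighted least
    squares with Taylor-linearized variance when one is supplied.
    """
    needed = [exposure, outcome, *covariates]
    if design is not None:
        needed += [design.stratum, design.psu, design.weight]
    data = _complete_cases(table, needed)
    X, names = _design_matrix(data, [exposure, *covariates])
    _check_rank(X, names)
    y = data[outcome].to_numpy(dtype=float)
    j = names.index(exposure)
    if design is None:
        beta, cov, _ = _ols(X, y)
    else:
        beta, cov = _survey_wls(
            X, y,
            data[design.weight].to_numpy(dtype=float),
            data[design.stratum].to_numpy(),
            data[design.psu].to_numpy(),
        )
    return _estimate_from_fit(
        exposure, outcome, beta[j], np.sqrt(cov[j, j]), len(data), "single"
    )


def fit_joint(
    table: pd.DataFrame,
    exposures: Sequence[str],
    outcome: str,
    covariates: Sequence[str],
    model_tag: str = "multiple",
) -> list[AssociationEstimate]:
    """One OLS fit containing several exposures jointly (mutual adjustment)."""
    data = _complete_cases(table, [*exposures, outcome, *covariates])
    X, names = _design_matrix(data, [*exposures, *covariates])
    _check_rank(X, names)
    y = data[outcome].to_numpy(dtype=float)
    beta, cov, _ = _ols(X, y)
    return [
        _estimate_from_fit(
            e, outcome, beta[names.index(e)],
            np.sqrt(cov[names.index(e), names.index(e)]), len(data), model_tag,
        )
        for e in exposures
    ]


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

def default_knots(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Knots at the 5th/35th/65th/95th percentiles (4 knots) or evenly
    spaced quantiles between the 5th and 95th for other counts."""
    if n_knots == 4:
        q = [5, 35, 65, 95]
    else:
        q = np.linspace(5, 95, n_knots)
    return np.percentile(np.asarray(x, dtype=float), q)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    Column 0 is x itself; columns 1..k-2 are the restricted cubic terms
    normalized by (t_k - t_1)^2, linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    norm = (t[-1] - t[0]) ** 2

    def cube(u: np.ndarray) -> np.ndarray:
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def fit_rcs(
    table: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: Sequence[str],
    n_knots: int = 4,
    knots: Optional[np.ndarray] = None,
    grid_size: int = 100,
) -> RcsFit:
    """Dose-response fit on a restricted-cubic-spline basis.

    Returns the fitted curve (covariates held at their means) on an even
    grid over the exposure range and the joint Wald p-value of the
    nonlinear terms (chi-square, k-2 df); small p indicates departure from
    linearity.
    """
    if n_knots < 3:
        raise ValueError("n_knots must be at least 3")
    data = _complete_cases(table, [exposure, outcome, *covariates])
    x = data[exposure].to_numpy(dtype=float)
    if np.unique(x).size < n_knots:
        raise ValueError(
            f"exposure {exposure!r} has fewer distinct values than knots"
        )
    t = default_knots(x, n_knots) if knots is None else np.asarray(knots, float)
    basis = rcs_basis(x, t)
    Xc, names = _design_matrix(data, list(covariates))
    X = np.column_stack([Xc, basis])
    spline_names = [f"{exposure}_s{j}" for j in range(basis.shape[1])]
    _check_rank(X, names + spline_names)
    y = data[outcome].to_numpy(dtype=float)
    beta, cov, _ = _ols(X, y)

    p0 = Xc.shape[1]
    nonlin = slice(p0 + 1, X.shape[1])  # all spline columns beyond the linear one
    c = beta[nonlin]
    Vc = cov[nonlin, :][:, nonlin]
    wald = float(c @ np.linalg.solve(Vc, c)) if c.size else 0.0
    p_nonlinear = float(stats.chi2.sf(wald, c.size)) if c.size else 1.0

    grid = np.linspace(x.min(), x.max(), grid_size)
    basis_grid = rcs_basis(grid, t)
    covariate_means = Xc.mean(axis=0)
    fitted = covariate_means @ beta[:p0] + basis_grid @ beta[p0:]
    return RcsFit(
        exposure=exposure, outcome=outcome, knots=t, grid=grid,
        fitted=fitted, p_nonlinear=p_nonlinear, coefs=beta, n_used=len(data),
    )


# ---------------------------------------------------------------------------
# Interaction tests
# ---------------------------------------------------------------------------

def fit_interaction(
    table: pd.DataFrame,
    exposure: str,
    outcome: str,
    modifier: str,
    covariates: Sequence[str],
) -> InteractionResult:
    """Cross-product interaction test with per-stratum refits.

    The interaction p-value is the Wald p of the exposure-by-modifier
    product term; stratum-specific slopes come from separate fits within
    each level of the binary modifier.
    """
    data = _complete_cases(table, [exposure, outcome, modifier, *covariates])
    levels = np.sort(data[modifier].unique())
    if levels.size < 2:
        raise ValueError(f"modifier {modifier!r} is constant; interaction undefined")
    if levels.size > 2:
        raise ValueError(f"modifier {modifier!r} must be binary")

    work = data.copy()
    product = f"{exposure}_x_{modifier}"
    work[product] = work[exposure] * work[modifier]
    other_covs = [c for c in covariates if c != modifier]
    X, names = _design_matrix(work, [exposure, modifier, product, *other_covs])
    _check_rank(X, names)
    y = work[outcome].to_numpy(dtype=float)
    beta, cov, _ = _ols(X, y)
    j = names.index(product)
    se_j = float(np.sqrt(cov[j, j]))
    p_int = float(2.0 * stats.norm.sf(abs(beta[j] / se_j)))

    strata: dict[int, AssociationEstimate] = {}
    for level in levels:
        sub = data.loc[data[modifier] == level]
        n_params = 2 + len(other_covs)
        if len(sub) <= n_params:
            warnings.warn(
                f"stratum {modifier}={level} has too few rows; estimate omitted"
            )
            continue
        try:
            strata[int(level)] = fit_single_marker(sub, exposure, outcome, other_covs)
        except ValueError as exc:
            warnings.warn(f"stratum {modifier}={level} fit failed: {exc}")
    return InteractionResult(
        exposure=exposure, outcome=outcome, modifier=modifier,
        p_interaction=p_int, interaction_beta=float(beta[j]),
        stratum_estimates=strata,
    )
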