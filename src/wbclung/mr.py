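"""Two-sample Mendelian randomization from harmonized summary statistics.

Instrument QC (F statistic, confounder screen, palindrome handling),
allele harmonization, and the three estimators used for causal inference
on WBC counts and lung function: inverse-variance weighting (IVW), MR-Egger
regression (slope = pleiotropy-adjusted effect, intercept = average
directional pleiotropy), and the MR-PRESSO resampling test (global RSS
test, per-SNP outlier test with Bonferroni adjustment, distortion test).

Units follow the application: exposure effects in 10^9 cells/L per allele,
outcome effects in mL per allele, causal estimates in mL per 10^9 cells/L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta import Z95

logger = logging.getLogger(__name__)

__all__ = [
    "MRResult",
    "PressoResult",
    "compute_f_stat",
    "filter_instruments",
    "harmonize",
    "ivw",
    "egger",
    "mr_presso",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Effect-allele-frequency window in which a palindromic SNP cannot be
#: oriented from frequency alone.
AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class MRResult:
    method: str  # "IVW" or "Egger"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q_stat: float
    het_p: float
    n_snps: int
    egger_intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_ci: Optional[tuple[float, float]] = None
    intercept_p: Optional[float] = None


@dataclass(frozen=True)
class PressoResult:
    rss_observed: float
    global_p: float
    outlier_p: np.ndarray  # Bonferroni-adjusted, one per instrument
    outlier_indices: tuple[int, ...]
    distortion_p: Optional[float]
    n_simulations: int
    seed: Optional[int]


# ---------------------------------------------------------------------------
# Instrument strength and QC
# ---------------------------------------------------------------------------

def compute_f_stat(beta_x, se_x) -> np.ndarray:
    """Summary-data instrument strength F = (beta_x / se_x)^2."""
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    if np.any(se_x <= 0):
        raise ValueError("se_x must be positive")
    return (beta_x / se_x) ** 2


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def filter_instruments(
    instruments: pd.DataFrame,
    confounder_pvals: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    f_threshold: float = 10.0,
    presso_outliers: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Apply the instrument-validity screens; returns retained set + log.

    Removals, each logged with its reason: weak instruments (F < 10), SNPs
    associated with any confounding covariate at the Bonferroni-corrected
    level alpha / (n_snps * n_confounders), palindromic SNPs with effect-
    allele frequency too close to 0.5 to orient, and externally supplied
    MR-PRESSO outliers.  ``confounder_pvals`` is long format with columns
    snp, confounder, p.
    """
    df = instruments.copy()
    if "f_stat" not in df.columns:
        df["f_stat"] = compute_f_stat(df["beta_exposure"], df["se_exposure"])
    log: list[tuple[str, str]] = []
    drop = set()

    for _, row in df.iterrows():
        if row["f_stat"] < f_threshold:
            drop.add(row["snp"])
            log.append((row["snp"], f"weak instrument (F = {row['f_stat']:.2f} < "
                                    f"{f_threshold:g})"))

    if confounder_pvals is not None and len(confounder_pvals):
        n_conf = confounder_pvals["confounder"].nunique()
        cut = alpha / (len(df) * n_conf)
        assoc = confounder_pvals.loc[confounder_pvals["p"] < cut]
        for _, row in assoc.iterrows():
            if row["snp"] in set(df["snp"]) and row["snp"] not in {
                s for s, r in log if r.startswith("confounder")
            }:
                drop.add(row["snp"])
                log.append(
                    (row["snp"],
                     f"confounder-associated ({row['confounder']}, "
                     f"p = {row['p']:.3g} < {cut:.3g})")
                )

    lo, hi = AMBIGUOUS_EAF_WINDOW
    for _, row in df.iterrows():
        if _is_palindromic(row["effect_allele"], row["other_allele"]) and (
            lo < row["eaf"] < hi
        ):
            drop.add(row["snp"])
            log.append((row["snp"], "palindromic with ambiguous frequency"))

    if presso_outliers:
        for snp in presso_outliers:
            if snp in set(df["snp"]):
                drop.add(snp)
                log.append((snp, "MR-PRESSO outlier"))

    retained = df.loc[~df["snp"].isin(drop)].reset_index(drop=True)
    if len(retained) == 0:
        raise ValueError("all instruments excluded; no IVs remain")
    return retained, log


def harmonize(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Align outcome summary statistics to the exposure effect allele.

    Both inputs need columns snp, effect_allele, other_allele, eaf, beta,
    se, p, n.  Outcome rows coded on the swapped allele get their beta sign
    and frequency flipped; opposite-strand codings are complemented first.
    Palindromic SNPs with exposure frequency inside the ambiguity window are
    flagged, not dropped (filter_instruments removes them).  SNPs whose
    allele sets stay incompatible after complementing are dropped with a log
    entry.
    """
    log: list[tuple[str, str]] = []
    exp = exposure.set_index("snp")
    out = outcome.set_index("snp")
    common = exp.index.intersection(out.index)
    for snp in exposure.loc[~exposure["snp"].isin(common), "snp"]:
        log.append((snp, "missing from outcome statistics"))

    rows = []
    for snp in common:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = e["effect_allele"].upper(), e["other_allele"].upper()
        ea_o, oa_o = o["effect_allele"].upper(), o["other_allele"].upper()
        beta_y, eaf_y = float(o["beta"]), float(o["eaf"])
        if {ea_o, oa_o} != {ea_e, oa_e}:
            comp = {_COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?")}
            if comp == {ea_e, oa_e}:
                ea_o, oa_o = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
            else:
                log.append((snp, f"incompatible alleles "
                                 f"{ea_e}/{oa_e} vs {ea_o}/{oa_o}"))
                continue
        if ea_o != ea_e:  # swapped coding: flip outcome effect direction
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y
        pal = _is_palindromic(ea_e, oa_e)
        lo, hi = AMBIGUOUS_EAF_WINDOW
        ambiguous = pal and (lo < float(e["eaf"]) < hi)
        if ambiguous:
            log.append((snp, "palindromic with ambiguous frequency (flagged)"))
        rows.append(
            {
                "snp": snp,
                "chr": e.get("chr", np.nan),
                "pos": e.get("pos", np.nan),
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "eaf": float(e["eaf"]),
                "beta_exposure": float(e["beta"]),
                "se_exposure": float(e["se"]),
                "p_exposure": float(e["p"]),
                "n_exposure": e.get("n", np.nan),
                "beta_outcome": beta_y,
                "se_outcome": float(o["se"]),
                "p_outcome": float(o["p"]),
                "n_outcome": o.get("n", np.nan),
                "palindromic": pal,
                "ambiguous": ambiguous,
            }
        )
    return pd.DataFrame(rows), log


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _extract(instruments: pd.DataFrame):
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sx = instruments["se_exposure"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("standard errors must be positive")
    return bx, by, sx, sy


def ivw(instruments: pd.DataFrame, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted causal estimate.

    Equivalent to the weighted through-origin regression of beta_outcome on
    beta_exposure with weights 1/se_outcome^2; the one-instrument case
    reduces to the Wald ratio.  By default the fixed-effect (unscaled)
    variance is used; ``random_effects=True`` applies the multiplicative
    overdispersion factor max(1, Q/(n-1)).
    """
    bx, by, _, sy = _extract(instruments)
    n = bx.size
    if n < 1:
        raise ValueError("no instruments")
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    est = float(np.sum(w * bx * by) / sxx)
    var = 1.0 / sxx

    # Heterogeneity across Wald ratios; SNPs with beta_x = 0 have no ratio.
    usable = bx != 0
    if not usable.all():
        import warnings

        warnings.warn(
            f"{int((~usable).sum())} instruments with beta_exposure = 0 "
            "excluded from the ratio-based Q statistic"
        )
    ratios = by[usable] / bx[usable]
    wq = (bx[usable] / sy[usable]) ** 2
    q = float(np.sum(wq * (ratios - est) ** 2))
    het_p = float(stats.chi2.sf(q, n - 1)) if n > 1 else 1.0
    if random_effects and n > 1:
        var *= max(1.0, q / (n - 1))
    se = float(np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(est / se)))
    return MRResult(
        method="IVW", estimate=est, se=se, ci_low=est - Z95 * se,
        ci_high=est + Z95 * se, p=p, q_stat=q, het_p=het_p, n_snps=int(n),
    )


def egger(instruments: pd.DataFrame) -> MRResult:
    """MR-Egger weighted regression with a free intercept.

    Instruments are first oriented so every exposure effect is positive
    (joint sign flips of beta_exposure/beta_outcome leave the causal slope
    unchanged but make the intercept identifiable).  Weights 1/se_outcome^2;
    heterogeneity Q from the weighted residuals on n-2 df.
    """
    bx, by, _, sy = _extract(instruments)
    n = bx.size
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    XtW = X.T * w
    A_inv = np.linalg.inv(XtW @ X)
    beta = A_inv @ (XtW @ by)
    resid = by - X @ beta
    q = float(np.sum(w * resid**2))
    het_p = float(stats.chi2.sf(q, n - 2))
    se = np.sqrt(np.diag(A_inv))
    est, icpt = float(beta[1]), float(beta[0])
    slope_se, icpt_se = float(se[1]), float(se[0])
    return MRResult(
        method="Egger",
        estimate=est, se=slope_se,
        ci_low=est - Z95 * slope_se, ci_high=est + Z95 * slope_se,
        p=float(2.0 * stats.norm.sf(abs(est / slope_se))),
        q_stat=q, het_p=het_p, n_snps=int(n),
        egger_intercept=icpt, intercept_se=icpt_se,
        intercept_ci=(icpt - Z95 * icpt_se, icpt + Z95 * icpt_se),
        intercept_p=float(2.0 * stats.norm.sf(abs(icpt / icpt_se))),
    )


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope with each instrument left out in turn (vectorized)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    instruments: pd.DataFrame,
    n_simulations: int = 1000,
    seed: Optional[int] = None,
    significance: float = 0.05,
    distortion: bool = True,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares uses leave-one-out IVW predictions:
    RSS = sum_j w_j (beta_y_j - b_(-j) beta_x_j)^2 with w_j = 1/se_y_j^2.
    Its null distribution is built by parametric simulation: beta_x* ~
    N(beta_x, se_x), beta_y* ~ N(b_(-j) beta_x_j, se_y), recomputing the
    leave-one-out RSS per draw.  The global p is the upper-tail fraction
    with a +1/(N+1) continuity adjustment; per-SNP outlier p-values come
    from each SNP's simulated residual distribution, Bonferroni-adjusted
    over instruments; the distortion p compares the outlier-driven shift of
    the IVW estimate against removals of random non-outlier subsets.
    """
    bx, by, sx, sy = _extract(instruments)
    n = bx.size
    if n < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if n_simulations < 100:
        raise ValueError("n_simulations must be at least 100")
    if np.allclose(bx, bx[0]) and np.allclose(by, by[0]):
        raise ValueError("degenerate instruments: no variation in effects")

    w = 1.0 / sy**2
    b_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - b_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    N = n_simulations
    bx_sim = rng.normal(bx, sx, size=(N, n))
    by_sim = rng.normal(b_loo * bx, sy, size=(N, n))
    sxy_s = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sxx_s = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    b_loo_s = (sxy_s - w * bx_sim * by_sim) / (sxx_s - w * bx_sim**2)
    res_sim = w * (by_sim - b_loo_s * bx_sim) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (N + 1))
    raw_p = (1 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (N + 1)
    outlier_p = np.minimum(1.0, raw_p * n)
    outliers = tuple(int(j) for j in np.flatnonzero(outlier_p < significance))

    distortion_p = None
    if distortion and outliers and len(outliers) < n:
        keep = np.setdiff1d(np.arange(n), outliers)
        def _slope(idx):
            return np.sum(w[idx] * bx[idx] * by[idx]) / np.sum(w[idx] * bx[idx] ** 2)
        b_all = _slope(np.arange(n))
        b_clean = _slope(keep)
        if b_clean != 0:
            d_obs = abs((b_all - b_clean) / b_clean)
            d_null = np.empty(N)
            for s in range(N):
                rm = rng.choice(keep, size=len(outliers), replace=False)
                b_s = _slope(np.setdiff1d(np.arange(n), rm))
                d_null[s] = abs((b_s - b_clean) / b_clean) if b_clean else np.nan
            distortion_p = float((1 + np.sum(d_null >= d_obs)) / (N + 1))

    return PressoResult(
        rss_observed=rss_obs, global_p=global_p, outlier_p=outlier_p,
        outlier_indices=outliers, distortion_p=distortion_p,
        n_simulations=N, seed=seed,
    )
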