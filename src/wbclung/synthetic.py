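"""Synthetic cohorts and two-sample GWAS summary statistics with known truth.

Two generators drive the test surface of the whole package:

``generate_cohort``
    Individual-level records (demographics, lifestyle, white-blood-cell
    differential, spirometry) for an NHANES-, coke-oven-worker- or
    Dongfeng-Tongji-like population.  WBC subtype counts are drawn on the
    log scale from a correlated multivariate normal and exponentiated, so
    eosinophils and basophils come out right-skewed; total WBC is the exact
    sum of the subtypes.  Lung function is a configurable linear function of
    covariates and counts plus Gaussian noise, with optional sex/smoking
    interaction slopes.

``generate_two_sample``
    Per-SNP exposure and outcome summary statistics with a configurable true
    causal effect, balanced or directional pleiotropy, and planted
    high-pleiotropy outlier instruments, together with a truth record.

All randomness flows from one integer seed expanded into named substreams,
so adding a field to one stream does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "TwoSampleSpec",
    "TwoSampleTruth",
    "generate_cohort",
    "generate_two_sample",
    "nhanes_spec",
    "cow_spec",
    "dftj_spec",
    "scramble_outcome_coding",
]

_LN10 = np.log(10.0)

_BINARY_COVARIATES = ("sex", "smoking", "alcohol", "exercise")

#: Default log-scale correlation among the five WBC subtypes.  Within-cohort
#: subtype correlations are not published for these populations, so these are
#: plausible modest positive values, not estimates.
DEFAULT_WBC_CORRELATION = np.array(
    [
        #  neut  lymph  mono   eos   baso
        [1.00, 0.15, 0.35, 0.15, 0.15],
        [0.15, 1.00, 0.25, 0.15, 0.15],
        [0.35, 0.25, 1.00, 0.20, 0.20],
        [0.15, 0.15, 0.20, 1.00, 0.30],
        [0.15, 0.15, 0.20, 0.30, 1.00],
    ]
)


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``wbc_means`` are natural-scale mean counts (10^9 cells/L) per subtype;
    ``wbc_log_sds`` the log-scale standard deviations; ``wbc_correlation``
    the log-scale correlation matrix in the same subtype order.  Effect sizes
    are mL of FVC/FEV1 per unit of the named column; a ``log10_<col>`` key
    applies the slope to log10 of that count, mirroring how skewed subtypes
    enter the regression models.  ``outcome_means`` anchors the intercepts so
    the generated cohort means match the target spirometry levels.
    """

    n_subjects: int
    covariate_means_sds: Mapping[str, tuple[float, float]]
    categorical_prevalences: Mapping[str, float]
    wbc_means: Mapping[str, float]
    wbc_log_sds: Mapping[str, float]
    wbc_correlation: Optional[np.ndarray] = None
    effect_sizes: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    noise_sd: float = 450.0
    noise_corr: float = 0.9
    outcome_means: tuple[float, float] = (3000.0, 2500.0)
    race_probs: Optional[Mapping[str, float]] = None
    survey: Optional[tuple[int, int, tuple[float, float]]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, p in self.categorical_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {name!r} outside [0, 1]: {p}")
        corr = self.correlation_matrix()
        k = len(self.wbc_means)
        if corr.shape != (k, k):
            raise ValueError(
                f"wbc_correlation is {corr.shape}, expected ({k}, {k}) "
                f"for subtypes {list(self.wbc_means)}"
            )
        if not np.allclose(corr, corr.T):
            raise ValueError("wbc_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("wbc_correlation must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"wbc_correlation is not positive semi-definite "
                f"(smallest eigenvalue {eigmin:.3e})"
            )

    def correlation_matrix(self) -> np.ndarray:
        if self.wbc_correlation is not None:
            return np.asarray(self.wbc_correlation, dtype=float)
        k = len(self.wbc_means)
        if k == 5:
            return DEFAULT_WBC_CORRELATION.copy()
        # Three-part differential (or other panel): modest exchangeable default.
        return np.full((k, k), 0.2) + 0.8 * np.eye(k)


def _expected_column_value(spec: CohortSpec, name: str) -> float:
    """Expectation of one linear-predictor column under the spec."""
    if name.startswith("log10_"):
        base = name[len("log10_"):]
        mean = spec.wbc_means[base]
        sigma = spec.wbc_log_sds[base]
        # log X ~ N(mu, sigma^2) with mu chosen so E[X] = mean.
        mu = np.log(mean) - 0.5 * sigma**2
        return mu / _LN10
    if name in spec.wbc_means:
        return float(spec.wbc_means[name])
    if name == "wbc_total":
        return float(sum(spec.wbc_means.values()))
    if name in spec.covariate_means_sds:
        return float(spec.covariate_means_sds[name][0])
    if name in spec.categorical_prevalences:
        return float(spec.categorical_prevalences[name])
    raise KeyError(f"effect size refers to unknown column {name!r}")


def _column_values(table: pd.DataFrame, name: str) -> np.ndarray:
    if name.startswith("log10_"):
        return np.log10(table[name[len("log10_"):]].to_numpy())
    return table[name].to_numpy()


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort table; identical specs give identical tables."""
    spec.validate()
    n = spec.n_subjects
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_cov = np.random.default_rng(streams[0])
    rng_counts = np.random.default_rng(streams[1])
    rng_noise = np.random.default_rng(streams[2])
    rng_survey = np.random.default_rng(streams[3])

    table = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)]})
    for name, (mean, sd) in spec.covariate_means_sds.items():
        table[name] = rng_cov.normal(mean, sd, n)
    for name in _BINARY_COVARIATES:
        p = spec.categorical_prevalences.get(name, 0.5)
        table[name] = (rng_cov.random(n) < p).astype(int)
    if spec.race_probs is not None:
        levels = list(spec.race_probs)
        probs = np.array([spec.race_probs[k] for k in levels], dtype=float)
        probs = probs / probs.sum()
        table["race"] = rng_cov.choice(levels, size=n, p=probs)

    # WBC subtypes: correlated lognormal with natural-scale means matched
    # exactly; mu_i = log(mean_i) - sigma_i^2 / 2.
    subtypes = list(spec.wbc_means)
    sigma = np.array([spec.wbc_log_sds[s] for s in subtypes], dtype=float)
    mu = np.log([spec.wbc_means[s] for s in subtypes]) - 0.5 * sigma**2
    corr = spec.correlation_matrix()
    cov = corr * np.outer(sigma, sigma)
    # PSD guaranteed by validate(); jitter only for exact-singular matrices.
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(subtypes)))
    counts = np.exp(mu + rng_counts.standard_normal((n, len(subtypes))) @ chol.T)
    bad = ~(np.isfinite(counts).all(axis=1) & (counts > 0).all(axis=1))
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > 100:
            raise RuntimeError(
                f"count resampling failed for {bad.sum()} subjects after 100 rounds"
            )
        redraw = np.exp(
            mu + rng_counts.standard_normal((int(bad.sum()), len(subtypes))) @ chol.T
        )
        counts[bad] = redraw
        bad = ~(np.isfinite(counts).all(axis=1) & (counts > 0).all(axis=1))
    for j, s in enumerate(subtypes):
        table[s] = counts[:, j]
    table["wbc_total"] = counts.sum(axis=1)

    # Linear predictors for FVC / FEV1, anchored so population means match
    # outcome_means in expectation.
    lp = np.zeros((n, 2))
    expected = np.zeros(2)
    for name, effs in spec.effect_sizes.items():
        effs = np.asarray(effs, dtype=float)
        vals = _column_values(table, name)
        lp += np.outer(vals, effs)
        expected += _expected_column_value(spec, name) * effs
    for (exp_name, mod_name), effs in spec.interaction_effects.items():
        effs = np.asarray(effs, dtype=float)
        vals = _column_values(table, exp_name) * table[mod_name].to_numpy()
        lp += np.outer(vals, effs)
        expected += (
            _expected_column_value(spec, exp_name)
            * spec.categorical_prevalences.get(mod_name, 0.5)
            * effs
        )
    intercepts = np.asarray(spec.outcome_means, dtype=float) - expected
    lp += intercepts

    if spec.noise_sd > 0:
        ncov = spec.noise_sd**2 * np.array(
            [[1.0, spec.noise_corr], [spec.noise_corr, 1.0]]
        )
        nchol = np.linalg.cholesky(ncov)
        noise = rng_noise.standard_normal((n, 2)) @ nchol.T
        out = lp + noise
        # Resample noise for subjects violating fvc >= fev1 >= 0 rather than
        # clipping, so configured means are only marginally disturbed.
        bad = ~((out[:, 0] >= out[:, 1]) & (out[:, 1] >= 0))
        attempts = 0
        while bad.any():
            attempts += 1
            if attempts > 100:
                raise RuntimeError(
                    f"noise resampling failed for {bad.sum()} subjects after "
                    "100 rounds; outcome means and noise_sd are inconsistent"
                )
            redraw = rng_noise.standard_normal((int(bad.sum()), 2)) @ nchol.T
            out[bad] = lp[bad] + redraw
            bad = ~((out[:, 0] >= out[:, 1]) & (out[:, 1] >= 0))
    else:
        out = lp
        if not ((out[:, 0] >= out[:, 1]) & (out[:, 1] >= 0)).all():
            raise ValueError(
                "noiseless linear predictors violate fvc >= fev1 >= 0; "
                "adjust outcome_means or effect sizes"
            )
    table["fvc"] = out[:, 0]
    table["fev1"] = out[:, 1]

    if spec.survey is not None:
        n_strata, psus_per_stratum, (w_lo, w_hi) = spec.survey
        idx = np.arange(n)
        table["survey_stratum"] = idx % n_strata
        table["survey_psu"] = (idx // n_strata) % psus_per_stratum
        table["survey_weight"] = rng_survey.uniform(w_lo, w_hi, n)
    return table


# ---------------------------------------------------------------------------
# Cohort profiles.  Means, prevalences and spirometry targets follow the
# published descriptive statistics of the three source populations; log-scale
# spreads are set so natural-scale SDs and the right skew of eosinophils /
# basophils look realistic.  Subtype means are chosen to sum exactly to the
# published total WBC so the subtype-sum identity and the total's mean can
# both hold.
# ---------------------------------------------------------------------------

_COMMON_EFFECTS_5 = {
    "age": (-22.0, -25.0),
    "sex": (500.0, 430.0),
    "height": (40.0, 35.0),
    "smoking": (-80.0, -100.0),
    "alcohol": (0.0, 0.0),
    "exercise": (30.0, 30.0),
    "neutrophils": (-33.0, -20.0),
    "lymphocytes": (0.0, 0.0),
    "monocytes": (-108.0, -97.0),
    "log10_eosinophils": (-31.0, -65.0),
    "log10_basophils": (-143.0, -29.0),
}


def dftj_spec(n_subjects: int = 13827, seed: int = 0, **overrides) -> CohortSpec:
    """Dongfeng-Tongji-like retiree cohort (five-part differential)."""
    kw = dict(
        n_subjects=n_subjects,
        covariate_means_sds={"age": (64.40, 8.2), "height": (160.07, 8.2)},
        categorical_prevalences={
            "sex": 0.432, "smoking": 0.273, "alcohol": 0.309, "exercise": 0.902,
        },
        wbc_means={
            "neutrophils": 3.25, "lymphocytes": 1.59, "monocytes": 0.28,
            "eosinophils": 0.17, "basophils": 0.09,
        },
        wbc_log_sds={
            "neutrophils": 0.32, "lymphocytes": 0.30, "monocytes": 0.35,
            "eosinophils": 0.75, "basophils": 0.70,
        },
        effect_sizes=dict(_COMMON_EFFECTS_5),
        outcome_means=(2422.85, 2080.33),
        noise_sd=450.0,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def nhanes_spec(n_subjects: int = 3570, seed: int = 0, **overrides) -> CohortSpec:
    """NHANES-2011-12-like survey sample (five-part differential, complex design)."""
    kw = dict(
        n_subjects=n_subjects,
        covariate_means_sds={"age": (45.43, 17.0), "height": (169.28, 10.0)},
        categorical_prevalences={
            "sex": 0.496, "smoking": 0.438, "alcohol": 0.912, "exercise": 0.195,
        },
        wbc_means={
            "neutrophils": 4.12, "lymphocytes": 2.04, "monocytes": 0.51,
            "eosinophils": 0.20, "basophils": 0.06,
        },
        wbc_log_sds={
            "neutrophils": 0.34, "lymphocytes": 0.30, "monocytes": 0.35,
            "eosinophils": 0.75, "basophils": 0.70,
        },
        effect_sizes=dict(_COMMON_EFFECTS_5),
        race_probs={
            "asian": 0.130, "mexican": 0.100, "other_hispanic": 0.101,
            "white": 0.374, "black": 0.264, "other": 0.031,
        },
        outcome_means=(4112.97, 3207.40),
        noise_sd=520.0,
        survey=(14, 2, (0.5, 3.0)),
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def cow_spec(n_subjects: int = 1762, seed: int = 0, **overrides) -> CohortSpec:
    """Coke-oven-worker-like occupational cohort (three-part differential)."""
    kw = dict(
        n_subjects=n_subjects,
        covariate_means_sds={"age": (41.33, 9.3), "height": (170.12, 6.3)},
        categorical_prevalences={
            "sex": 0.871, "smoking": 0.582, "alcohol": 0.373, "exercise": 0.591,
        },
        wbc_means={
            "neutrophils": 3.60, "lymphocytes": 2.18, "intermediate_cells": 0.58,
        },
        wbc_log_sds={
            "neutrophils": 0.32, "lymphocytes": 0.28, "intermediate_cells": 0.40,
        },
        effect_sizes={
            "age": (-22.0, -25.0),
            "sex": (500.0, 430.0),
            "height": (40.0, 35.0),
            "smoking": (-80.0, -100.0),
            "alcohol": (0.0, 0.0),
            "exercise": (30.0, 30.0),
            "neutrophils": (-26.0, -18.0),
            "lymphocytes": (0.0, 0.0),
            "intermediate_cells": (-120.0, -100.0),
        },
        outcome_means=(3488.55, 3108.48),
        noise_sd=430.0,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


# ---------------------------------------------------------------------------
# Two-sample summary statistics
# ---------------------------------------------------------------------------

_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                          ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

SUMMARY_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele", "eaf",
    "beta_exposure", "se_exposure", "p_exposure", "n_exposure",
    "beta_outcome", "se_outcome", "p_outcome", "n_outcome",
]


@dataclass
class TwoSampleSpec:
    """Recipe for harmonized two-sample summary statistics.

    ``causal_effect`` is the true effect of the exposure on the outcome in mL
    per 10^9 cells/L; per-SNP direct (pleiotropic) outcome effects are drawn
    N(pleiotropy_mean, pleiotropy_sd), with ``n_outliers`` SNPs receiving an
    additional direct effect of ``outlier_magnitude``.  Exposure effects are
    observed with error se_x, so weak-instrument dilution can be studied by
    raising it.
    """

    n_snps: int = 30
    beta_x_range: tuple[float, float] = (0.05, 0.25)
    se_x: float = 0.005
    se_y: float = 50.0
    causal_effect: float = -100.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_magnitude: float = 0.0
    eaf_range: tuple[float, float] = (0.10, 0.90)
    palindromic_fraction: float = 0.1
    n_exposure: int = 62076
    n_outcome: int = 4012
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if self.n_outliers > self.n_snps:
            raise ValueError("n_outliers cannot exceed n_snps")
        if not (0.0 < self.eaf_range[0] < self.eaf_range[1] < 1.0):
            raise ValueError("eaf_range must lie strictly inside (0, 1)")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("se_x and se_y must be positive")


@dataclass(frozen=True)
class TwoSampleTruth:
    """Ground truth recorded alongside a generated two-sample dataset."""

    causal_effect: float
    outlier_indices: tuple[int, ...]
    true_beta_x: np.ndarray
    pleiotropy: np.ndarray


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def generate_two_sample(spec: TwoSampleSpec) -> tuple[pd.DataFrame, TwoSampleTruth]:
    """Generate harmonized instruments plus the truth record.

    Per SNP j: beta_outcome[j] = causal_effect * beta_x_true[j] + alpha[j] +
    N(0, se_y), with alpha[j] the pleiotropic direct effect; beta_exposure[j]
    = beta_x_true[j] + N(0, se_x).
    """
    spec.validate()
    if spec.n_snps < 3:
        import warnings

        warnings.warn(
            "fewer than 3 instruments: MR-Egger will not be estimable downstream",
            stacklevel=2,
        )
    n = spec.n_snps
    streams = np.random.SeedSequence(spec.seed).spawn(3)
    rng_var = np.random.default_rng(streams[0])   # alleles, positions, eaf
    rng_bx = np.random.default_rng(streams[1])
    rng_eff = np.random.default_rng(streams[2])   # pleiotropy + noise

    bx_true = rng_bx.uniform(*spec.beta_x_range, n)
    beta_x = bx_true + rng_bx.normal(0.0, spec.se_x, n)
    alpha = rng_eff.normal(spec.pleiotropy_mean, spec.pleiotropy_sd, n)
    outlier_idx = tuple(
        sorted(rng_eff.choice(n, size=spec.n_outliers, replace=False).tolist())
    )
    alpha_full = alpha.copy()
    for j in outlier_idx:
        alpha_full[j] += spec.outlier_magnitude
    beta_y = spec.causal_effect * bx_true + alpha_full + rng_eff.normal(
        0.0, spec.se_y, n
    )

    n_pal = int(round(spec.palindromic_fraction * n))
    is_pal = np.zeros(n, dtype=bool)
    if n_pal:
        is_pal[rng_var.choice(n, size=n_pal, replace=False)] = True
    alleles = []
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if is_pal[j] else _NON_PALINDROMIC_PAIRS
        alleles.append(pool[rng_var.integers(len(pool))])
    eaf = rng_var.uniform(*spec.eaf_range, n)
    chrom = rng_var.integers(1, 23, n)
    pos = rng_var.integers(1, 2_000_000_00, n)

    se_x = np.full(n, spec.se_x)
    se_y = np.full(n, spec.se_y)
    df = pd.DataFrame(
        {
            "snp": [f"rs{100000 + j}" for j in range(n)],
            "chr": chrom,
            "pos": pos,
            "effect_allele": [a[0] for a in alleles],
            "other_allele": [a[1] for a in alleles],
            "eaf": eaf,
            "beta_exposure": beta_x,
            "se_exposure": se_x,
            "p_exposure": _two_sided_p(beta_x, se_x),
            "n_exposure": spec.n_exposure,
            "beta_outcome": beta_y,
            "se_outcome": se_y,
            "p_outcome": _two_sided_p(beta_y, se_y),
            "n_outcome": spec.n_outcome,
        }
    )
    truth = TwoSampleTruth(
        causal_effect=spec.causal_effect,
        outlier_indices=outlier_idx,
        true_beta_x=bx_true,
        pleiotropy=alpha_full,
    )
    return df, truth


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def scramble_outcome_coding(
    df: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a harmonized table into exposure/outcome halves with mixed coding.

    A random subset of outcome rows has its effect/other alleles swapped
    (with beta sign and eaf flipped) and another subset is reported on the
    opposite strand, emulating GWAS files that disagree on allele coding.
    ``wbclung.mr.harmonize`` should restore the original orientation.
    """
    rng = np.random.default_rng(seed)
    exposure = df[
        ["snp", "chr", "pos", "effect_allele", "other_allele", "eaf",
         "beta_exposure", "se_exposure", "p_exposure", "n_exposure"]
    ].rename(
        columns={
            "beta_exposure": "beta", "se_exposure": "se",
            "p_exposure": "p", "n_exposure": "n",
        }
    )
    outcome = df[
        ["snp", "chr", "pos", "effect_allele", "other_allele", "eaf",
         "beta_outcome", "se_outcome", "p_outcome", "n_outcome"]
    ].rename(
        columns={
            "beta_outcome": "beta", "se_outcome": "se",
            "p_outcome": "p", "n_outcome": "n",
        }
    ).copy()
    swap = rng.random(len(outcome)) < 0.5
    strand = rng.random(len(outcome)) < 0.3
    ea = outcome["effect_allele"].to_numpy().copy()
    oa = outcome["other_allele"].to_numpy().copy()
    beta = outcome["beta"].to_numpy().copy()
    eaf = outcome["eaf"].to_numpy().copy()
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    beta[swap] = -beta[swap]
    eaf[swap] = 1.0 - eaf[swap]
    pal = np.array(
        [a == _COMPLEMENT[b] for a, b in zip(ea, oa)]
    )
    flip_strand = strand & ~pal  # strand flips on palindromes are invisible
    ea[flip_strand] = [_COMPLEMENT[a] for a in ea[flip_strand]]
    oa[flip_strand] = [_COMPLEMENT[a] for a in oa[flip_strand]]
    outcome["effect_allele"] = ea
    outcome["other_allele"] = oa
    outcome["beta"] = beta
    outcome["eaf"] = eaf
    return exposure, outcome
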