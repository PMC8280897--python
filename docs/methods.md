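# Methods

This note records the statistical models implemented in `wbclung`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions used throughout.

## Observational models

**Outlier exclusion.** Subjects whose total WBC count lies more than three
standard deviations from the cohort mean are excluded.  The mean and SD are
computed once on the full sample (no re-iteration after removal); an SD of
zero triggers a warning and no exclusions.

**Transforms.** Eosinophil and basophil counts are right-skewed and enter
all models as log10 counts.  Zero counts are shifted by half the smallest
positive value observed in that column before the log — a conventional
offset that keeps the transform monotone without distorting the bulk of the
distribution.  No other column is touched.

**Single-marker model.** For each exposure (total WBC or one subtype) and
each outcome (FVC, FEV1 in mL), an ordinary least-squares fit of outcome on
exposure plus covariates (age, sex, height, smoking, alcohol, exercise, and
race when more than one level is present — a single-level categorical
contributes nothing).  Missing data are handled complete-case per model.
With a survey design (stratum, PSU, weight columns), point estimates come
from weighted least squares and variances from Taylor linearization with
between-PSU-within-stratum contrasts and no finite-population correction —
the standard design-based default for NHANES-like multistage samples.
Single-PSU strata contribute no variance rather than erroring.

**Intervals and p-values.** All 95% CIs are beta ± 1.96·se and p-values use
the normal reference, not t.  This makes the CI ↔ SE conversion used by the
meta-analysis stage ((upper − lower)/3.92) exact by construction.  At the
cohort sizes this package targets (hundreds to tens of thousands) the
normal/t difference is negligible; the interaction-test calibration test
confirms the rejection rate stays inside the exact binomial band at n = 400.

**Restricted cubic splines.** Dose–response shape is assessed on Harrell's
restricted (natural) cubic basis — truncated powers constrained to be
linear beyond the boundary knots, normalized by (t_k − t_1)² — with 4 knots
at the 5th/35th/65th/95th percentiles by default.  Departure from linearity
is the joint Wald chi-square of the nonlinear terms (k − 2 df).

**Interactions.** Effect modification by sex or smoking is tested by adding
an exposure × modifier cross-product to the adjusted model; P_int is the
Wald p of that term.  Stratum-specific slopes come from separate refits per
modifier level; a stratum with fewer rows than parameters is omitted with a
warning while P_int is still returned.

**LASSO selection.** Candidates are the subtypes significant in the
single-marker screen (p < .05).  Covariates are unpenalized: the outcome
and the candidate columns are residualized on the covariates
(Frisch–Waugh), which yields the same optimum as a joint fit with zero
penalty factors.  Candidates are standardized to unit variance before
penalization (the cell types span two orders of magnitude in count scale)
and coefficients reported back on the original scale.  The penalty grid is
100 log-spaced values from λ_max (the KKT bound max|X'r|/n at which every
penalized coefficient is zero) down four decades; λ* minimizes the 10-fold
cross-validated MSE (fold residualization is done within training folds),
with ties broken toward the larger penalty.  The minimum-MSE rule is used,
not the 1-SE rule.  The penalized solve is scikit-learn's coordinate
descent (tol 1e-10); non-convergence raises rather than warns.  The
selected subtypes then enter one joint OLS ("multiple-marker model") for
mutually-adjusted estimates; near-collinear selections (|r| > 0.999) are
rejected with the offending pair named.

**Meta-analysis.** Per-cohort estimates are pooled with inverse-variance
weights.  Cochran's Q on k − 1 df decides the model: fixed effect when the
heterogeneity p ≥ .05, DerSimonian–Laird random effects otherwise, with
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) and weights 1/(se² + τ²).  The .05
switch threshold is exposed in configuration.  A single study passes
through unchanged with heterogeneity p reported as 1.  A direct input mode
accepts (beta, ci_low, ci_high) triples so published per-cohort rows can be
re-pooled; because printed CIs are rounded to two decimals, re-pooled
estimates agree with published pooled values to roughly 1–2% relative, not
exactly.

## Mendelian randomization

Instruments are per-SNP summary associations: beta_exposure/se_exposure
(10^9 cells/L per allele) and beta_outcome/se_outcome (mL per allele) on a
common effect allele.

**Harmonization.** Outcome rows coded on the swapped allele get beta sign
and frequency flipped; opposite-strand codings are complemented first;
allele sets that remain incompatible drop the SNP with a log entry.
Palindromic (A/T, C/G) SNPs with effect-allele frequency in (0.42, 0.58)
cannot be oriented from frequency and are flagged ambiguous.

**Instrument QC.** Weak instruments are removed at F = (β_x/se_x)² < 10 —
the standard summary-data approximation to the first-stage F.  SNPs
associated with any confounding covariate at the Bonferroni-corrected level
α/(n_SNPs × n_confounders) are removed, as are ambiguous palindromes and
MR-PRESSO-flagged outliers when available.  Every removal is logged with
its reason.

**IVW.** The estimate Σwⱼβxⱼβyⱼ / Σwⱼβ²xⱼ with wⱼ = 1/se²yⱼ — equivalently
the weighted through-origin regression of outcome on exposure effects; one
instrument reduces to the Wald ratio.  The default variance is fixed-effect
(1/Σwⱼβ²xⱼ, no overdispersion scaling); a multiplicative random-effects
variant (scale max(1, Q/(n−1))) sits behind a flag.  Between-instrument
heterogeneity is Cochran's Q over the Wald ratios on n − 1 df; instruments
with β_x = 0 are excluded from the ratio-based Q with a warning.

**MR-Egger.** Weighted regression of β_y on β_x with a free intercept,
weights 1/se²_y, after flipping signs so every β_x > 0 (joint sign flips
leave the slope invariant; the orientation makes the intercept — the
average directional pleiotropy — identifiable).  Requires ≥ 3 instruments.
Heterogeneity Q from the weighted residuals on n − 2 df.

**MR-PRESSO.** The observed residual sum of squares uses leave-one-out IVW
predictions, RSS = Σⱼ wⱼ(βyⱼ − b₍₋ⱼ₎βxⱼ)².  Its null distribution is built
by parametric simulation (default 1000 draws): βx* ~ N(βx, se_x),
βy* ~ N(b₍₋ⱼ₎βxⱼ, se_y), recomputing the leave-one-out RSS per draw
(vectorized across draws).  The global p is the upper-tail fraction with a
+1/(N+1) continuity adjustment, so it is never exactly zero.  Per-SNP
outlier p-values come from each SNP's simulated weighted-residual
distribution, Bonferroni-multiplied by the instrument count; SNPs with
adjusted p < .05 are flagged.  The distortion test compares the
outlier-driven relative shift of the IVW estimate against a null built by
removing equally many randomly chosen non-outlier SNPs — a simplified
randomization version of the original bootstrap formulation, adequate for
flagging whether outliers move the estimate more than chance removals do.
Needs ≥ 4 instruments and ≥ 100 simulations; all resampling is seeded.

## Synthetic data

**Cohorts.** Three profiles mirror the descriptive statistics of the
populations this pipeline targets: a US survey sample with a complex design
and a multi-level race variable (n ≈ 3,570), an occupational cohort with a
3-part differential (neutrophils, lymphocytes, intermediate cells;
n ≈ 1,762), and a large retiree cohort with a 5-part differential
(n ≈ 13,827).  WBC subtypes are drawn on the log scale from a correlated
multivariate normal and exponentiated: with log-SD σ and natural-scale
target mean m, the log-mean is log m − σ²/2, so configured means are exact
and eosinophils/basophils come out right-skewed.  Total WBC is computed as
the subtype sum, so the subtype-sum identity holds exactly for every
subject.  Published tables report eosinophil/basophil location as medians
with 5th–95th percentiles; the generator instead fixes natural-scale means
chosen so the subtype means sum exactly to the published total (e.g. 3.25 +
1.59 + 0.28 + 0.17 + 0.09 = 5.38), which makes the total's mean a checkable
property at the cost of eosinophil medians running slightly high.
Within-cohort subtype correlations are not published; the defaults are
modest positive placeholders (0.15–0.35).

FVC and FEV1 are linear in the configured covariate and count effects plus
bivariate Gaussian noise (default SD 430–520 mL, correlation 0.9 between
the two outcomes).  Intercepts are solved from the target outcome means and
the expectations of every linear-predictor term, so cohort means land on
the configured spirometry levels.  Noise pairs violating
FVC ≥ FEV1 ≥ 0 are resampled per subject (at most 100 rounds, then error)
rather than clipped; at the default noise levels this truncation biases the
FEV1 mean down by about 1% and is the price of enforcing the physiological
ordering.  One global seed is expanded into independent substreams
(covariates, counts, noise, survey), so adding a field to one stream does
not shift the others.

The generator emulates means, prevalences, skewness, the subtype-sum
identity and configurable linear/interaction effects.  It does **not**
emulate age–count dependence, assortative covariate structure, measurement
error in spirometry, informative missingness, or real survey weight
construction — passing tests demonstrate the estimators are correct under
the stated model, not that the published cohort coefficients are
recoverable from real data.

**Two-sample summary statistics.** True per-allele exposure effects are
uniform in a configured range (default 0.05–0.25 with se_x = 0.005, giving
F statistics in the hundreds, as for genome-wide-significant hits from a
six-figure GWAS); observed exposure betas add N(0, se_x) noise, so
weak-instrument dilution can be studied by inflating se_x.  Outcome betas
are causal_effect × true β_x plus a pleiotropic direct effect
N(pleiotropy_mean, pleiotropy_sd), plus N(0, se_y) noise; planted outliers
receive an extra direct effect of configured magnitude, and their indices
are stored in the truth record.  The default se_y = 50 mL per allele makes
a 30-SNP IVW standard error of roughly 60 mL per 10^9 cells/L — the
precision regime of an outcome GWAS of a few thousand subjects.  Alleles,
positions and frequencies are decorative but schema-complete; a configured
fraction of SNPs is palindromic so harmonization and QC paths are
exercised.  `scramble_outcome_coding` re-expresses the outcome half with
randomly swapped or strand-flipped allele codings to test harmonization
round-trips.

## Problem sizes used in validation

The test suite validates the stochastic claims at fixed, seeded problem
sizes chosen to give the relevant checks high power while keeping the suite
quick: IVW recovery/coverage over 500 replicates of 30 SNPs; the Egger
intercept null calibration over 1000 replicates and its directional-
pleiotropy recovery (δ = 2.0, se_y = 10 so the recovery check is
informative) over 500; MR-PRESSO outlier detection (direct effect 10 ×
se_y among 20 clean SNPs) over 200 replicates at 1000 simulations and its
null global-test behaviour over 200 replicates at 300 simulations; the
interaction-test calibration over 1000 cohorts of n = 400; and the
confounded-marker experiment (null lymphocyte effect, correlation 0.5 with
an active neutrophil effect of −30 mL) over 30 cohorts of n = 6,000, which
reproduces the qualitative mutual-adjustment result: significant alone,
null after adjustment.

## Known limitations

- The survey variance ignores finite-population corrections and treats
  single-PSU strata as contributing zero variance.
- Post-LASSO inference is naive OLS on the selected set; no
  selective-inference correction is applied (deliberately, to mirror common
  practice).
- The MR-PRESSO distortion test is the simplified randomization form
  described above.
- Weighted-median/mode MR estimators, multivariable MR and LD-aware
  clumping are out of scope; instruments are assumed pre-pruned.
- The meta module's CI↔SE conversion uses 1.96 exactly; feeding it
  intervals produced with the exact normal quantile (1.959964) changes
  reconstructed SEs by 2 parts in 10⁵, far below the rounding error of
  printed tables.
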