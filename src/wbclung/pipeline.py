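"""End-to-end orchestration of the observational and MR stages.

A single YAML config drives the run:

.. code-block:: yaml

    seed: 7
    outdir: results/
    covariates: [age, sex, height, smoking, alcohol, exercise]
    outcomes: [fvc, fev1]
    exposures: [wbc_total, neutrophils, lymphocytes, monocytes,
                log10_eosinophils, log10_basophils]
    cohorts:
      - name: dftj
        path: dftj.tsv
      - name: nhanes
        path: nhanes.tsv
        covariates: [age, sex, race, height, smoking, alcohol, exercise]
        survey: true
    mr:
      summary_stats: twosample.tsv
      n_simulations: 1000

Stages per cohort: total-WBC outlier exclusion, log10 transforms,
single-marker models, LASSO selection among significant candidates,
multiple-marker model; then inverse-variance meta-analysis across cohorts
and, if configured, the two-sample MR block (F-statistic screen,
instrument filtering, IVW, MR-Egger, MR-PRESSO with outlier re-fit).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .association import (
    SurveyDesign,
    exclude_wbc_outliers,
    fit_single_marker,
    transform_counts,
)
from .io import (
    estimates_to_frame,
    read_cohort_table,
    read_summary_stats,
    write_estimates,
)
from .meta import pool
from .mr import egger, filter_instruments, ivw, mr_presso
from .selection import LassoConfig, fit_multiple_marker, select_lasso

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex", "height", "smoking", "alcohol", "exercise"]
DEFAULT_EXPOSURES = [
    "wbc_total", "neutrophils", "lymphocytes", "monocytes",
    "log10_eosinophils", "log10_basophils",
]


@dataclass
class CohortConfig:
    name: str
    path: str
    covariates: Optional[list[str]] = None
    mapping: Optional[dict[str, str]] = None
    survey: bool = False
    exposures: Optional[list[str]] = None


@dataclass
class PipelineConfig:
    outdir: str
    cohorts: list[CohortConfig] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    outcomes: list[str] = field(default_factory=lambda: ["fvc", "fev1"])
    exposures: list[str] = field(default_factory=lambda: list(DEFAULT_EXPOSURES))
    meta_het_threshold: float = 0.05
    lasso_folds: int = 10
    candidate_alpha: float = 0.05
    mr: Optional[dict[str, Any]] = None
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = [CohortConfig(**c) for c in raw.pop("cohorts", [])]
        return cls(cohorts=cohorts, **raw)

    def validate(self) -> None:
        for c in self.cohorts:
            if not Path(c.path).exists():
                raise FileNotFoundError(f"cohort {c.name}: {c.path}")
        stochastic = bool(self.cohorts) or self.mr is not None
        if stochastic and self.seed is None:
            raise ValueError(
                "config must set a seed: fold assignment and MR-PRESSO "
                "resampling are stochastic"
            )
        if self.mr is not None:
            ss = self.mr.get("summary_stats")
            if not ss or not Path(ss).exists():
                raise FileNotFoundError(f"mr.summary_stats: {ss}")


def _available(table: pd.DataFrame, names: list[str]) -> list[str]:
    return [n for n in names if n.removeprefix("log10_") in table.columns
            or n in table.columns]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every configured stage; returns a bundle of results/paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"outputs": []}
    single_frames, multiple_frames = [], []

    for cohort in config.cohorts:
        logger.info("stage=read cohort=%s", cohort.name)
        table = read_cohort_table(cohort.path, cohort.mapping)
        table, exclusion = exclude_wbc_outliers(table)
        table = transform_counts(table)
        covs = cohort.covariates or config.covariates
        if "race" in table.columns and "race" not in covs:
            covs = [*covs, "race"]
        design = SurveyDesign() if cohort.survey else None
        exposures = _available(table, cohort.exposures or config.exposures)

        singles = []
        for outcome in config.outcomes:
            for exposure in exposures:
                try:
                    singles.append(
                        fit_single_marker(table, exposure, outcome, covs, design)
                    )
                except ValueError as exc:
                    raise RuntimeError(
                        f"stage=single-marker cohort={cohort.name} "
                        f"exposure={exposure} outcome={outcome}: {exc}"
                    ) from exc
        frame = estimates_to_frame(singles, cohort.name)
        single_frames.append(frame)

        # LASSO over significant subtype candidates (total WBC is not a
        # candidate: it is the sum of the others), then mutual adjustment.
        multiples = []
        for outcome in config.outcomes:
            cands = [
                e.exposure for e in singles
                if e.outcome == outcome and e.p < config.candidate_alpha
                and e.exposure != "wbc_total"
            ]
            sel = select_lasso(
                table, outcome, cands, covs,
                LassoConfig(n_folds=config.lasso_folds, seed=config.seed or 0),
            )
            if sel.selected:
                multiples.extend(
                    fit_multiple_marker(table, sel.selected, outcome, covs)
                )
        if multiples:
            multiple_frames.append(estimates_to_frame(multiples, cohort.name))

    results: dict[str, pd.DataFrame] = {}
    if single_frames:
        results["single"] = pd.concat(single_frames, ignore_index=True)
        for tag in ("single", "multiple"):
            frames = single_frames if tag == "single" else multiple_frames
            if not frames:
                continue
            allf = pd.concat(frames, ignore_index=True)
            pooled_rows = []
            for (exposure, outcome), grp in allf.groupby(["exposure", "outcome"]):
                m = pool(grp["beta"].to_numpy(), grp["se"].to_numpy(),
                         het_threshold=config.meta_het_threshold)
                pooled_rows.append(
                    {
                        "exposure": exposure, "outcome": outcome, "model": tag,
                        "beta": m.pooled_beta, "se": m.pooled_se,
                        "ci_low": m.ci_low, "ci_high": m.ci_high, "p": m.p,
                        "q": m.q_stat, "het_p": m.het_p, "tau2": m.tau2,
                        "method": m.method, "k": m.k,
                    }
                )
            results[f"meta_{tag}"] = pd.DataFrame(pooled_rows)
            path = outdir / f"estimates_{tag}.tsv"
            write_estimates(allf, path)
            bundle["outputs"].append(str(path))
            path = outdir / f"meta_{tag}.tsv"
            results[f"meta_{tag}"].to_csv(path, sep="\t", index=False,
                                          float_format="%.10g")
            bundle["outputs"].append(str(path))
    if multiple_frames:
        results["multiple"] = pd.concat(multiple_frames, ignore_index=True)

    if config.mr is not None:
        mr_cfg = config.mr
        stats_df = read_summary_stats(mr_cfg["summary_stats"])
        conf_path = mr_cfg.get("confounder_pvals")
        conf = pd.read_csv(conf_path, sep="\t") if conf_path else None
        retained, qc_log = filter_instruments(stats_df, conf,
                                              alpha=mr_cfg.get("alpha", 0.05))
        n_sim = int(mr_cfg.get("n_simulations", 1000))
        presso = None
        if len(retained) >= 4:
            presso = mr_presso(retained, n_simulations=n_sim, seed=config.seed)
            if presso.outlier_indices:
                flagged = retained.iloc[list(presso.outlier_indices)]["snp"]
                retained, more_log = filter_instruments(
                    retained, presso_outliers=list(flagged)
                )
                qc_log.extend(more_log)
        rows = []
        res_ivw = ivw(retained)
        rows.append(res_ivw)
        res_egger = egger(retained) if len(retained) >= 3 else None
        if res_egger is not None:
            rows.append(res_egger)
        mr_frame = pd.DataFrame(
            [
                {
                    "method": r.method, "n_snps": r.n_snps,
                    "estimate": r.estimate, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "p": r.p,
                    "egger_intercept": r.egger_intercept,
                    "intercept_p": r.intercept_p,
                    "q": r.q_stat, "het_p": r.het_p,
                    "presso_global_p": presso.global_p if presso else None,
                }
                for r in rows
            ]
        )
        path = outdir / "mr_results.tsv"
        mr_frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        bundle["outputs"].append(str(path))
        results["mr"] = mr_frame
        results["mr_qc_log"] = qc_log
        if presso is not None:
            results["presso"] = presso

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "covariates": config.covariates,
        "outcomes": config.outcomes,
        "exposures": config.exposures,
        "meta_het_threshold": config.meta_het_threshold,
        "lasso_folds": config.lasso_folds,
        "cohorts": [c.name for c in config.cohorts],
        "mr": config.mr,
        "outputs": bundle["outputs"],
    }
    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    bundle["outputs"].append(str(log_path))
    bundle["results"] = results
    return bundle
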