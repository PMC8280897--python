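"""Reading and writing the tab-separated formats used across the pipeline.

Cohort tables and GWAS summary statistics travel as UTF-8 TSV with a header
row and '.' decimals; estimate tables use one long format (cohort, exposure,
outcome, beta, se, ci_low, ci_high, p, n) shared by the association,
selection and meta stages.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .association import AssociationEstimate
from .synthetic import SUMMARY_COLUMNS

logger = logging.getLogger(__name__)

NUMERIC_COHORT_COLUMNS = [
    "age", "height", "wbc_total", "neutrophils", "lymphocytes", "monocytes",
    "eosinophils", "basophils", "intermediate_cells", "fvc", "fev1",
    "survey_weight",
]


def read_cohort_table(
    path: str | Path, mapping: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Read a cohort TSV, renaming columns via ``mapping`` (file -> canonical).

    Rows with unparseable numbers in canonical numeric columns are rejected
    and reported with their 1-based data line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty:
        raise ValueError(f"{path}: no data rows")
    if mapping:
        missing = [c for c in mapping if c not in table.columns]
        if missing:
            raise KeyError(f"{path}: mapped columns absent: {missing}")
        table = table.rename(columns=dict(mapping))
    bad = np.zeros(len(table), dtype=bool)
    for col in table.columns:
        if col in NUMERIC_COHORT_COLUMNS:
            values = pd.to_numeric(table[col], errors="coerce")
            bad |= values.isna().to_numpy() & table[col].notna().to_numpy()
            table[col] = values
        elif col in ("sex", "smoking", "alcohol", "exercise",
                     "survey_stratum", "survey_psu"):
            table[col] = pd.to_numeric(table[col], errors="coerce")
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +1 header, +1 one-based
        logger.warning("%s: rejected %d malformed rows (file lines %s)",
                       path, int(bad.sum()), lines)
        table = table.loc[~bad]
    return table.reset_index(drop=True)


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read two-sample summary statistics, validating the declared schema."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dups = df.loc[df["snp"].duplicated(), "snp"].unique().tolist()
    if dups:
        raise ValueError(f"{path}: duplicate SNP ids {dups}")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    bad_eaf = df.loc[(df["eaf"] <= 0) | (df["eaf"] >= 1)]
    if len(bad_eaf):
        raise ValueError(
            f"{path}: effect-allele frequencies outside (0, 1) for "
            f"{bad_eaf['snp'].tolist()}"
        )
    for col in ("se_exposure", "se_outcome"):
        if (df[col] <= 0).any():
            raise ValueError(f"{path}: non-positive values in {col}")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def estimates_to_frame(
    estimates: Sequence[AssociationEstimate], cohort: str
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cohort": cohort, "exposure": e.exposure, "outcome": e.outcome,
                "model": e.model, "beta": e.beta, "se": e.se,
                "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p, "n": e.n_used,
            }
            for e in estimates
        ]
    )


def write_estimates(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
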