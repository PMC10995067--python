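"""Reduce individual-level study data to GWAS-style summary statistics.

Each study is summarised by the age-adjusted linear regression

    y_i = b0 + b1 * snp_i + b2 * age_i + e_i

exactly as a per-study GWAS would fit it: no interaction and no quadratic
terms, whatever the true generating mechanism.  The per-allele estimate
``b1``, its conventional residual-variance standard error, and the study's
sample mean and SD of age are what downstream meta-analysis and
meta-regression consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudySummary",
    "DegenerateStudyError",
    "fit_study",
    "fit_collection",
    "summaries_to_frame",
    "frame_to_summaries",
    "write_summary_csv",
    "read_summary_csv",
]


class DegenerateStudyError(ValueError):
    """Raised when a study's design matrix is singular (e.g. monomorphic SNP)."""


@dataclass(frozen=True)
class StudySummary:
    """One study's (or study-occasion's) contribution to a meta-analysis.

    ``beta1`` is the per-allele SNP effect estimate with standard error ``se``;
    ``mean_age``/``sd_age`` are the study's age descriptives (sample SD, n-1
    denominator).  ``occasion_age`` and ``cohort_id`` are carried only by
    repeated-measures tables where one cohort contributes several rows.
    ``mean_age3`` optionally carries the study's raw third age moment
    ``mean(age^3)`` when it is known, overriding the zero-skewness derivation
    used for cubic meta-regression.
    """

    study_id: str
    beta1: float
    se: float
    n: int
    mean_age: float
    sd_age: float
    cohort_id: str | None = None
    occasion_age: float | None = None
    mean_age3: float | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.n < 3:
            raise ValueError("n must be >= 3 (the study model has 3 parameters)")
        if self.sd_age < 0:
            raise ValueError("sd_age must be >= 0")


def fit_study(table: pd.DataFrame, study_id: str | None = None) -> StudySummary:
    """OLS of ``y`` on intercept, ``snp`` and ``age`` for one study.

    Returns the SNP coefficient, its residual-variance SE, and the sample mean
    and SD (n-1) of age.  Raises :class:`DegenerateStudyError` if the design is
    singular — in simulated data that means a monomorphic SNP draw.
    """
    if len(table) < 3:
        raise DegenerateStudyError("need at least 3 participants")
    y = table["y"].to_numpy(dtype=float)
    snp = table["snp"].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    if np.ptp(snp) == 0 or np.ptp(age) == 0:
        raise DegenerateStudyError(
            "constant genotype or age column: study design matrix is singular"
        )
    n = len(y)
    X = np.column_stack([np.ones(n), snp, age])
    xtx = X.T @ X
    # guard against numerically singular designs beyond the constant-column case
    if np.linalg.cond(xtx) > 1e12:
        raise DegenerateStudyError("ill-conditioned study design matrix")
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - 3)
    cov = sigma2 * np.linalg.inv(xtx)
    se1 = float(np.sqrt(cov[1, 1]))
    if study_id is None:
        study_id = str(table["study"].iloc[0]) if "study" in table else "0"
    return StudySummary(
        study_id=study_id,
        beta1=float(coef[1]),
        se=se1,
        n=n,
        mean_age=float(age.mean()),
        sd_age=float(age.std(ddof=1)),
    )


def fit_collection(tables: Sequence[pd.DataFrame]) -> list[StudySummary]:
    """Fit every study, dropping (with a warning) degenerate ones.

    Monomorphic-SNP studies are excluded rather than imputed; with MAF 0.2 and
    n >= 1000 the event is vanishingly rare but must be handled
    deterministically.
    """
    out = []
    for j, table in enumerate(tables):
        try:
            out.append(fit_study(table))
        except DegenerateStudyError as exc:
            warnings.warn(f"study {j} dropped: {exc}", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# tabular interchange

#: fixed, documented column order of the StudySummary CSV schema
SUMMARY_COLUMNS = [
    "study_id",
    "beta1",
    "se",
    "n",
    "mean_age",
    "sd_age",
    "cohort_id",
    "occasion_age",
    "mean_age3",
]

_REQUIRED = ["study_id", "beta1", "se", "n", "mean_age", "sd_age"]


def summaries_to_frame(summaries: Sequence[StudySummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])[SUMMARY_COLUMNS]


def frame_to_summaries(df: pd.DataFrame) -> list[StudySummary]:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"summary table missing required columns: {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _REQUIRED}
        for opt in ("cohort_id", "occasion_age", "mean_age3"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = row[opt]
        sid = kwargs["study_id"]
        if isinstance(sid, (int, np.integer)) or (
            isinstance(sid, (float, np.floating)) and float(sid).is_integer()
        ):
            sid = int(sid)
        kwargs["study_id"] = str(sid)
        kwargs["n"] = int(kwargs["n"])
        out.append(StudySummary(**kwargs))
    return out


def write_summary_csv(summaries: Sequence[StudySummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_summary_csv(path) -> list[StudySummary]:
    return frame_to_summaries(pd.read_csv(path, float_precision="round_trip"))
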