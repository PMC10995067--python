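"""Applied pipeline: age-varying SNP association from a cohort-by-occasion table.

The canonical use case is an early-life FTO/BMI-style analysis: a handful of
cohorts each report the per-allele SNP effect on the phenotype at several
measurement ages.  The pipeline

1. pools all rows by fixed-effect meta-analysis (the age-agnostic estimate),
2. fits a cubic random-effects meta-regression on age, uncentred, so the
   intercept is the SNP effect at age 0,
3. adjusts the meta-regression coefficient SEs for sample overlap (the same
   cohort measured at several ages) via generalized covariance-aware weights,
4. reports I^2 before (fixed-effect) and after (residual) the age moderators,
5. exports the signed effect-by-age prediction curve with its 95% band.

Occasion rows are treated as narrow age bands: ``occasion_age`` supplies the
mean age with ``sd_age = 0`` unless per-occasion age SDs are given, so the
derived moments collapse to pure powers of age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metamodels, overlap
from .metamodels import MetaFit
from .studyfit import StudySummary, frame_to_summaries

__all__ = ["AppliedConfig", "AppliedReport", "run_applied", "convert_supplement_xlsx"]

APPLIED_INPUT_COLUMNS = ["cohort_id", "occasion_age", "beta1", "se", "n"]


@dataclass
class AppliedConfig:
    """Configuration of the applied pipeline.

    ``overlap_rule`` is one of ``"shared-n"`` (default: within-cohort
    correlation ``min(n_j,n_k)/sqrt(n_j n_k)``), ``"none"`` (rows independent)
    or a path to a long-format correlation CSV (cohort_id,row_i,row_j,r).
    ``degree=3, centre=0`` is the canonical cubic, uncentred specification.
    """

    input_path: str | Path | None = None
    table: pd.DataFrame | None = None
    degree: int = 3
    centre: float = 0.0
    overlap_rule: str = "shared-n"
    age_grid: Sequence[float] = field(
        default_factory=lambda: np.round(np.arange(0.0, 13.01, 0.25), 4)
    )

    def load_table(self) -> pd.DataFrame:
        if self.table is not None:
            df = self.table.copy()
        elif self.input_path is not None:
            df = pd.read_csv(self.input_path)
        else:
            raise ValueError("AppliedConfig needs input_path or an in-memory table")
        missing = [
            c for c in APPLIED_INPUT_COLUMNS if c not in df.columns and c != "cohort_id"
        ]
        if missing:
            raise ValueError(f"applied input table missing columns: {missing}")
        return df


@dataclass
class AppliedReport:
    """Everything the applied pipeline computes, serialisable to JSON/CSV."""

    fe: MetaFit
    mr: MetaFit
    i2_unadjusted: float
    i2_residual: float
    curve: pd.DataFrame
    n_rows: int
    n_summed: int  # per-occasion sample sizes summed over all rows
    n_unique: int  # one (largest-occasion) count per cohort: unique participants
    overlap_rule: str
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fixed_effect": self.fe.to_dict(),
            "meta_regression": self.mr.to_dict(),
            "i2_unadjusted_pct": self.i2_unadjusted,
            "i2_residual_pct": self.i2_residual,
            "n_rows": self.n_rows,
            "n_summed_over_occasions": self.n_summed,
            "n_unique_participants": self.n_unique,
            "overlap_rule": self.overlap_rule,
            "notes": self.notes,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def write_curve_csv(self, path) -> None:
        self.curve.to_csv(path, index=False)

    def text_summary(self) -> str:
        sign_ages = self.curve[np.sign(self.curve["effect"]).diff().fillna(0) != 0]
        lines = [
            f"rows: {self.n_rows}  cohorts contribute repeated occasions "
            f"(overlap rule: {self.overlap_rule})",
            f"N summed over occasion rows: {self.n_summed}; "
            f"unique participants (max occasion per cohort): {self.n_unique}",
            "",
            "Fixed-effect meta-analysis (age-agnostic pooled effect):",
            f"  beta = {self.fe.estimate:+.4f} "
            f"(95% CI {self.fe.ci_low[0]:+.4f} to {self.fe.ci_high[0]:+.4f}), "
            f"I^2 = {self.i2_unadjusted:.2f}%",
            "",
            f"Meta-regression (degree {self.mr.degree}, centre {self.mr.centre:g}):",
        ]
        for name, b, s in zip(self.mr.names, self.mr.coef, self.mr.se):
            lines.append(f"  {name:>14} = {b:+.5g} (SE {s:.3g})")
        lines.append(f"  residual I^2 = {self.i2_residual:.2f}%")
        if len(sign_ages):
            ages = ", ".join(f"{a:.2f}" for a in sign_ages["age"])
            lines.append(f"  fitted effect changes sign near age(s): {ages} years")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def _rows_to_summaries(df: pd.DataFrame) -> list[StudySummary]:
    df = df.copy()
    if "mean_age" not in df.columns:
        df["mean_age"] = df["occasion_age"]
    if "sd_age" not in df.columns:
        df["sd_age"] = 0.0
    df["sd_age"] = df["sd_age"].fillna(0.0)
    if "study_id" not in df.columns:
        if "cohort_id" in df.columns:
            cohort = df["cohort_id"].astype(str)
        else:
            cohort = pd.Series([f"row{i}" for i in range(len(df))], index=df.index)
        df["study_id"] = [
            f"{c}@{a:g}y" for c, a in zip(cohort, df["occasion_age"])
        ]
    return frame_to_summaries(df)


def run_applied(config: AppliedConfig) -> AppliedReport:
    """Run the full applied pipeline; see the module docstring for the steps."""
    df = config.load_table()
    notes: list[str] = []
    summaries = _rows_to_summaries(df)
    if len(summaries) <= config.degree + 1:
        raise ValueError(
            f"need more than {config.degree + 1} rows for a degree-{config.degree} fit"
        )

    fe = metamodels.fixed_effect_ma(summaries)

    have_cohorts = "cohort_id" in df.columns and df["cohort_id"].notna().all()
    rule = config.overlap_rule
    if rule != "none" and not have_cohorts:
        warnings.warn(
            "cohort ids missing: overlap adjustment SKIPPED; standard errors "
            "assume independent rows",
            stacklevel=2,
        )
        notes.append("independence-assumed: cohort ids missing, no overlap adjustment")
        rule = "none"

    if config.degree == 0:
        mr = metamodels.random_effects_ma(summaries)
        mr.centre = config.centre
        if rule != "none":
            structure = overlap.OverlapStructure.from_summaries(summaries)
            cov = overlap.build_covariance(summaries, structure)
            mr = overlap.gls_meta_fit(summaries, cov, degree=0, centre=config.centre)
    elif rule == "none":
        mr = metamodels.meta_regression(
            summaries, degree=config.degree, centre=config.centre
        )
        if "independence-assumed" not in " ".join(notes):
            notes.append("independence-assumed: overlap rule 'none'")
    else:
        if rule == "shared-n":
            structure = overlap.OverlapStructure.from_summaries(summaries)
            notes.append(
                "overlap covariance from shared-sample rule "
                "r = min(n_j,n_k)/sqrt(n_j n_k) within cohorts"
            )
        else:
            structure = overlap.OverlapStructure.from_csv(
                _cohort_map_frame(df), rule
            )
            notes.append(f"overlap correlations read from {rule}")
        cov = overlap.build_covariance(summaries, structure)
        mr = overlap.gls_meta_fit(
            summaries, cov, degree=config.degree, centre=config.centre
        )

    curve = metamodels.predict_effect_at_age(mr, config.age_grid)

    n = df["n"].astype(int)
    if have_cohorts:
        n_unique = int(df.groupby("cohort_id")["n"].max().sum())
    else:
        n_unique = int(n.sum())
    return AppliedReport(
        fe=fe,
        mr=mr,
        i2_unadjusted=fe.I2,
        i2_residual=mr.I2,
        curve=curve,
        n_rows=len(df),
        n_summed=int(n.sum()),
        n_unique=n_unique,
        overlap_rule=rule,
        notes=notes,
    )


def _cohort_map_frame(df: pd.DataFrame):
    import io

    buf = io.StringIO()
    pd.DataFrame(
        {"study_id": range(len(df)), "cohort_id": df["cohort_id"].astype(str)}
    ).to_csv(buf, index=False)
    buf.seek(0)
    return buf


#: expected column mapping of a supplement-style XLSX sheet.  Keys are this
#: package's canonical column names, values the spreadsheet headers to look for.
XLSX_COLUMN_MAP = {
    "cohort_id": "Cohort",
    "occasion_age": "Age",
    "beta1": "Beta",
    "se": "SE",
    "n": "N",
}


def convert_supplement_xlsx(
    xlsx_path, sheet=0, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Convert a cohort-by-occasion XLSX sheet to the canonical CSV layout.

    The expected sheet has one row per cohort x measurement age with columns
    for cohort name, occasion age (years), per-allele effect estimate, its SE
    and the occasion sample size; ``column_map`` overrides the default header
    names in :data:`XLSX_COLUMN_MAP`.  Requires openpyxl.
    """
    cmap = dict(XLSX_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_excel(xlsx_path, sheet_name=sheet)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(
            f"XLSX sheet lacks expected columns {missing}; "
            f"pass column_map to adapt (have: {list(raw.columns)})"
        )
    out = pd.DataFrame({dst: raw[src] for dst, src in cmap.items()})
    out["mean_age"] = out["occasion_age"]
    out["sd_age"] = 0.0
    return out
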