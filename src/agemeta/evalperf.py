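"""Monte Carlo harness: factorial simulation experiments and performance measures.

A cell of the experiment grid fixes one data-generating condition (scenario,
age-overlap level, number of studies, per-study sample size, within/between
variability).  For each replicate the harness simulates a collection, reduces
every study to summary statistics, and applies each requested estimator
(fixed-effect MA, REML random-effects MA, meta-regression of degree 1-3).
Replicate-level estimates are then summarised per estimand by the standard
simulation-study performance measures:

* mean estimate and bias (mean - truth),
* coverage of the 95% confidence interval,
* empirical SE (SD of estimates across replicates),
* mean reported SE,

each with its Monte Carlo standard error (bias: EmpSE/sqrt(R); coverage:
sqrt(p(1-p)/R); EmpSE: EmpSE/sqrt(2(R-1))).

True estimand values are derived from the generating coefficients and the
centring age — the effect polynomial ``b_snp + b1*a + b2*a^2`` re-expressed
about the centre ``c`` gives intercept ``p(c)``, linear ``b1 + 2c*b2`` and
quadratic ``b2`` — never hand-entered per cell.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metamodels, studyfit, synthdata
from .synthdata import ScenarioSpec, SimDesign

__all__ = [
    "ExperimentGrid",
    "CellConfig",
    "ESTIMATORS",
    "true_effects",
    "run_cell",
    "summarise",
    "render_wide",
    "render_long",
    "run_grid",
]

MEASURES = ["mean", "bias", "coverage", "empse", "meanse"]


def _fit_fe(summaries, centre):
    return metamodels.fixed_effect_ma(summaries)


def _fit_re(summaries, centre):
    return metamodels.random_effects_ma(summaries)


def _make_mr(degree):
    def fit(summaries, centre):
        return metamodels.meta_regression(summaries, degree=degree, centre=centre)

    return fit


#: estimator registry: name -> callable(summaries, centre) -> MetaFit
ESTIMATORS: dict[str, Callable] = {
    "fe": _fit_fe,
    "re": _fit_re,
    "mr1": _make_mr(1),
    "mr2": _make_mr(2),
    "mr3": _make_mr(3),
}


@dataclass(frozen=True)
class CellConfig:
    """One fully specified cell of the factorial experiment."""

    scenario_id: int
    overlap_pct: int = 0
    n_studies: int = 40
    n_per_study: int = 1000
    sigma_within: float = 1.0
    sigma_between: float = 1.0
    centre: float = 10.0
    estimators: tuple[str, ...] = ("fe", "re", "mr1", "mr2")

    def scenario(self) -> ScenarioSpec:
        return ScenarioSpec(
            scenario_id=self.scenario_id,
            sigma_within=self.sigma_within,
            sigma_between=self.sigma_between,
        )

    def design(self, seed: int) -> SimDesign:
        return SimDesign(
            n_studies=self.n_studies,
            n_per_study=self.n_per_study,
            overlap_pct=self.overlap_pct,
            seed=seed,
        )

    @property
    def cell_id(self) -> str:
        return (
            f"s{self.scenario_id}_ov{self.overlap_pct}_k{self.n_studies}"
            f"_n{self.n_per_study}_sw{self.sigma_within:g}_sb{self.sigma_between:g}"
            f"_c{self.centre:g}"
        )


def true_effects(spec: ScenarioSpec, centre: float) -> dict[str, float]:
    """Estimand truths implied by the generating coefficients at a centring age."""
    c0, c1, c2 = synthdata.effect_polynomial(spec)
    return {
        "beta_snp": c0 + c1 * centre + c2 * centre**2,
        "beta_snp_age": c1 + 2.0 * centre * c2,
        "beta_snp_age2": c2,
        "beta_snp_age3": 0.0,
    }


def run_cell(
    cell: CellConfig, replications: int, seed: int
) -> pd.DataFrame:
    """Replicate-level estimates for one cell.

    Returns a long DataFrame with one row per replicate x estimator x
    coefficient: ``rep, estimator, estimand, estimate, se, ci_low, ci_high,
    ok, error``.  Estimator failures are recorded (``ok=False`` with the
    error message), never dropped silently.  Deterministic given ``seed``.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    spec = cell.scenario()
    children = np.random.SeedSequence(seed).spawn(replications)
    rows = []
    for rep, child in enumerate(children):
        design_seed = int(child.generate_state(1)[0] % (2**31))
        design = cell.design(design_seed)
        tables = synthdata.simulate_collection(design, spec)
        summaries = studyfit.fit_collection(tables)
        for name in cell.estimators:
            try:
                fit = ESTIMATORS[name](summaries, cell.centre)
            except KeyError:
                raise ValueError(f"unknown estimator {name!r}") from None
            except Exception as exc:  # tallied, not silently dropped
                rows.append(
                    {
                        "rep": rep,
                        "estimator": name,
                        "estimand": "beta_snp",
                        "estimate": np.nan,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "df": np.nan,
                        "tau2": np.nan,
                        "ok": False,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
                continue
            for term, b, s, lo, hi in zip(
                fit.names, fit.coef, fit.se, fit.ci_low, fit.ci_high
            ):
                rows.append(
                    {
                        "rep": rep,
                        "estimator": name,
                        "estimand": term,
                        "estimate": b,
                        "se": s,
                        "ci_low": lo,
                        "ci_high": hi,
                        "df": fit.df,
                        "tau2": fit.tau2,
                        "ok": True,
                        "error": "",
                    }
                )
    return pd.DataFrame(rows)


def summarise(replicates: pd.DataFrame, truths: dict[str, float]) -> pd.DataFrame:
    """Performance measures with Monte Carlo SEs, per estimator x estimand."""
    rows = []
    for (est, term), grp in replicates.groupby(["estimator", "estimand"], sort=False):
        ok = grp[grp["ok"]]
        n_fail = int((~grp["ok"]).sum())
        R = len(ok)
        if R < 2:
            raise ValueError(
                f"estimator {est!r}, estimand {term!r}: need >= 2 successful "
                f"replicates, got {R}"
            )
        truth = truths[term]
        estimates = ok["estimate"].to_numpy()
        ses = ok["se"].to_numpy()
        covered = (
            (ok["ci_low"].to_numpy() <= truth) & (truth <= ok["ci_high"].to_numpy())
        )
        mean = estimates.mean()
        empse = estimates.std(ddof=1)
        p = covered.mean()
        rows.append(
            {
                "estimator": est,
                "estimand": term,
                "truth": truth,
                "n_reps": R,
                "n_fail": n_fail,
                "mean": mean,
                "bias": mean - truth,
                "coverage": p,
                "empse": empse,
                "meanse": ses.mean(),
                "mean_mcse": empse / np.sqrt(R),
                "bias_mcse": empse / np.sqrt(R),
                "coverage_mcse": np.sqrt(p * (1.0 - p) / R),
                "empse_mcse": empse / np.sqrt(2.0 * (R - 1)),
                "meanse_mcse": ses.std(ddof=1) / np.sqrt(R),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# publication-style table reshaping

_ID_COLS = ["estimator", "estimand", "truth", "n_reps", "n_fail"]


def render_wide(perf: pd.DataFrame) -> pd.DataFrame:
    """Long performance table -> one column per (measure, value/mcse) pair."""
    return perf.set_index(_ID_COLS)[
        MEASURES + [m + "_mcse" for m in MEASURES]
    ].reset_index()


def render_long(perf: pd.DataFrame) -> pd.DataFrame:
    """Wide table -> tidy rows (estimator, estimand, measure, value, mcse)."""
    rows = []
    for _, r in perf.iterrows():
        for m in MEASURES:
            rows.append(
                {
                    "estimator": r["estimator"],
                    "estimand": r["estimand"],
                    "measure": m,
                    "value": r[m],
                    "mcse": r[m + "_mcse"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grids


@dataclass
class ExperimentGrid:
    """Factorial experiment: the cross product of all listed factor levels."""

    scenarios: Sequence[int] = (1, 2, 3, 4, 5)
    overlaps: Sequence[int] = (0,)
    n_studies: Sequence[int] = (40,)
    n_per_study: Sequence[int] = (1000,)
    sigma_within: Sequence[float] = (1.0,)
    sigma_between: Sequence[float] = (1.0,)
    estimators: Sequence[str] = ("fe", "re", "mr1", "mr2")
    centre: float = 10.0
    replications: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        # normalise sequence fields so configs compare equal across YAML trips
        for name in ("scenarios", "overlaps", "n_studies", "n_per_study",
                     "sigma_within", "sigma_between", "estimators"):
            setattr(self, name, tuple(getattr(self, name)))
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")

    def cells(self) -> list[CellConfig]:
        out = []
        for sc in self.scenarios:
            for ov in self.overlaps:
                for k in self.n_studies:
                    for n in self.n_per_study:
                        for sw in self.sigma_within:
                            for sb in self.sigma_between:
                                out.append(
                                    CellConfig(
                                        scenario_id=sc,
                                        overlap_pct=ov,
                                        n_studies=k,
                                        n_per_study=n,
                                        sigma_within=sw,
                                        sigma_between=sb,
                                        centre=self.centre,
                                        estimators=tuple(self.estimators),
                                    )
                                )
        return out

    @classmethod
    def from_yaml(cls, path) -> "ExperimentGrid":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "seed" not in cfg:
            raise ValueError("grid config must state an explicit seed")
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("scenarios", "overlaps", "n_studies", "n_per_study",
                    "sigma_within", "sigma_between", "estimators"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def run_grid(
    grid: ExperimentGrid,
    out_dir: str | Path | None = None,
    log=None,
) -> pd.DataFrame:
    """Run every cell of the grid; returns the concatenated performance table.

    With ``out_dir`` each cell's performance table is written to
    ``<cell_id>.csv`` as it completes and cells whose file already exists are
    loaded instead of rerun, so an interrupted grid resumes with only the
    missing cells.  Per-cell seeds are spawned deterministically from the grid
    seed by cell position, so resuming reproduces the full-run results.
    """
    cells = grid.cells()
    children = np.random.SeedSequence(grid.seed).spawn(len(cells))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    pieces = []
    for cell, child in zip(cells, children):
        cell_seed = int(child.generate_state(1)[0] % (2**31))
        target = None if out_dir is None else out_dir / f"{cell.cell_id}.csv"
        if target is not None and target.exists():
            perf = pd.read_csv(target)
            if log:
                log(f"cell {cell.cell_id}: loaded existing results")
        else:
            t0 = time.perf_counter()
            reps = run_cell(cell, grid.replications, cell_seed)
            truths = true_effects(cell.scenario(), cell.centre)
            perf = summarise(reps, truths)
            if target is not None:
                perf.to_csv(target, index=False)
            if log:
                log(
                    f"cell {cell.cell_id}: R={grid.replications} seed={cell_seed} "
                    f"({time.perf_counter() - t0:.1f}s)"
                )
        for key, val in asdict(cell).items():
            if key != "estimators":
                perf[key] = val
        pieces.append(perf)
    return pd.concat(pieces, ignore_index=True)
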