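"""Simulation of multi-study cross-sectional GWAS data with age-varying SNP effects.

Five data-generating scenarios for a single quantitative-trait SNP are supported.
Writing ``a`` for participant age and ``g`` for minor-allele count, the phenotype of
participant ``i`` in study ``j`` is

* scenario 1: ``y = b0 + b_age*a + (b_snp + u_j)*g + e``
* scenario 2: scenario 1 plus a linear SNP-by-age interaction ``b_snp_age*a*g``
* scenario 3: scenario 1 plus a quadratic age main effect ``b_age2*a**2``
* scenario 4: scenario 3 plus the linear interaction
* scenario 5: scenario 4 plus a quadratic interaction ``b_snp_age2*a**2*g``

with ``e ~ N(0, sigma_within**2)`` per participant and a study-level shift
``u_j ~ N(0, sigma_between**2)`` of the SNP coefficient only, corresponding to a
random-effects meta-analysis model for the genotype-phenotype association.

Studies sample ages uniformly from per-study windows whose pairwise overlap is
controlled by a single percentage: 0% gives disjoint windows (high age diversity
across studies), 100% gives identical windows spanning the whole range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScenarioSpec",
    "SimDesign",
    "InvalidDesignError",
    "BASE_CASE",
    "make_age_windows",
    "simulate_collection",
    "effect_polynomial",
    "emulate_applied_table",
    "write_individual_csv",
    "read_individual_csv",
]

ALLOWED_OVERLAPS = (0, 25, 50, 75, 100)

#: which generating coefficients are active in each scenario's equation
_SCENARIO_TERMS = {
    1: frozenset({"beta0", "beta_age", "beta_snp"}),
    2: frozenset({"beta0", "beta_age", "beta_snp", "beta_snp_age"}),
    3: frozenset({"beta0", "beta_age", "beta_age2", "beta_snp"}),
    4: frozenset({"beta0", "beta_age", "beta_age2", "beta_snp", "beta_snp_age"}),
    5: frozenset(
        {"beta0", "beta_age", "beta_age2", "beta_snp", "beta_snp_age", "beta_snp_age2"}
    ),
}


class InvalidDesignError(ValueError):
    """Raised when a simulation design or scenario specification is inconsistent."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Phenotype-generating equation choice plus its parameter vector.

    Coefficients of terms absent from the chosen scenario's equation are forced
    to zero, so a spec is always internally consistent with its ``scenario_id``.
    Units: phenotype units (``beta0``), per year (``beta_age``), per year^2
    (``beta_age2``), per allele (``beta_snp``), per allele-year (``beta_snp_age``),
    per allele-year^2 (``beta_snp_age2``).
    """

    scenario_id: int
    beta0: float = 25.0
    beta_age: float = 0.010
    beta_age2: float = 0.001
    beta_snp: float = 1.5
    beta_snp_age: float = 0.020
    beta_snp_age2: float = 0.001
    sigma_within: float = 1.0
    sigma_between: float = 1.0
    maf: float = 0.2

    def __post_init__(self) -> None:
        if self.scenario_id not in _SCENARIO_TERMS:
            raise InvalidDesignError(f"scenario_id must be 1..5, got {self.scenario_id}")
        if not (self.sigma_within > 0):
            raise InvalidDesignError("sigma_within must be > 0")
        if self.sigma_between < 0:
            raise InvalidDesignError("sigma_between must be >= 0")
        if not (0 < self.maf <= 0.5):
            raise InvalidDesignError("maf must lie in (0, 0.5]")
        active = _SCENARIO_TERMS[self.scenario_id]
        for name in ("beta_age2", "beta_snp_age", "beta_snp_age2"):
            if name not in active:
                object.__setattr__(self, name, 0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)


@dataclass(frozen=True)
class SimDesign:
    """Collection-level design: study count, sizes, age-window geometry, seed."""

    n_studies: int = 40
    n_per_study: int | Sequence[int] = 1000
    global_age_range: tuple[float, float] = (10.0, 59.0)
    overlap_pct: int = 0
    per_study_age_ranges: Sequence[tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise InvalidDesignError("n_studies must be >= 2")
        lo, hi = self.global_age_range
        if not lo < hi:
            raise InvalidDesignError("global_age_range must satisfy min < max")
        if self.per_study_age_ranges is None:
            if self.overlap_pct not in ALLOWED_OVERLAPS:
                raise InvalidDesignError(
                    f"overlap_pct must be one of {ALLOWED_OVERLAPS} "
                    "unless per_study_age_ranges is given"
                )
        else:
            if len(self.per_study_age_ranges) != self.n_studies:
                raise InvalidDesignError(
                    "per_study_age_ranges must have one (lo, hi) pair per study"
                )
            for w_lo, w_hi in self.per_study_age_ranges:
                if not (lo <= w_lo < w_hi <= hi):
                    raise InvalidDesignError(
                        f"window [{w_lo}, {w_hi}] falls outside global range [{lo}, {hi}]"
                    )
        sizes = self.study_sizes()
        if any(n < 3 for n in sizes):
            raise InvalidDesignError("every study needs at least 3 participants")

    def study_sizes(self) -> list[int]:
        if np.isscalar(self.n_per_study):
            return [int(self.n_per_study)] * self.n_studies
        sizes = [int(n) for n in self.n_per_study]  # type: ignore[union-attr]
        if len(sizes) != self.n_studies:
            raise InvalidDesignError("n_per_study list length must equal n_studies")
        return sizes

    def to_dict(self) -> dict:
        d = asdict(self)
        d["global_age_range"] = list(self.global_age_range)
        if self.per_study_age_ranges is not None:
            d["per_study_age_ranges"] = [list(w) for w in self.per_study_age_ranges]
        if not np.isscalar(self.n_per_study):
            d["n_per_study"] = list(self.n_per_study)  # type: ignore[arg-type]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimDesign":
        d = dict(d)
        if "global_age_range" in d:
            d["global_age_range"] = tuple(d["global_age_range"])
        if d.get("per_study_age_ranges") is not None:
            d["per_study_age_ranges"] = [tuple(w) for w in d["per_study_age_ranges"]]
        return cls(**d)


#: Base-case design: 40 cross-sectional studies of 1000 participants, ages 10-59,
#: disjoint age windows (maximal age diversity).
BASE_CASE = SimDesign()


def make_age_windows(design: SimDesign) -> list[tuple[float, float]]:
    """Per-study age windows ``[lo, hi]`` realising the requested overlap level.

    All windows share one width ``w`` and their centres are equally spaced across
    the global range; adjacent windows overlap by ``overlap_pct/100 * w`` years.
    Solving ``w + (k-1)*spacing = range`` with ``spacing = w*(1 - f)`` gives
    ``w = range / (1 + (k-1)*(1-f))``; at 100% every window is the full range.
    The union of the windows always equals the global range.
    """
    if design.per_study_age_ranges is not None:
        return [tuple(w) for w in design.per_study_age_ranges]
    lo, hi = design.global_age_range
    k = design.n_studies
    f = design.overlap_pct / 100.0
    span = hi - lo
    if design.overlap_pct == 100:
        return [(lo, hi)] * k
    width = span / (1.0 + (k - 1) * (1.0 - f))
    spacing = width * (1.0 - f)
    return [(lo + j * spacing, lo + j * spacing + width) for j in range(k)]


def _phenotype(spec: ScenarioSpec, age: np.ndarray, snp: np.ndarray, u: float,
               eps: np.ndarray) -> np.ndarray:
    return (
        spec.beta0
        + spec.beta_age * age
        + spec.beta_age2 * age**2
        + (spec.beta_snp + u) * snp
        + spec.beta_snp_age * age * snp
        + spec.beta_snp_age2 * age**2 * snp
        + eps
    )


def simulate_collection(design: SimDesign, spec: ScenarioSpec) -> list[pd.DataFrame]:
    """Simulate one multi-study collection of individual-level tables.

    Returns one DataFrame per study with columns ``study, age, snp, y`` plus the
    study's realised SNP-effect shift ``u`` in ``df.attrs``.  Each study draws
    from its own RNG substream spawned from ``design.seed``, so changing one
    study's sample size leaves every other study's data untouched.
    """
    windows = make_age_windows(design)
    sizes = design.study_sizes()
    children = np.random.SeedSequence(design.seed).spawn(design.n_studies)
    tables = []
    for j, (window, n, ss) in enumerate(zip(windows, sizes, children)):
        rng = np.random.default_rng(ss)
        u = rng.normal(0.0, spec.sigma_between) if spec.sigma_between > 0 else 0.0
        age = rng.uniform(window[0], window[1], size=n)
        snp = rng.binomial(2, spec.maf, size=n).astype(float)
        eps = rng.normal(0.0, spec.sigma_within, size=n)
        df = pd.DataFrame(
            {"study": j, "age": age, "snp": snp, "y": _phenotype(spec, age, snp, u, eps)}
        )
        df.attrs["u"] = u
        df.attrs["window"] = window
        tables.append(df)
    return tables


def effect_polynomial(spec: ScenarioSpec) -> np.ndarray:
    """Coefficients ``[c0, c1, c2]`` of the true SNP effect as a polynomial in age.

    The population SNP effect at age ``a`` is ``c0 + c1*a + c2*a**2`` (study
    shifts ``u_j`` average to zero).
    """
    return np.array([spec.beta_snp, spec.beta_snp_age, spec.beta_snp_age2])


# ---------------------------------------------------------------------------
# applied-example-shaped summary tables

#: generating cubic for the emulated cohort-by-occasion table: per-allele effect
#: on the phenotype at age a.  Negative at ages 0-3, one sign change near 4.5,
#: positive at 5.5-13 — the qualitative pattern of an early-life FTO/BMI analysis.
APPLIED_TRUE_COEF = np.array([-0.06, 0.002, 0.003, -0.00012])


def applied_true_effect(age: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the emulated table's generating cubic effect at ``age`` (years)."""
    a = np.asarray(age, dtype=float)
    return np.polynomial.polynomial.polyval(a, APPLIED_TRUE_COEF)


def emulate_applied_table(
    n_cohorts: int = 8,
    occasions_per_cohort: int = 10,
    age_grid: Sequence[float] | None = None,
    seed: int = 0,
    tau_cohort: float = 0.02,
) -> pd.DataFrame:
    """Emulate a cohort-by-occasion summary table shaped like an early-life
    repeated-measures SNP/BMI meta-analysis input.

    Each of ``n_cohorts`` cohorts reports a per-allele effect estimate with its
    SE at up to ``occasions_per_cohort`` measurement ages drawn from ``age_grid``
    (default: 10 ages spanning 0-13 years).  The true effect follows the built-in
    cubic :data:`APPLIED_TRUE_COEF`, so the sign-change behaviour of an
    age-varying association is exercisable without any external data.  Cohort
    sizes span the few-hundred to few-thousand range typical of birth cohorts,
    and SEs scale as ``1.5/sqrt(n)``.

    Returns a DataFrame with columns
    ``cohort_id, occasion_age, beta1, se, n, mean_age, sd_age``.
    """
    if n_cohorts < 2:
        raise InvalidDesignError("n_cohorts must be >= 2")
    if age_grid is None:
        age_grid = np.linspace(0.0, 13.0, occasions_per_cohort)
    age_grid = np.asarray(age_grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cohorts):
        n0 = int(rng.integers(569, 7483))
        u_c = rng.normal(0.0, tau_cohort)
        ages = age_grid[:occasions_per_cohort]
        # follow-up attrition: each later occasion retains ~96-99% of the
        # previous one, as in real birth-cohort waves
        retain = rng.uniform(0.96, 0.99, size=len(ages))
        retain[0] = 1.0
        ns = np.maximum(np.round(n0 * np.cumprod(retain)), 100).astype(int)
        se = 1.5 / np.sqrt(ns) * np.exp(rng.normal(0.0, 0.1, size=len(ages)))
        # one shared cohort-level draw + occasion-level noise: repeated measures
        # on one sample are positively correlated across occasions
        shared = rng.normal(0.0, 1.0)
        occ = rng.normal(0.0, 1.0, size=len(ages))
        z = 0.6 * shared + 0.8 * occ
        beta = applied_true_effect(ages) + u_c + se * z
        for a, b, s, n in zip(ages, beta, se, ns):
            rows.append(
                {
                    "cohort_id": f"cohort_{c + 1:02d}",
                    "occasion_age": float(a),
                    "beta1": float(b),
                    "se": float(s),
                    "n": int(n),
                    "mean_age": float(a),
                    "sd_age": 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text round trips

INDIVIDUAL_COLUMNS = ["study", "age", "snp", "y"]


def write_individual_csv(tables: Sequence[pd.DataFrame], path) -> None:
    pd.concat(tables, ignore_index=True)[INDIVIDUAL_COLUMNS].to_csv(path, index=False)


def read_individual_csv(path) -> list[pd.DataFrame]:
    df = pd.read_csv(path)
    missing = set(INDIVIDUAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"individual-level CSV missing columns: {sorted(missing)}")
    return [g.reset_index(drop=True) for _, g in df.groupby("study", sort=True)]


def load_config(path) -> tuple[SimDesign, ScenarioSpec]:
    """Read a YAML config with ``design:`` and ``scenario:`` sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return SimDesign.from_dict(cfg["design"]), ScenarioSpec.from_dict(cfg["scenario"])


def dump_config(design: SimDesign, spec: ScenarioSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"design": design.to_dict(), "scenario": spec.to_dict()}, fh)
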