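"""Meta-analysis and age-moment meta-regression of per-study SNP effects.

Given per-study effect estimates ``b_j`` with sampling variances ``s_j^2``,
this module fits

* fixed-effect meta-analysis: inverse-variance pooling under a common true
  effect, weights ``w_j = 1/s_j^2``;
* random-effects meta-analysis: ``b_j = mu + xi_j + eta_j`` with between-study
  variance ``tau^2`` estimated by restricted maximum likelihood (REML), weights
  ``1/(s_j^2 + tau^2)``;
* random-effects meta-regression on age moments: the per-study effect is
  modelled as a polynomial in age,

      b_j = c0 + c1*m1_j + c2*m2_j + c3*m3_j + xi_j + eta_j,

  where ``m_p`` is the study's mean of ``(age - centre)^p``.  The intercept is
  the SNP effect at the centring age and ``c1``, ``c2``, ``c3`` are the linear,
  quadratic and cubic SNP-by-age interaction coefficients.  Higher moments are
  derived from each study's reported mean and SD of age:
  ``mean(age^2) = SD^2 + mean^2``, and (assuming zero within-study age
  skewness) ``mean((age-c)^3) = (mean-c)^3 + 3*(mean-c)*SD^2``.

Heterogeneity is summarised by Cochran's ``Q`` (computed against the
fixed-effect-weighted moderator fit) and ``I^2 = max(0, (Q - df)/Q) * 100``;
for a meta-regression these are the residual statistics after the moderators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .studyfit import StudySummary

__all__ = [
    "MetaFit",
    "CollinearityError",
    "InsufficientStudiesError",
    "RemlConvergenceError",
    "derive_age_moments",
    "build_moderator_matrix",
    "reml_tau2",
    "fixed_effect_ma",
    "random_effects_ma",
    "meta_regression",
    "recentre",
    "heterogeneity",
    "predict_effect_at_age",
    "weighted_mean_age",
]

#: normal critical value for 95% Wald intervals
Z95 = 1.96

COEF_NAMES = ["beta_snp", "beta_snp_age", "beta_snp_age2", "beta_snp_age3"]


class InsufficientStudiesError(ValueError):
    """Fewer studies than the model has parameters (plus one)."""


class CollinearityError(ValueError):
    """Moderator matrix is rank deficient (e.g. all studies share one mean age)."""


class RemlConvergenceError(RuntimeError):
    """REML optimisation failed to converge; carries diagnostics."""


@dataclass
class MetaFit:
    """A fitted meta-analysis or meta-regression.

    ``coef`` holds the intercept (SNP effect at the centring age) followed by
    the interaction coefficients up to ``degree``.  ``tau2`` is the (residual)
    between-study variance, ``Q``/``I2`` the (residual) heterogeneity
    statistics, ``cov`` the coefficient covariance used for prediction bands.
    """

    model: str  # "fixed" | "random" | "metareg"
    degree: int
    centre: float
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    cov: np.ndarray
    tau2: float
    Q: float
    df: int
    I2: float
    k: int
    names: list[str] = field(default_factory=list)
    age_span: tuple[float, float] | None = None
    knapp_hartung: bool = False

    @property
    def estimate(self) -> float:
        """Pooled estimate / effect at the centring age (the intercept)."""
        return float(self.coef[0])

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "degree": self.degree,
            "centre": self.centre,
            "names": self.names,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "cov": self.cov.tolist(),
            "tau2": self.tau2,
            "Q": self.Q,
            "df": self.df,
            "I2": self.I2,
            "k": self.k,
            "age_span": list(self.age_span) if self.age_span else None,
            "knapp_hartung": self.knapp_hartung,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "MetaFit":
        d = dict(d)
        for key in ("coef", "se", "ci_low", "ci_high", "cov"):
            d[key] = np.asarray(d[key], dtype=float)
        if d.get("age_span"):
            d["age_span"] = tuple(d["age_span"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "MetaFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def text_report(self) -> str:
        lines = [
            f"{self.model} model, k={self.k} studies, degree={self.degree}, "
            f"centre={self.centre:g} years",
            f"tau^2 = {self.tau2:.6g}   Q = {self.Q:.4g} on {self.df} df   "
            f"I^2 = {self.I2:.2f}%",
            "",
            f"{'term':>14} {'estimate':>12} {'se':>10} {'95% CI':>24}",
        ]
        for name, b, s, lo, hi in zip(
            self.names, self.coef, self.se, self.ci_low, self.ci_high
        ):
            lines.append(
                f"{name:>14} {b:12.5g} {s:10.4g} [{lo:10.4g}, {hi:10.4g}]"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# moments and moderator matrices


def derive_age_moments(
    mean_age: float,
    sd_age: float,
    centre: float = 0.0,
    degree: int = 1,
    mean_age3: float | None = None,
) -> np.ndarray:
    """Centred age moments ``[m1, ..., m_degree]`` from a study's mean/SD of age.

    ``m_p = mean((age - centre)^p)``.  The second moment uses the identity
    ``mean(age^2) = sd^2 + mean^2`` as reported (sample-SD convention); the
    third assumes zero within-study age skewness (exact for uniform ages)
    unless the raw third moment ``mean_age3 = mean(age^3)`` is supplied.
    """
    if degree > 3:
        raise ValueError("degrees above 3 are not supported")
    if sd_age < 0:
        raise ValueError("sd_age must be >= 0")
    m1 = mean_age - centre
    out = [m1]
    if degree >= 2:
        out.append(sd_age**2 + m1**2)
    if degree >= 3:
        if mean_age3 is None:
            out.append(m1**3 + 3.0 * m1 * sd_age**2)
        else:
            raw2 = sd_age**2 + mean_age**2
            out.append(
                mean_age3
                - 3.0 * centre * raw2
                + 3.0 * centre**2 * mean_age
                - centre**3
            )
    return np.array(out[:degree], dtype=float)


def build_moderator_matrix(
    summaries: Sequence[StudySummary], degree: int, centre: float
) -> np.ndarray:
    """Stack ``[1, m1, ..., m_degree]`` rows for every study."""
    k = len(summaries)
    X = np.ones((k, degree + 1))
    for i, s in enumerate(summaries):
        if degree >= 1:
            X[i, 1:] = derive_age_moments(
                s.mean_age, s.sd_age, centre, degree, s.mean_age3
            )
    return X


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X, tol=1e-8 * max(1.0, np.abs(X).max())) < X.shape[1]:
        # identify offending columns: those not raising the rank
        bad = []
        rank = 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == rank:
                bad.append(j)
            rank = r
        names = [COEF_NAMES[j] if j < len(COEF_NAMES) else f"col{j}" for j in bad]
        raise CollinearityError(
            "moderator matrix is rank deficient; collinear columns: "
            + ", ".join(names)
            + " (all studies may share the same mean age)"
        )


# ---------------------------------------------------------------------------
# REML for the between-study variance


def _neg_restricted_ll(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    xtwx = (X * w[:, None]).T @ X
    beta = np.linalg.solve(xtwx, (X * w[:, None]).T @ y)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(xtwx)
    return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r * r))


def reml_tau2(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_tau2: float | None = None,
) -> float:
    """REML estimate of the between-study variance ``tau^2``.

    Maximises the restricted log-likelihood of ``y ~ N(X beta, diag(v) + tau2*I)``
    over ``tau2 >= 0`` by bounded scalar search; a negative unconstrained
    optimum is truncated at zero.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, p = X.shape
    if k <= p:
        raise InsufficientStudiesError(
            f"REML needs more studies ({k}) than fixed parameters ({p})"
        )
    if max_tau2 is None:
        max_tau2 = 1e3 * float(np.max(v))
    res = optimize.minimize_scalar(
        _neg_restricted_ll,
        bounds=(0.0, max_tau2),
        args=(y, v, X),
        method="bounded",
        options={"xatol": tol, "maxiter": 500},
    )
    if not res.success:  # pragma: no cover - bounded Brent essentially always converges
        raise RemlConvergenceError(
            f"REML did not converge after {res.nit} iterations: {res.message} "
            f"(bounds [0, {max_tau2:g}], last tau2 {res.x:g})"
        )
    # the bounded optimiser can stall a hair above an exact boundary optimum
    tau2 = float(res.x)
    if _neg_restricted_ll(0.0, y, v, X) <= res.fun:
        tau2 = 0.0
    return tau2


# ---------------------------------------------------------------------------
# fitting


def _extract(summaries: Sequence[StudySummary]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.beta1 for s in summaries], dtype=float)
    v = np.array([s.se**2 for s in summaries], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all studies must have se > 0 for meta-analysis")
    return y, v


def _residual_Q(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q against the fixed-effect-weighted moderator fit, df, I2."""
    w = 1.0 / v
    xtwx = (X * w[:, None]).T @ X
    beta = np.linalg.solve(xtwx, (X * w[:, None]).T @ y)
    r = y - X @ beta
    Q = float(np.sum(w * r * r))
    df = len(y) - X.shape[1]
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, df, I2


def _wls(
    y: np.ndarray, v: np.ndarray, X: np.ndarray, tau2: float
) -> tuple[np.ndarray, np.ndarray]:
    """GLS coefficients and covariance under marginal variances ``v + tau2``."""
    w = 1.0 / (v + tau2)
    xtwx = (X * w[:, None]).T @ X
    cov = np.linalg.inv(xtwx)
    beta = cov @ ((X * w[:, None]).T @ y)
    return beta, cov


def _assemble(
    model: str,
    degree: int,
    centre: float,
    beta: np.ndarray,
    cov: np.ndarray,
    tau2: float,
    Q: float,
    df: int,
    I2: float,
    summaries: Sequence[StudySummary],
    knapp_hartung: bool,
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
) -> MetaFit:
    k = len(summaries)
    se = np.sqrt(np.diag(cov))
    crit = Z95
    if knapp_hartung and df > 0:
        w = 1.0 / (v + tau2)
        r = y - X @ beta
        q = float(np.sum(w * r * r)) / df
        scale = np.sqrt(max(q, 1.0))  # truncated Knapp-Hartung
        se = se * scale
        cov = cov * scale**2
        crit = float(stats.t.ppf(0.975, df))
    ages = [s.mean_age for s in summaries]
    return MetaFit(
        model=model,
        degree=degree,
        centre=centre,
        coef=beta,
        se=se,
        ci_low=beta - crit * se,
        ci_high=beta + crit * se,
        cov=cov,
        tau2=tau2,
        Q=Q,
        df=df,
        I2=I2,
        k=k,
        names=COEF_NAMES[: degree + 1],
        age_span=(min(ages), max(ages)),
        knapp_hartung=knapp_hartung,
    )


def fixed_effect_ma(summaries: Sequence[StudySummary]) -> MetaFit:
    """Inverse-variance fixed-effect pooling (common-effect model)."""
    if len(summaries) < 2:
        raise InsufficientStudiesError("fixed-effect meta-analysis needs k >= 2")
    y, v = _extract(summaries)
    X = np.ones((len(y), 1))
    beta, cov = _wls(y, v, X, 0.0)
    Q, df, I2 = _residual_Q(y, v, X)
    return _assemble(
        "fixed", 0, 0.0, beta, cov, 0.0, Q, df, I2, summaries, False, y, v, X
    )


def random_effects_ma(
    summaries: Sequence[StudySummary], knapp_hartung: bool = False
) -> MetaFit:
    """REML random-effects pooling: weights ``1/(s_j^2 + tau2)``."""
    if len(summaries) < 2:
        raise InsufficientStudiesError("random-effects meta-analysis needs k >= 2")
    y, v = _extract(summaries)
    X = np.ones((len(y), 1))
    tau2 = reml_tau2(y, v, X)
    beta, cov = _wls(y, v, X, tau2)
    Q, df, I2 = _residual_Q(y, v, X)
    return _assemble(
        "random", 0, 0.0, beta, cov, tau2, Q, df, I2, summaries, knapp_hartung, y, v, X
    )


def meta_regression(
    summaries: Sequence[StudySummary],
    degree: int = 1,
    centre: float = 0.0,
    knapp_hartung: bool = False,
) -> MetaFit:
    """Random-effects meta-regression on derived age moments.

    ``degree`` 1-3 adds linear/quadratic/cubic age-interaction moderators;
    degree 0 reduces exactly to :func:`random_effects_ma`.  The intercept
    estimates the SNP effect at ``centre`` years.
    """
    if degree < 0 or degree > 3:
        raise ValueError("degree must be 0..3")
    if degree == 0:
        fit = random_effects_ma(summaries, knapp_hartung=knapp_hartung)
        fit.centre = centre
        return fit
    if len(summaries) <= degree + 1:
        raise InsufficientStudiesError(
            f"meta-regression of degree {degree} needs k > {degree + 1} studies"
        )
    y, v = _extract(summaries)
    X = build_moderator_matrix(summaries, degree, centre)
    _check_rank(X)
    tau2 = reml_tau2(y, v, X)
    beta, cov = _wls(y, v, X, tau2)
    Q, df, I2 = _residual_Q(y, v, X)
    return _assemble(
        "metareg", degree, centre, beta, cov, tau2, Q, df, I2,
        summaries, knapp_hartung, y, v, X,
    )


def recentre(
    fit: MetaFit, summaries: Sequence[StudySummary], new_centre: float
) -> MetaFit:
    """Refit the same meta-regression with age centred at ``new_centre``.

    Interaction coefficients are invariant to the centring age; only the
    intercept (and its SE) move, the intercept becoming the fitted polynomial
    evaluated at the new centre.
    """
    if fit.model != "metareg":
        raise ValueError("recentre applies to meta-regression fits")
    return meta_regression(
        summaries, degree=fit.degree, centre=new_centre,
        knapp_hartung=fit.knapp_hartung,
    )


def heterogeneity(fit: MetaFit) -> tuple[float, float]:
    """(Q, I2) of a fit; residual values for meta-regression models."""
    if fit.df < 1:
        raise ValueError("heterogeneity is undefined with zero residual df")
    return fit.Q, fit.I2


def predict_effect_at_age(fit: MetaFit, age_grid: Sequence[float]):
    """Fitted SNP effect and 95% band over an age grid.

    Evaluates the coefficient polynomial in powers of ``(age - centre)`` —
    derived moments matter only for fitting, not prediction — with delta-method
    SEs from the coefficient covariance.  Ages outside the span of the study
    mean ages are flagged as extrapolation in the ``extrapolated`` column.
    """
    import pandas as pd

    ages = np.asarray(age_grid, dtype=float)
    T = np.vander(ages - fit.centre, N=fit.degree + 1, increasing=True)
    eff = T @ fit.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", T, fit.cov, T))
    out = pd.DataFrame(
        {
            "age": ages,
            "effect": eff,
            "se": se,
            "ci_low": eff - Z95 * se,
            "ci_high": eff + Z95 * se,
        }
    )
    if fit.age_span is not None:
        out["extrapolated"] = (ages < fit.age_span[0]) | (ages > fit.age_span[1])
        out.attrs["age_span"] = fit.age_span
    return out


def weighted_mean_age(summaries: Sequence[StudySummary]) -> float:
    """Inverse-variance weighted mean age over all studies (centring option)."""
    w = np.array([1.0 / s.se**2 for s in summaries])
    a = np.array([s.mean_age for s in summaries])
    return float(np.sum(w * a) / np.sum(w))
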