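"""Generalized (covariance-aware) weights for overlapping samples.

When one cohort contributes effect estimates at several measurement occasions,
those estimates share participants and are therefore positively correlated;
treating the rows as independent understates meta-analytic standard errors.
This module builds a block-diagonal covariance matrix of the effect estimates
(blocks = cohorts) and fits the meta-regression by generalized least squares
with weight matrix ``(Sigma + tau2*I)^-1``, which reduces exactly to the
independent-rows fit when ``Sigma`` is diagonal.

When within-cohort correlations are not supplied, repeated measures on one
cohort default to ``r_jk = n_shared / sqrt(n_j n_k)`` with
``n_shared = min(n_j, n_k)`` — full overlap of the smaller occasion sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metamodels import (
    MetaFit,
    COEF_NAMES,
    InsufficientStudiesError,
    _check_rank,
    _residual_Q,
    build_moderator_matrix,
    Z95,
)
from .studyfit import StudySummary

__all__ = ["OverlapStructure", "build_covariance", "gls_meta_fit", "reml_tau2_gls"]


@dataclass
class OverlapStructure:
    """Occasion-row -> cohort mapping plus optional per-cohort correlations.

    ``correlations`` maps cohort id to a square correlation matrix over that
    cohort's rows (in row order); cohorts absent from the mapping use the
    shared-sample default rule.  Rows from different cohorts are independent.
    """

    cohort_of: Sequence[str]
    correlations: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_summaries(cls, summaries: Sequence[StudySummary]) -> "OverlapStructure":
        cohorts = [s.cohort_id for s in summaries]
        if any(c is None for c in cohorts):
            raise ValueError("every row needs a cohort_id to build an OverlapStructure")
        return cls(cohort_of=[str(c) for c in cohorts])

    @classmethod
    def from_csv(cls, mapping_path, correlation_path=None) -> "OverlapStructure":
        """Read an occasion->cohort two-column CSV (study_id, cohort_id), plus an
        optional long-format correlation CSV (cohort_id, row_i, row_j, r)."""
        mapping = pd.read_csv(mapping_path)
        cohorts = mapping["cohort_id"].astype(str).tolist()
        corrs: dict[str, np.ndarray] = {}
        if correlation_path is not None:
            long = pd.read_csv(correlation_path)
            for cid, grp in long.groupby("cohort_id"):
                m = int(max(grp["row_i"].max(), grp["row_j"].max())) + 1
                R = np.eye(m)
                for _, row in grp.iterrows():
                    i, j = int(row["row_i"]), int(row["row_j"])
                    R[i, j] = R[j, i] = float(row["r"])
                corrs[str(cid)] = R
        return cls(cohort_of=cohorts, correlations=corrs)


def _nearest_psd(block: np.ndarray) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    vals, vecs = np.linalg.eigh(block)
    clipped = np.clip(vals, 0.0, None)
    fixed = (vecs * clipped) @ vecs.T
    return fixed, float(np.linalg.norm(fixed - block))


def build_covariance(
    summaries: Sequence[StudySummary], structure: OverlapStructure
) -> np.ndarray:
    """Block-diagonal covariance of the effect estimates.

    Diagonal entries are the sampling variances ``s_j^2``; within-cohort
    off-diagonals are ``r_jk * s_j * s_k`` with ``r_jk`` from the structure's
    correlation matrix or, by default, ``min(n_j, n_k)/sqrt(n_j n_k)``.
    Non-PSD user-supplied blocks are projected to the nearest PSD matrix with
    a warning reporting the adjustment magnitude.
    """
    k = len(summaries)
    if len(structure.cohort_of) != k:
        raise ValueError("structure maps a different number of rows than summaries")
    s = np.array([x.se for x in summaries])
    n = np.array([x.n for x in summaries], dtype=float)
    cov = np.diag(s**2)
    cohorts = np.asarray(structure.cohort_of)
    for cid in dict.fromkeys(cohorts):  # preserve order
        idx = np.flatnonzero(cohorts == cid)
        if len(idx) < 2:
            continue
        if cid in structure.correlations:
            R = np.asarray(structure.correlations[cid], dtype=float)
            if R.shape != (len(idx), len(idx)):
                raise ValueError(
                    f"correlation matrix for cohort {cid} has shape {R.shape}, "
                    f"expected {(len(idx), len(idx))}"
                )
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError(
                    f"correlation matrix for cohort {cid} must be symmetric "
                    "with unit diagonal"
                )
        else:
            ni = n[idx]
            shared = np.minimum.outer(ni, ni)
            R = shared / np.sqrt(np.outer(ni, ni))
        block = R * np.outer(s[idx], s[idx])
        if np.linalg.eigvalsh(block).min() < -1e-10 * block.diagonal().max():
            block, delta = _nearest_psd(block)
            warnings.warn(
                f"cohort {cid}: correlation block not positive semi-definite; "
                f"projected to nearest PSD (Frobenius adjustment {delta:.3g})",
                stacklevel=2,
            )
        cov[np.ix_(idx, idx)] = block
    return cov


def _neg_restricted_ll_gls(
    tau2: float, y: np.ndarray, Sigma: np.ndarray, X: np.ndarray
) -> float:
    V = Sigma + tau2 * np.eye(len(y))
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    xtvx = Xw.T @ Xw
    beta = np.linalg.solve(xtvx, Xw.T @ yw)
    r = yw - Xw @ beta
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet_X = np.linalg.slogdet(xtvx)
    return 0.5 * (logdet_V + logdet_X + float(r @ r))


def reml_tau2_gls(
    y: np.ndarray, Sigma: np.ndarray, X: np.ndarray, tol: float = 1e-8
) -> float:
    """REML for tau2 under correlated sampling errors (whitened problem).

    Marginal model ``y ~ N(X beta, Sigma + tau2*I)``; scalar bounded search as
    in the diagonal case.  A singular ``Sigma`` is handled through the ridge
    the tau2 term provides away from zero.
    """
    from scipy import optimize

    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, p = X.shape
    if k <= p:
        raise InsufficientStudiesError(
            f"REML needs more rows ({k}) than fixed parameters ({p})"
        )
    max_tau2 = 1e3 * float(np.max(np.diag(Sigma)))
    # Sigma may be singular (perfectly redundant rows): nudge the lower bound
    eps = 0.0
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        eps = 1e-10 * float(np.max(np.diag(Sigma)))
    res = optimize.minimize_scalar(
        _neg_restricted_ll_gls,
        bounds=(eps, max_tau2),
        args=(y, Sigma, X),
        method="bounded",
        options={"xatol": tol, "maxiter": 500},
    )
    tau2 = float(res.x)
    if eps == 0.0 and _neg_restricted_ll_gls(0.0, y, Sigma, X) <= res.fun:
        tau2 = 0.0
    return tau2


def gls_meta_fit(
    summaries: Sequence[StudySummary],
    covariance: np.ndarray,
    degree: int = 0,
    centre: float = 0.0,
    tau2: float | None = None,
) -> MetaFit:
    """Meta-analysis / meta-regression by GLS under correlated effect estimates.

    Weight matrix ``(covariance + tau2*I)^-1`` with ``tau2`` REML-estimated on
    the whitened problem unless supplied.  With a diagonal covariance this
    reproduces the independent-rows fits to machine precision.  Q and I2 are
    reported with the standard independence-form statistic so they remain
    comparable with unadjusted fits.
    """
    k = len(summaries)
    if degree < 0 or degree > 3:
        raise ValueError("degree must be 0..3")
    if k <= degree + 1:
        raise InsufficientStudiesError(
            f"GLS fit of degree {degree} needs k > {degree + 1} rows"
        )
    covariance = np.asarray(covariance, dtype=float)
    if covariance.shape != (k, k):
        raise ValueError(f"covariance must be {k}x{k}")
    y = np.array([s.beta1 for s in summaries], dtype=float)
    v = np.array([s.se**2 for s in summaries], dtype=float)
    X = build_moderator_matrix(summaries, degree, centre)
    if degree >= 1:
        _check_rank(X)
    if tau2 is None:
        tau2 = reml_tau2_gls(y, covariance, X)
    V = covariance + tau2 * np.eye(k)
    cond = np.linalg.cond(V)
    if cond > 1e12:
        # perfectly redundant rows (r = 1) make V singular; the Moore-Penrose
        # limit reproduces the deduplicated fit, so fall back to it with notice
        warnings.warn(
            f"weight matrix nearly singular (condition number {cond:.3g}); "
            "using its pseudo-inverse (perfect-redundancy limit)",
            stacklevel=2,
        )
        Vi = np.linalg.pinv(V, hermitian=True)
        Vi_X = Vi @ X
    else:
        Vi_X = np.linalg.solve(V, X)
    xtvx = X.T @ Vi_X
    if np.linalg.cond(xtvx) > 1e12:
        raise np.linalg.LinAlgError(
            "normal-equations matrix is singular (condition number "
            f"{np.linalg.cond(xtvx):.3g}); the covariance leaves no information "
            "on some coefficient"
        )
    cov_beta = np.linalg.inv(xtvx)
    beta = cov_beta @ (Vi_X.T @ y)
    se = np.sqrt(np.diag(cov_beta))
    Q, df, I2 = _residual_Q(y, v, X)
    ages = [s.mean_age for s in summaries]
    return MetaFit(
        model="metareg" if degree else "random",
        degree=degree,
        centre=centre,
        coef=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        cov=cov_beta,
        tau2=float(tau2),
        Q=Q,
        df=df,
        I2=I2,
        k=k,
        names=COEF_NAMES[: degree + 1],
        age_span=(min(ages), max(ages)),
    )
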