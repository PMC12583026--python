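"""Night-to-night reliability of mean CVT.

Fits the random-intercept model

    y_ij = mu + beta_j + u_i + e_ij

with recording number as a categorical fixed effect and subject as the
random intercept, by REML, and reports the intraclass correlation
(between-subject share of total variance).  Subjects contributing a
single recording are excluded before fitting.

For a single random intercept the covariance V = sigma^2 (I + lambda ZZ')
is block diagonal with closed-form block inverses, so the REML criterion
profiles down to a one-dimensional search over the variance ratio
lambda = var_between / var_within.  This gives machine-precision
estimates (REML equals the ANOVA moment estimator on balanced designs)
without iterative matrix factorizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ICCResult", "fit_random_intercept", "icc"]


@dataclass(frozen=True)
class ICCResult:
    var_between: float
    var_within: float
    icc: float
    n_subjects: int
    n_observations: int
    fixed_effect_levels: int
    converged: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def icc(var_between: float, var_within: float) -> float:
    """Between-subject share of total variance."""
    if var_between < 0 or var_within < 0:
        raise ValueError("variance components must be >= 0")
    total = var_between + var_within
    if total == 0:
        raise ValueError("degenerate: both variance components are zero")
    return var_between / total


def _reml_criterion(lam: float, y, X, group_slices):
    """-2 profiled REML log-likelihood (up to a constant) at ratio lam.

    Uses the Woodbury form of each subject block:
    V_i^{-1} = I - lam/(1 + lam*n_i) * J.
    Returns (criterion, sigma2_hat).
    """
    n, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    logdet_v = 0.0
    for sl in group_slices:
        Xi, yi = X[sl], y[sl]
        ni = len(yi)
        c = lam / (1.0 + lam * ni)
        si = Xi.sum(axis=0)
        ti = yi.sum()
        A += Xi.T @ Xi - c * np.outer(si, si)
        b += Xi.T @ yi - c * si * ti
        q += yi @ yi - c * ti * ti
        logdet_v += np.log1p(lam * ni)
    beta = np.linalg.solve(A, b)
    rss = q - b @ beta
    sigma2 = max(rss / (n - p), 1e-300)
    sign, logdet_a = np.linalg.slogdet(A)
    crit = (n - p) * np.log(sigma2) + logdet_v + logdet_a
    return crit, sigma2


def fit_random_intercept(
    observations: pd.DataFrame,
    value_col: str = "mean_cvt",
    subject_col: str = "subject_id",
    recording_col: str = "recording_number",
    include_recording_effect: bool = True,
    maxiter: int = 500,
) -> ICCResult:
    """REML variance components for repeated mean-CVT observations.

    Handles unbalanced designs natively.  The between-subject variance
    is floored at zero (boundary REML solution).  Raises on fewer than
    two eligible subjects.
    """
    df = observations[[subject_col, recording_col, value_col]].dropna().copy()
    counts = df.groupby(subject_col)[value_col].size()
    eligible = counts[counts >= 2].index
    df = df[df[subject_col].isin(eligible)]
    n_subjects = df[subject_col].nunique()
    if n_subjects < 2:
        raise ValueError(
            f"need >= 2 subjects with >= 2 recordings each, got {n_subjects}"
        )
    df = df.sort_values([subject_col, recording_col], kind="stable")
    n_obs = len(df)
    levels = df[recording_col].nunique()

    y = df[value_col].to_numpy(dtype=float)
    if include_recording_effect and levels > 1:
        X = pd.get_dummies(
            df[recording_col].astype("category"), drop_first=True, dtype=float
        ).to_numpy()
        X = np.column_stack([np.ones(n_obs), X])
    else:
        X = np.ones((n_obs, 1))
    codes = pd.factorize(df[subject_col])[0]
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    edges = np.concatenate([[0], boundaries, [n_obs]])
    group_slices = [slice(int(a), int(z)) for a, z in zip(edges[:-1], edges[1:])]

    # Degenerate within-subject variance: the criterion diverges, so use
    # the closed form directly.
    centered = df[value_col] - df.groupby(subject_col)[value_col].transform("mean")
    if float(np.max(np.abs(centered))) < 1e-12:
        subj_means = df.groupby(subject_col)[value_col].mean().to_numpy()
        vb = float(np.var(subj_means, ddof=1))
        return ICCResult(vb, 0.0, icc(vb, 0.0), n_subjects, n_obs, levels)

    def objective(log_lam: float) -> float:
        return _reml_criterion(np.exp(log_lam), y, X, group_slices)[0]

    result = optimize.minimize_scalar(
        objective,
        bounds=(-30.0, 30.0),
        method="bounded",
        options={"xatol": 1e-12, "maxiter": maxiter},
    )
    if not result.success:
        raise RuntimeError(
            "REML did not converge: "
            f"{n_obs} observations, {n_subjects} subjects, {levels} fixed-effect levels"
        )
    lam = float(np.exp(result.x))
    crit_hat, sigma2 = _reml_criterion(lam, y, X, group_slices)
    crit_zero, sigma2_zero = _reml_criterion(0.0, y, X, group_slices)
    if crit_zero <= crit_hat:  # boundary solution: no between-subject variance
        lam, sigma2 = 0.0, sigma2_zero
    var_within = float(sigma2)
    var_between = float(lam * sigma2)
    return ICCResult(
        var_between=var_between,
        var_within=var_within,
        icc=icc(var_between, var_within),
        n_subjects=n_subjects,
        n_observations=n_obs,
        fixed_effect_levels=levels,
    )
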