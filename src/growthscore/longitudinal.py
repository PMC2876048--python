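"""Random-intercept mixed models for repeated growth SDS outcomes.

The longitudinal model for subject i at age t is

    y_it = x_it' beta + u_i + e_it,   u_i ~ N(0, sigma_u^2),  e_it ~ N(0, sigma_e^2)

with fixed effects including the risk-allele score, age, their
interaction (the per-year change in the per-allele effect) and sex.
Estimation is full maximum likelihood, not REML, so that models with
different fixed effects (the polynomial interaction checks) remain
comparable by likelihood.

The fit profiles the likelihood down to the single variance ratio
theta = sigma_u^2 / sigma_e^2: for fixed theta the GLS problem is an
OLS on partially group-mean-centred data (multiply each subject block
by V^{-1/2}, which shrinks the subject mean by 1 - 1/sqrt(1 + n_i
theta)), and sigma_e^2 maximizes in closed form.  A bounded scalar
search over theta then yields the exact ML solution, cheaply enough to
support simulation studies with hundreds of refits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))

SIX_WEEKS = 42 / 365.25

DEFAULT_TERMS = ("score", "age_years", "score:age_years", "sex")


class LongitudinalError(ValueError):
    pass


@dataclass
class MixedFit:
    """ML fit of a random-intercept linear mixed model."""

    params: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    sigma_u: float
    sigma_e: float
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool
    method: str = "ml"

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            }
        )


def _encode_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise LongitudinalError(f"model term refers to unknown column {name!r}")
    col = df[name]
    if col.dtype == object or str(col.dtype) == "category":
        if name == "sex":
            return (col == "female").to_numpy(float)
        raise LongitudinalError(f"cannot encode non-numeric column {name!r}")
    return col.to_numpy(float)


def build_design(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix from term strings.

    Terms are column names, optionally raised to an integer power with
    ``^`` and combined into products with ``:`` (e.g. ``score:age^2``).
    An intercept column is always prepended.  ``sex`` is coded 0/1
    (male = 0, female = 1).
    """
    X = pd.DataFrame({"const": np.ones(len(df))})
    for term in terms:
        out = np.ones(len(df))
        for factor in term.split(":"):
            if "^" in factor:
                name, power = factor.split("^")
                out = out * _encode_column(df, name) ** int(power)
            else:
                out = out * _encode_column(df, factor)
        X[term] = out
    return X


def _profile(theta: float, y, X, codes, counts):
    """Profile log-likelihood pieces at variance ratio theta."""
    n, p = X.shape
    shrink = 1.0 - 1.0 / np.sqrt(1.0 + counts * theta)
    ym = np.bincount(codes, weights=y) / counts
    yt = y - shrink[codes] * ym[codes]
    Xt = np.empty_like(X)
    for j in range(p):
        xm = np.bincount(codes, weights=X[:, j]) / counts
        Xt[:, j] = X[:, j] - shrink[codes] * xm[codes]
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * np.sum(
        np.log1p(counts * theta)
    )
    return loglik, beta, sigma2, Xt, rank


def fit_random_intercepts(
    obs: pd.DataFrame,
    terms=DEFAULT_TERMS,
    outcome: str = "sds",
    group: str = "subject_id",
    theta_max: float = 1e4,
    xatol: float = 1e-10,
) -> MixedFit:
    """ML fit of the random-intercept model ``outcome ~ terms + (1|group)``.

    Falls back to pooled OLS (with a warning) when no subject has more
    than one observation, in which case the intercept variance is not
    identified.
    """
    df = obs.dropna(subset=[outcome]).reset_index(drop=True)
    y = df[outcome].to_numpy(float)
    Xdf = build_design(df, terms)
    X = Xdf.to_numpy(float)
    # rescale columns to unit RMS: polynomial interaction terms span many
    # orders of magnitude and would otherwise degrade the normal equations
    col_scale = np.sqrt(np.mean(X**2, axis=0))
    col_scale[col_scale == 0] = 1.0
    X = X / col_scale
    codes, uniques = pd.factorize(df[group])
    counts = np.bincount(codes).astype(float)
    n, p = X.shape
    if n <= p:
        raise LongitudinalError("not enough observations for the model terms")

    if counts.max() < 2:
        warnings.warn(
            "no within-subject replication: random intercept not identified, "
            "falling back to pooled OLS",
            stacklevel=2,
        )
        return _ols_fallback(y, X, Xdf.columns, len(uniques), col_scale)

    def neg(theta):
        return -_profile(theta, y, X, codes, counts)[0]

    # coarse log-spaced sweep, then a bounded refinement around the best point
    grid = np.concatenate([[0.0], np.logspace(-8, np.log10(theta_max), 60)])
    values = np.array([neg(t) for t in grid])
    k = int(np.argmin(values))
    converged = True
    if k == 0:
        theta_hat = 0.0
    else:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": xatol, "maxiter": 500}
        )
        converged = bool(res.success)
        theta_hat = float(res.x) if res.fun <= values[k] else float(grid[k])
        if not converged:
            logger.warning("variance-ratio search did not report convergence; using best point")

    loglik, beta, sigma2, Xt, rank = _profile(theta_hat, y, X, codes, counts)
    if rank < p:
        raise LongitudinalError("rank-deficient fixed-effect design")
    cov = sigma2 * np.linalg.inv(Xt.T @ Xt)
    names = Xdf.columns
    params = pd.Series(beta / col_scale, index=names)
    se = pd.Series(np.sqrt(np.diag(cov)) / col_scale, index=names)
    z = params / se
    return MixedFit(
        params=params,
        se=se,
        ci_low=params - Z975 * se,
        ci_high=params + Z975 * se,
        p_values=pd.Series(2 * stats.norm.sf(np.abs(z)), index=names),
        sigma_u=float(np.sqrt(theta_hat * sigma2)),
        sigma_e=float(np.sqrt(sigma2)),
        loglik=float(loglik),
        n_obs=n,
        n_subjects=len(uniques),
        converged=converged,
        method="ml",
    )


def _ols_fallback(y, X, names, n_subjects, col_scale) -> MixedFit:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise LongitudinalError("rank-deficient fixed-effect design")
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = pd.Series(np.sqrt(np.diag(cov)) / col_scale, index=names)
    params = pd.Series(beta / col_scale, index=names)
    z = params / se
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return MixedFit(
        params=params,
        se=se,
        ci_low=params - Z975 * se,
        ci_high=params + Z975 * se,
        p_values=pd.Series(2 * stats.norm.sf(np.abs(z)), index=names),
        sigma_u=0.0,
        sigma_e=float(np.sqrt(sigma2)),
        loglik=float(loglik),
        n_obs=n,
        n_subjects=n_subjects,
        converged=True,
        method="ols_fallback",
    )


def piecewise_slopes(
    obs: pd.DataFrame,
    breakpoint_years: float = SIX_WEEKS,
    boundary_tol: float = 0.02,
    terms=DEFAULT_TERMS,
    **kwargs,
) -> tuple[MixedFit, MixedFit]:
    """Separate infancy and childhood score-by-age slopes.

    Two independent random-intercept fits restricted to ages at or below
    / at or above the breakpoint (default 6 weeks); measurements within
    ``boundary_tol`` years of the breakpoint — the 6-week visit itself —
    enter both windows.  When the frame carries a ``visit_age`` column
    (the nominal visit schedule), windows are defined on it, so a
    boundary visit belongs to both windows regardless of the jitter in
    its precise measurement age.  A window averaging fewer than two
    observations per subject triggers a warning (the within-subject
    information is thin there) but is still fitted by ML as long as
    some subjects are replicated.
    """
    window_age = obs["visit_age"] if "visit_age" in obs.columns else obs["age_years"]
    window_age = window_age.to_numpy(float)
    early = obs[window_age <= breakpoint_years + boundary_tol]
    late = obs[window_age >= breakpoint_years - boundary_tol]
    if early.empty and late.empty:
        raise LongitudinalError("no observations in either age window")
    if early.empty or late.empty:
        # all data on one side of the breakpoint: degenerate to a single fit
        warnings.warn("only one age window supplied; returning a single fit twice", stacklevel=2)
        fit = fit_random_intercepts(obs, terms=terms, **kwargs)
        return fit, fit
    fits = []
    for name, window in (("early", early), ("late", late)):
        per_subject = window.groupby("subject_id").size()
        if per_subject.mean() < 2:
            warnings.warn(
                f"{name} window averages {per_subject.mean():.2f} observations per subject; "
                "within-subject information is limited",
                stacklevel=2,
            )
        fits.append(fit_random_intercepts(window, terms=terms, **kwargs))
    return fits[0], fits[1]


def polynomial_interaction_test(
    obs: pd.DataFrame,
    max_degree: int = 3,
    base_terms=DEFAULT_TERMS,
    **kwargs,
) -> pd.Series:
    """Wald p-values for score x age^2 ... score x age^max_degree.

    The higher-order interaction terms are added jointly to the base
    model and each is tested by its Wald statistic in the extended fit.
    ``max_degree = 1`` returns an empty result (no terms beyond the
    linear interaction).
    """
    extra = [f"score:age_years^{d}" for d in range(2, max_degree + 1)]
    extra += [f"age_years^{d}" for d in range(2, max_degree + 1)]
    if max_degree < 2:
        return pd.Series(dtype=float)
    fit = fit_random_intercepts(obs, terms=tuple(base_terms) + tuple(extra), **kwargs)
    keep = [t for t in extra if t.startswith("score:")]
    return fit.p_values[keep]
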