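"""Cross-sectional association of the risk-allele score with outcomes.

Continuous outcomes (SDS or body-composition indices) are analysed by
ordinary least squares with the score as exposure plus configurable
covariates; binary outcomes (failure to thrive, overweight/obesity) by
maximum-likelihood logistic regression.  Effects are reported per risk
allele with Wald 95% confidence intervals (estimate +/- 1.96 SE) and
two-sided p-values, matching the symmetric intervals conventional in
this literature.  All analyses are complete-case.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))


class AssociationError(ValueError):
    pass


class SeparationError(AssociationError):
    """Complete separation: the logistic MLE does not exist."""


@dataclass
class AssocResult:
    outcome: str
    n: int
    effect_per_allele: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float

    def as_dict(self):
        return asdict(self)


@dataclass
class OddsResult:
    outcome: str
    n_cases: int
    n_total: int
    or_per_allele: float
    ci_low: float
    ci_high: float
    p_value: float

    def as_dict(self):
        return asdict(self)


def _design(score: np.ndarray, covariates: pd.DataFrame | None, n: int) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(n), "score": score})
    if covariates is not None and covariates.shape[1]:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    return X


def _check_design(X: pd.DataFrame) -> None:
    if np.ptp(X["score"].to_numpy()) == 0:
        raise AssociationError("score has no variance in the analysis sample")
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR: columns beyond the rank are the collinear ones
        from scipy.linalg import qr

        _, _, piv = qr(arr, mode="economic", pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise AssociationError(f"rank-deficient design; collinear columns: {bad}")


def _complete_cases(outcome, score, covariates):
    y = np.asarray(outcome, float)
    s = np.asarray(score, float)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        keep = np.isfinite(y) & np.isfinite(s) & np.isfinite(cov.to_numpy()).all(axis=1)
        cov = cov.loc[keep].reset_index(drop=True)
    else:
        cov = None
        keep = np.isfinite(y) & np.isfinite(s)
    return y[keep], s[keep], cov


def linear_assoc(
    outcome_sds,
    score,
    covariates: pd.DataFrame | None = None,
    label: str = "outcome",
) -> AssocResult:
    """Per-allele linear effect of the score on a continuous outcome.

    Least-squares slope with Wald 95% CI (normal approximation) and
    two-sided p-value; complete cases only.
    """
    y, s, cov = _complete_cases(outcome_sds, score, covariates)
    X = _design(s, cov, len(y))
    if len(y) <= X.shape[1]:
        raise AssociationError("not enough complete cases for the model terms")
    _check_design(X)
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params["score"])
    se = float(fit.bse["score"])
    p = 2 * float(stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return AssocResult(
        outcome=label,
        n=len(y),
        effect_per_allele=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        p_value=p,
    )


def per_age_profile(
    sds_table: pd.DataFrame,
    scores: pd.Series,
    ages,
    covariate_cols: tuple[str, ...] = ("sex",),
    measures=None,
    age_tol: float = 0.25,
    min_n: int = 50,
) -> pd.DataFrame:
    """Per-age, per-measure score coefficients (age-profile table).

    Each row of ``sds_table`` is assigned to the nearest nominal age in
    ``ages`` (within ``age_tol`` years); at each age x measure with at
    least ``min_n`` complete cases a linear model of SDS on the score is
    fitted, adjusted for the listed covariates plus precise age.  Sex is
    encoded 0/1 (male = 0).  Returns a tidy frame, one row per fit.
    """
    ages = np.asarray(sorted(ages), float)
    df = sds_table.copy()
    idx = np.abs(df["age_years"].to_numpy()[:, None] - ages[None, :]).argmin(axis=1)
    df["nominal_age"] = ages[idx]
    df = df[np.abs(df["age_years"] - df["nominal_age"]) <= age_tol]
    df = df.join(scores.rename("score"), on="subject_id")
    if measures is None:
        measures = sorted(df["measure"].unique())

    rows = []
    for measure in measures:
        for age in ages:
            block = df[(df["measure"] == measure) & (df["nominal_age"] == age)]
            block = block.dropna(subset=["sds", "score"])
            if len(block) < min_n:
                continue
            cov = pd.DataFrame({"age_years": block["age_years"].to_numpy(float)})
            for c in covariate_cols:
                col = block[c]
                cov[c] = (
                    (col == "female").to_numpy(float)
                    if c == "sex"
                    else col.to_numpy(float)
                )
            res = linear_assoc(
                block["sds"].to_numpy(float),
                block["score"].to_numpy(float),
                cov,
                label=f"{measure} SDS",
            )
            rows.append({"measure": measure, "age_years": float(age), **res.as_dict()})
    return pd.DataFrame(rows)


def logistic_assoc(
    binary_outcome,
    score,
    covariates: pd.DataFrame | None = None,
    label: str = "outcome",
) -> OddsResult:
    """Per-allele odds ratio for a binary outcome (ML logistic fit).

    Raises :class:`SeparationError` on complete separation rather than
    returning a silently non-converged fit.
    """
    y, s, cov = _complete_cases(np.asarray(binary_outcome, float), score, covariates)
    if len(np.unique(y)) < 2:
        raise AssociationError("both outcome classes must be present")
    X = _design(s, cov, len(y))
    _check_design(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed (separation?): {exc}") from exc
    beta = float(fit.params["score"])
    se = float(fit.bse["score"])
    if not fit.mle_retvals.get("converged", False) or se > 50 or abs(beta) > 50:
        raise SeparationError("logistic fit did not converge; likely complete separation")
    p = 2 * float(stats.norm.sf(abs(beta / se)))
    return OddsResult(
        outcome=label,
        n_cases=int(y.sum()),
        n_total=len(y),
        or_per_allele=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p_value=p,
    )


def variance_explained(outcome, score, covariates: pd.DataFrame | None = None) -> float:
    """Incremental R^2 of the score over the covariates-only model."""
    y, s, cov = _complete_cases(outcome, score, covariates)
    X_full = _design(s, cov, len(y))
    if len(y) <= X_full.shape[1]:
        raise AssociationError("not enough complete cases for the model terms")
    _check_design(X_full)
    X_base = X_full.drop(columns="score")
    r2_full = sm.OLS(y, X_full).fit().rsquared
    # intercept-only base model has R^2 = 0 by definition
    r2_base = sm.OLS(y, X_base).fit().rsquared if X_base.shape[1] > 1 else 0.0
    return float(max(r2_full - r2_base, 0.0))
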