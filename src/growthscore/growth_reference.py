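"""Age- and sex-standardized growth z-scores via the LMS method.

A growth reference is stored as age-indexed triples (L, M, S) per sex and
measure, where M is the median of the measurement at that age, S its
coefficient of variation, and L the Box-Cox power that removes skewness.
A raw value ``x`` maps to a standard deviation score (SDS)

    z = ((x / M)**L - 1) / (L * S)     for L != 0
    z = ln(x / M) / S                  for L == 0

and back via the exact inverse.  L, M and S are interpolated linearly in
age between tabulated grid points; no extrapolation beyond the grid is
performed.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
MEASURES = ("weight", "length_height", "bmi")

#: below this |L| the logarithmic branch of the LMS transform is used
L_SWITCH = 1e-12


class GrowthReferenceError(ValueError):
    """Invalid reference table or LMS transform input."""


class AgeOutOfRangeError(GrowthReferenceError):
    """Requested age lies outside the tabulated reference age grid."""


class ValidationError(GrowthReferenceError):
    """Input rows violate the measurement schema."""


class LMSReference:
    """LMS reference table: per sex x measure, (L, M, S) on an age grid.

    Parameters
    ----------
    table
        DataFrame with columns ``sex`` (male/female), ``measure``
        (weight/length_height/bmi), ``age_years``, ``L``, ``M``, ``S``.
        Each sex x measure block must have at least two strictly
        increasing ages, M > 0 and S > 0 everywhere.
    """

    REQUIRED_COLUMNS = ("sex", "measure", "age_years", "L", "M", "S")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.REQUIRED_COLUMNS) - set(table.columns)
        if missing:
            raise GrowthReferenceError(f"reference table missing columns: {sorted(missing)}")
        table = table.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        bad_sex = set(table["sex"]) - set(SEXES)
        if bad_sex:
            raise GrowthReferenceError(f"unknown sex codes in reference: {sorted(bad_sex)}")
        bad_measure = set(table["measure"]) - set(MEASURES)
        if bad_measure:
            raise GrowthReferenceError(f"unknown measures in reference: {sorted(bad_measure)}")

        self._blocks: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (sex, measure), block in table.groupby(["sex", "measure"], sort=True):
            block = block.sort_values("age_years")
            ages = block["age_years"].to_numpy(float)
            if len(ages) < 2:
                raise GrowthReferenceError(
                    f"reference block {sex}/{measure} needs >=2 age points, got {len(ages)}"
                )
            if not np.all(np.diff(ages) > 0):
                raise GrowthReferenceError(f"age grid not strictly increasing for {sex}/{measure}")
            M = block["M"].to_numpy(float)
            S = block["S"].to_numpy(float)
            if np.any(M <= 0) or np.any(S <= 0):
                raise GrowthReferenceError(f"M and S must be positive for {sex}/{measure}")
            self._blocks[(sex, measure)] = {
                "age": ages,
                "L": block["L"].to_numpy(float),
                "M": M,
                "S": S,
            }
        self.table = table.sort_values(["sex", "measure", "age_years"]).reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def keys(self) -> Iterable[tuple[str, str]]:
        return self._blocks.keys()

    def age_range(self, sex: str, measure: str) -> tuple[float, float]:
        block = self._block(sex, measure)
        return float(block["age"][0]), float(block["age"][-1])

    def _block(self, sex: str, measure: str) -> dict[str, np.ndarray]:
        try:
            return self._blocks[(sex, measure)]
        except KeyError:
            raise GrowthReferenceError(f"no reference block for sex={sex!r}, measure={measure!r}")

    def lookup(self, sex: str, measure: str, age_years):
        """Linearly interpolated (L, M, S) at ``age_years`` (scalar or array)."""
        block = self._block(sex, measure)
        age = np.asarray(age_years, float)
        lo, hi = block["age"][0], block["age"][-1]
        if np.any(age < lo) or np.any(age > hi):
            raise AgeOutOfRangeError(
                f"age outside reference grid [{lo:g}, {hi:g}] for {sex}/{measure}"
            )
        L = np.interp(age, block["age"], block["L"])
        M = np.interp(age, block["age"], block["M"])
        S = np.interp(age, block["age"], block["S"])
        if np.ndim(age_years) == 0:
            return float(L), float(M), float(S)
        return L, M, S


def interpolate_lms(ref: LMSReference, sex: str, measure: str, age_years):
    """(L, M, S) at a precise age, linear in age; exact at grid points."""
    return ref.lookup(sex, measure, age_years)


def to_sds(value, L, M, S):
    """LMS transform of raw value(s) to standard deviation score(s).

    Uses the logarithmic branch for |L| < 1e-12, which is the continuous
    limit of the power branch.
    """
    value = np.asarray(value, float)
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    if np.any(value <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise GrowthReferenceError("to_sds requires value > 0, M > 0, S > 0")
    ratio = value / M
    small_L = np.abs(L) < L_SWITCH
    L_safe = np.where(small_L, 1.0, L)
    # expm1 keeps the power branch accurate as L -> 0 (no cancellation)
    z = np.where(
        small_L,
        np.log(ratio) / S,
        np.expm1(L * np.log(ratio)) / (L_safe * S),
    )
    return float(z) if z.ndim == 0 else z


def from_sds(sds, L, M, S):
    """Inverse LMS transform: SDS back to the measurement scale.

    Undefined where ``1 + L*S*z <= 0`` (the Box-Cox inverse leaves the
    positive half-line); such inputs raise.
    """
    z = np.asarray(sds, float)
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise GrowthReferenceError("from_sds requires M > 0, S > 0")
    small_L = np.abs(L) < L_SWITCH
    base = 1.0 + L * S * z
    if np.any(~small_L & (base <= 0)):
        raise GrowthReferenceError("from_sds undefined: 1 + L*S*z <= 0")
    L_safe = np.where(small_L, 1.0, L)
    base = np.where(small_L, 1.0, L_safe * S * z)
    # log1p mirrors the expm1 of the forward transform
    value = np.where(
        small_L,
        M * np.exp(S * z),
        M * np.exp(np.log1p(base) / L_safe),
    )
    return float(value) if value.ndim == 0 else value


MEASUREMENT_COLUMNS = ("subject_id", "sex", "age_years", "measure", "value")


def standardize_cohort(
    measurements: pd.DataFrame,
    ref: LMSReference,
    return_excluded: bool = False,
):
    """Convert a long-format anthropometry table to an SDS table.

    Parameters
    ----------
    measurements
        Long format with columns ``subject_id, sex, age_years, measure,
        value``; extra columns (e.g. a nominal visit age) are carried
        through unchanged.
    ref
        LMS reference resolving every (sex, measure) present.
    return_excluded
        Also return the rows excluded because their age falls outside
        the reference grid.

    Returns
    -------
    DataFrame with the input key columns plus ``sds``; rows whose age is
    outside the reference grid are excluded with a logged count.  Unknown
    sex or measure codes raise :class:`ValidationError` listing the
    offending rows.
    """
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValidationError(f"measurement table missing columns: {sorted(missing)}")
    df = measurements.copy()

    bad = df.index[~df["sex"].isin(SEXES) | ~df["measure"].isin(MEASURES)]
    if len(bad):
        raise ValidationError(
            f"unknown sex/measure codes in rows (index): {list(bad[:20])}"
            + ("..." if len(bad) > 20 else "")
        )
    if np.any(df["value"].to_numpy(float) <= 0):
        bad = df.index[df["value"] <= 0]
        raise ValidationError(f"non-positive measurement values in rows (index): {list(bad[:20])}")

    if df.empty:
        out = df.copy()
        out["sds"] = pd.Series(dtype=float)
        return (out, out.iloc[0:0]) if return_excluded else out

    sds = np.full(len(df), np.nan)
    in_range = np.zeros(len(df), bool)
    pos = {idx: i for i, idx in enumerate(df.index)}
    for (sex, measure), block in df.groupby(["sex", "measure"], sort=False):
        lo, hi = ref.age_range(sex, measure)
        ages = block["age_years"].to_numpy(float)
        ok = (ages >= lo) & (ages <= hi)
        rows = np.array([pos[idx] for idx in block.index])
        in_range[rows[ok]] = True
        if ok.any():
            L, M, S = ref.lookup(sex, measure, ages[ok])
            sds[rows[ok]] = to_sds(block["value"].to_numpy(float)[ok], L, M, S)

    n_excluded = int((~in_range).sum())
    if n_excluded:
        logger.warning(
            "standardize_cohort: excluded %d row(s) with age outside the reference grid",
            n_excluded,
        )
    out = df.loc[in_range].copy()
    out["sds"] = sds[in_range]
    if return_excluded:
        return out, df.loc[~in_range].copy()
    return out
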