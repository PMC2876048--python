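"""Derived body-size indices and overweight/obesity classification.

BMI and the fat-mass / fat-free-mass indices are mass (kg) divided by
height squared (m^2).  Childhood overweight and obesity are classified
against sex- and age-specific BMI cutoff curves that pass through
25 and 30 kg/m^2 at age 18 (IOTF-style); the cutoffs are interpolated
at the child's exact age and the boundaries are inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class AnthropometryError(ValueError):
    pass


class CutoffAgeError(AnthropometryError):
    """Age outside the cutoff-curve grid."""


def bmi(weight_kg, height_m):
    """Body mass index, weight (kg) / height^2 (m^2)."""
    return mass_index(weight_kg, height_m)


def mass_index(mass_kg, height_m):
    """Mass (kg) divided by height squared (m^2); FMI/FFMI and BMI alike."""
    mass = np.asarray(mass_kg, float)
    height = np.asarray(height_m, float)
    if np.any(height <= 0):
        raise AnthropometryError("height must be positive")
    if np.any(mass < 0):
        raise AnthropometryError("mass must be non-negative")
    out = mass / height**2
    return float(out) if out.ndim == 0 else out


class CutoffCurves:
    """Sex- and age-specific BMI cutoffs for overweight and obesity.

    Table columns: ``sex, age_years, bmi_overweight_cutoff,
    bmi_obese_cutoff``.  Invariants: the obese cutoff exceeds the
    overweight cutoff at every age, and where the grid reaches age 18
    the curves equal 25 and 30 kg/m^2 there.
    """

    REQUIRED_COLUMNS = ("sex", "age_years", "bmi_overweight_cutoff", "bmi_obese_cutoff")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.REQUIRED_COLUMNS) - set(table.columns)
        if missing:
            raise AnthropometryError(f"cutoff table missing columns: {sorted(missing)}")
        self._blocks: dict[str, dict[str, np.ndarray]] = {}
        for sex, block in table.groupby("sex"):
            block = block.sort_values("age_years")
            ages = block["age_years"].to_numpy(float)
            over = block["bmi_overweight_cutoff"].to_numpy(float)
            obese = block["bmi_obese_cutoff"].to_numpy(float)
            if not np.all(np.diff(ages) > 0):
                raise AnthropometryError(f"cutoff age grid not strictly increasing for {sex}")
            if not np.all(obese > over):
                raise AnthropometryError(f"obese cutoff must exceed overweight cutoff ({sex})")
            if ages[0] <= 18.0 <= ages[-1]:
                o18 = np.interp(18.0, ages, over)
                b18 = np.interp(18.0, ages, obese)
                if abs(o18 - 25.0) > 1e-6 or abs(b18 - 30.0) > 1e-6:
                    raise AnthropometryError(
                        f"cutoff curves must pass through 25/30 kg/m^2 at age 18 ({sex}): "
                        f"got {o18:.3f}/{b18:.3f}"
                    )
            self._blocks[sex] = {"age": ages, "over": over, "obese": obese}
        self.table = table.sort_values(["sex", "age_years"]).reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CutoffCurves":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def cutoffs(self, sex: str, age_years):
        """Interpolated (overweight, obese) BMI cutoffs at exact age."""
        if sex not in self._blocks:
            raise AnthropometryError(f"no cutoff curves for sex={sex!r}")
        block = self._blocks[sex]
        age = np.asarray(age_years, float)
        if np.any(age < block["age"][0]) or np.any(age > block["age"][-1]):
            raise CutoffAgeError(
                f"age outside cutoff grid [{block['age'][0]:g}, {block['age'][-1]:g}]"
            )
        over = np.interp(age, block["age"], block["over"])
        obese = np.interp(age, block["age"], block["obese"])
        return (float(over), float(obese)) if age.ndim == 0 else (over, obese)


CATEGORIES = ("normal", "overweight", "obese")


def iotf_classify(bmi_value, age_years, sex, curves: CutoffCurves):
    """Classify BMI as normal / overweight / obese at exact age.

    Boundaries are inclusive: BMI at or above a cutoff takes the higher
    category, so at age 18 a BMI of exactly 25 (30) is overweight
    (obese).
    """
    over, obese = curves.cutoffs(sex, age_years)
    b = np.asarray(bmi_value, float)
    out = np.where(b >= obese, "obese", np.where(b >= over, "overweight", "normal"))
    return str(out) if out.ndim == 0 else out


def classify_cohort(df: pd.DataFrame, curves: CutoffCurves) -> pd.Series:
    """Row-wise IOTF-style category for a frame with bmi, age_years, sex."""
    cats = pd.Series(index=df.index, dtype=object)
    for sex, block in df.groupby("sex"):
        cats.loc[block.index] = iotf_classify(
            block["bmi"].to_numpy(float), block["age_years"].to_numpy(float), sex, curves
        )
    return cats
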