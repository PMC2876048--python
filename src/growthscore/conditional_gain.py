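"""Conditional infancy weight gain and failure-to-thrive flagging.

Raw change in weight SDS from birth regresses to the mean: lighter
newborns catch up and heavier ones cross downward even without any true
signal.  Conditional weight gain removes this by standardizing the
follow-up SDS against its regression on the baseline:

    gain = (SDS_followup - r * SDS_baseline) / sqrt(1 - r^2)

where r is the population correlation between baseline and follow-up
weight SDS, estimated within the analysis sample itself.  When both SDS
columns have unit variance the gain is uncorrelated with baseline and
itself has unit variance.  Failure to thrive is membership in the
slowest 5% of conditional gain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ConditionalGainError(ValueError):
    pass


def extract_pairs(
    sds_table: pd.DataFrame,
    baseline_age: float = 0.0,
    followup_age: float = 42 / 365.25,
    measure: str = "weight",
    age_tol: float = 0.05,
) -> pd.DataFrame:
    """Pair each subject's baseline and follow-up weight SDS.

    Rows of ``sds_table`` (columns subject_id, age_years, measure, sds)
    within ``age_tol`` years of each target age are used; if a subject
    has several, the closest to the target age wins.  When the table
    carries a ``visit_age`` column (nominal visit schedule), rows are
    matched on it exactly instead, which is robust to jittered precise
    ages.  Only complete pairs are returned.
    """
    rows = sds_table[sds_table["measure"] == measure]
    by_visit = "visit_age" in rows.columns

    def closest(target):
        if by_visit:
            near = rows[np.isclose(rows["visit_age"], target, atol=1e-9)].copy()
        else:
            near = rows[np.abs(rows["age_years"] - target) <= age_tol].copy()
        near["_dist"] = np.abs(near["age_years"] - target)
        near = near.sort_values("_dist").drop_duplicates("subject_id")
        return near.set_index("subject_id")["sds"]

    base = closest(baseline_age)
    follow = closest(followup_age)
    pairs = pd.DataFrame({"sds_baseline": base, "sds_followup": follow}).dropna()
    pairs.index.name = "subject_id"
    return pairs.reset_index()


def estimate_r(pairs: pd.DataFrame) -> float:
    """Pearson correlation between baseline and follow-up SDS."""
    b = pairs["sds_baseline"].to_numpy(float)
    f = pairs["sds_followup"].to_numpy(float)
    if len(b) < 3:
        raise ConditionalGainError("need >= 3 complete pairs to estimate r")
    if np.std(b) == 0 or np.std(f) == 0:
        raise ConditionalGainError("degenerate variance: cannot estimate correlation")
    return float(np.corrcoef(b, f)[0, 1])


def conditional_gain(pairs: pd.DataFrame, r: float) -> pd.DataFrame:
    """Regression-to-the-mean-corrected weight gain from birth.

    Returns the input frame with an ``sds_gain`` column.  Requires
    |r| < 1 (at |r| = 1 the conditional distribution is degenerate).
    """
    if not abs(r) < 1:
        raise ConditionalGainError("conditional gain undefined for |r| >= 1")
    out = pairs.copy()
    out["sds_gain"] = (out["sds_followup"] - r * out["sds_baseline"]) / np.sqrt(1 - r**2)
    return out


def flag_failure_to_thrive(gains, quantile: float = 0.05) -> np.ndarray:
    """Flag the slowest ``quantile`` of conditional gains.

    The threshold is the empirical quantile with linear interpolation
    between order statistics; ties at the threshold are all flagged
    (conservative toward flagging).  Refuses fewer than 20 values, where
    the 5th percentile is unstable.
    """
    g = np.asarray(gains, float)
    if len(g) < 20:
        raise ConditionalGainError("need >= 20 gains to flag failure to thrive")
    threshold = float(np.quantile(g, quantile))
    flags = g <= threshold
    if flags.all():
        logger.warning("flag_failure_to_thrive: all gains tie at the threshold; all flagged")
    return flags


def conditional_gain_analysis(
    sds_table: pd.DataFrame,
    baseline_age: float = 0.0,
    followup_age: float = 42 / 365.25,
    quantile: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Full conditional-gain stage: pair, estimate r, compute gain, flag.

    Returns (frame with subject_id, sds_baseline, sds_followup,
    sds_gain, ftt_flag; estimated r).
    """
    pairs = extract_pairs(sds_table, baseline_age, followup_age)
    r = estimate_r(pairs)
    out = conditional_gain(pairs, r)
    out["ftt_flag"] = flag_failure_to_thrive(out["sds_gain"].to_numpy(), quantile)
    return out, r
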