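"""LMS transform, interpolation and cohort standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import growthscore as gs
from growthscore.growth_reference import (
    AgeOutOfRangeError,
    GrowthReferenceError,
    ValidationError,
)


def brute_force_interp(ages, values, x):
    """Independent piecewise-linear oracle: locate the bracketing segment."""
    for i in range(len(ages) - 1):
        if ages[i] <= x <= ages[i + 1]:
            frac = (x - ages[i]) / (ages[i + 1] - ages[i])
            return values[i] * (1 - frac) + values[i + 1] * frac
    raise AssertionError("x outside grid")


class TestInterpolateLMS:
    def test_grid_point_identity(self, reference):
        block = reference.table.query("sex == 'male' and measure == 'weight'")
        row = block.iloc[5]
        L, M, S = gs.interpolate_lms(reference, "male", "weight", row["age_years"])
        assert (L, M, S) == (row["L"], row["M"], row["S"])

    def test_midpoint_is_mean_of_neighbours(self, reference):
        block = reference.table.query("sex == 'female' and measure == 'weight'")
        a, b = block.iloc[3], block.iloc[4]
        mid = (a["age_years"] + b["age_years"]) / 2
        L, M, S = gs.interpolate_lms(reference, "female", "weight", mid)
        assert M == pytest.approx((a["M"] + b["M"]) / 2, abs=1e-12)
        assert S == pytest.approx((a["S"] + b["S"]) / 2, abs=1e-12)

    def test_matches_brute_force_oracle(self, reference):
        rng = np.random.default_rng(0)
        block = reference.table.query("sex == 'male' and measure == 'length_height'")
        ages = block["age_years"].to_numpy()
        Ms = block["M"].to_numpy()
        for x in rng.uniform(ages[0], ages[-1], 50):
            _, M, _ = gs.interpolate_lms(reference, "male", "length_height", x)
            assert M == pytest.approx(brute_force_interp(ages, Ms, x), rel=1e-12)

    def test_out_of_range_raises(self, reference):
        with pytest.raises(AgeOutOfRangeError):
            gs.interpolate_lms(reference, "male", "weight", 99.0)


class TestLMSTransform:
    def test_median_maps_to_zero(self):
        assert gs.to_sds(12.0, -0.3, 12.0, 0.1) == pytest.approx(0.0)

    def test_linear_case(self):
        # L = 1: z = (x/M - 1)/S, so x = M(1+S) gives exactly 1
        assert gs.to_sds(11.0 * 1.1, 1.0, 11.0, 0.1) == pytest.approx(1.0)

    def test_log_branch_is_continuous_limit(self):
        # the two branches differ by O(L * ln^2(x/M) / S); near the median
        # this is far below 1e-8 at |L| = 1e-6
        value, M, S = 7.6, 7.5, 0.12
        z_log = np.log(value / M) / S
        for L in (1e-6, -1e-6):
            assert gs.to_sds(value, L, M, S) == pytest.approx(z_log, abs=1e-8)

    def test_power_branch_converges_to_log_branch(self):
        value, M, S = 9.0, 7.5, 0.12
        z_log = np.log(value / M) / S
        errors = [abs(gs.to_sds(value, L, M, S) - z_log) for L in (1e-2, 1e-4, 1e-6)]
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-6

    def test_domain_errors(self):
        with pytest.raises(GrowthReferenceError):
            gs.to_sds(-1.0, 1.0, 10.0, 0.1)
        with pytest.raises(GrowthReferenceError):
            gs.to_sds(5.0, 1.0, 10.0, -0.1)

    def test_inverse_trivials(self):
        assert gs.from_sds(0.0, -0.5, 8.0, 0.1) == pytest.approx(8.0)
        assert gs.from_sds(1.0, 1.0, 8.0, 0.1) == pytest.approx(8.0 * 1.1)

    def test_inverse_domain_error(self):
        # L*S*z = -2 < -1
        with pytest.raises(GrowthReferenceError):
            gs.from_sds(-20.0, 1.0, 10.0, 0.1)

    def test_round_trip_random_tuples(self):
        rng = np.random.default_rng(1)
        n = 1000
        L = rng.uniform(-3, 3, n)
        M = rng.uniform(0.5, 50, n)
        S = rng.uniform(0.05, 0.2, n)
        z = rng.normal(0, 1.5, n)
        valid = (np.abs(L) < 1e-12) | (1 + L * S * z > 1e-6)
        L, M, S, z = L[valid], M[valid], S[valid], z[valid]
        x = gs.from_sds(z, L, M, S)
        assert np.max(np.abs(gs.to_sds(x, L, M, S) - z)) < 1e-9

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        L=st.floats(-3, 3),
        M=st.floats(0.5, 60),
        S=st.floats(0.05, 0.2),
        z=st.floats(-3, 3),
    )
    def test_round_trip_property(self, L, M, S, z):
        if abs(L) >= 1e-12 and 1 + L * S * z <= 1e-6:
            return
        x = gs.from_sds(z, L, M, S)
        assert gs.to_sds(x, L, M, S) == pytest.approx(z, abs=1e-9)


class TestStandardizeCohort:
    def test_reference_median_curve_is_zero(self, reference):
        # feeding the reference's own median column back through yields 0
        block = reference.table.query("sex == 'female' and measure == 'weight'")
        meas = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(block))],
                "sex": "female",
                "age_years": block["age_years"].to_numpy(),
                "measure": "weight",
                "value": block["M"].to_numpy(),
            }
        )
        sds = gs.standardize_cohort(meas, reference)
        assert np.max(np.abs(sds["sds"])) < 1e-12

    def test_empty_input(self, reference):
        empty = pd.DataFrame(
            columns=["subject_id", "sex", "age_years", "measure", "value"]
        )
        out = gs.standardize_cohort(empty, reference)
        assert out.empty and "sds" in out.columns

    def test_unknown_codes_raise_listing_rows(self, reference):
        meas = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "sex": ["male", "martian"],
                "age_years": [1.0, 1.0],
                "measure": ["weight", "weight"],
                "value": [10.0, 10.0],
            }
        )
        with pytest.raises(ValidationError, match="1"):
            gs.standardize_cohort(meas, reference)

    def test_out_of_range_rows_flagged_not_silently_dropped(self, reference):
        meas = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "sex": ["male", "male"],
                "age_years": [1.0, 50.0],
                "measure": ["weight", "weight"],
                "value": [11.0, 60.0],
            }
        )
        out, excluded = gs.standardize_cohort(meas, reference, return_excluded=True)
        assert len(out) == 1 and len(excluded) == 1
        assert excluded.iloc[0]["subject_id"] == "b"

    def test_null_cohort_recovers_standard_normal(self, null_cohort):
        """Latent SDS ~ N(0,1) per age; the round trip must preserve it."""
        sds = null_cohort["sds"]
        weight = sds[sds["measure"] == "weight"]
        for _, block in weight.groupby("visit_age"):
            n = len(block)
            assert n >= 1000
            assert abs(block["sds"].mean()) < 4 / np.sqrt(n)
            assert 0.9 <= block["sds"].std() <= 1.1
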