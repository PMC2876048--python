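"""Random-intercept mixed models: ML correctness and model checks."""

import warnings

import numpy as np
import pandas as pd
import pytest

import growthscore as gs
from growthscore.longitudinal import LongitudinalError, build_design

from conftest import make_long_obs


class TestBuildDesign:
    def test_terms_products_and_powers(self):
        df = pd.DataFrame({"score": [2.0, 3.0], "age_years": [1.0, 2.0],
                           "sex": ["male", "female"]})
        X = build_design(df, ("score", "age_years^2", "score:age_years", "sex"))
        np.testing.assert_allclose(X["const"], [1, 1])
        np.testing.assert_allclose(X["age_years^2"], [1.0, 4.0])
        np.testing.assert_allclose(X["score:age_years"], [2.0, 6.0])
        np.testing.assert_allclose(X["sex"], [0.0, 1.0])

    def test_unknown_column_raises(self):
        with pytest.raises(LongitudinalError):
            build_design(pd.DataFrame({"a": [1.0]}), ("b",))


class TestFitRandomIntercepts:
    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM with full ML."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(10)
        obs = make_long_obs(rng, n_subjects=250, interaction=0.01, score_effect=0.02)
        fit = gs.fit_random_intercepts(obs)

        df = obs.assign(sexf=(obs.sex == "female").astype(float),
                        inter=obs.score * obs.age_years)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oracle = smf.mixedlm(
                "sds ~ score + age_years + inter + sexf", df, groups=df.subject_id
            ).fit(reml=False)
        np.testing.assert_allclose(
            fit.params.to_numpy(),
            oracle.params[["Intercept", "score", "age_years", "inter", "sexf"]].to_numpy(),
            atol=1e-5,
        )
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        assert fit.sigma_e == pytest.approx(np.sqrt(oracle.scale), abs=1e-4)
        assert fit.sigma_u == pytest.approx(np.sqrt(oracle.cov_re.iloc[0, 0]), abs=1e-3)

    def test_no_clustering_limit_equals_pooled_ols(self):
        """sigma_u = 0 data: fixed effects must collapse to pooled OLS."""
        rng = np.random.default_rng(11)
        for seed_rep in range(3):
            obs = make_long_obs(rng, n_subjects=200, sigma_u=0.0, interaction=0.005)
            fit = gs.fit_random_intercepts(obs)
            X = build_design(obs, ("score", "age_years", "score:age_years", "sex"))
            beta_ols = np.linalg.lstsq(X.to_numpy(), obs["sds"].to_numpy(), rcond=None)[0]
            np.testing.assert_allclose(fit.params.to_numpy(), beta_ols, atol=1e-4)

    def test_balanced_two_visit_closed_form(self):
        """Closed-form ML for the balanced one-way design.

        With N groups of m observations and only an intercept, the ML
        solution is sigma_e^2 = W/(N(m-1)) and sigma_e^2 + m*sigma_u^2
        = B/N, where W and B are the within and between sums of squares
        about the grand mean.
        """
        rng = np.random.default_rng(12)
        N, m = 400, 2
        u = rng.normal(0, 0.7, N)
        y = (u[:, None] + rng.normal(0, 0.5, (N, m))).ravel()
        obs = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(N), m),
                "age_years": np.tile([0.0, 1.0], N),
                "sds": y,
            }
        )
        fit = gs.fit_random_intercepts(obs, terms=())
        ybar_i = y.reshape(N, m).mean(axis=1)
        W = float(((y.reshape(N, m) - ybar_i[:, None]) ** 2).sum())
        B = float((m * (ybar_i - y.mean()) ** 2).sum())
        sigma_e2 = W / (N * (m - 1))
        sigma_u2 = (B / N - sigma_e2) / m
        assert fit.sigma_e**2 == pytest.approx(sigma_e2, abs=1e-6)
        assert fit.sigma_u**2 == pytest.approx(sigma_u2, abs=1e-6)
        assert fit.params["const"] == pytest.approx(y.mean(), abs=1e-10)

    def test_nested_loglik_ordering(self):
        rng = np.random.default_rng(13)
        obs = make_long_obs(rng, n_subjects=150, interaction=0.01)
        full = gs.fit_random_intercepts(obs)
        reduced = gs.fit_random_intercepts(obs, terms=("score", "age_years", "sex"))
        assert full.loglik >= reduced.loglik

    def test_invariant_to_relabeling_and_row_order(self):
        rng = np.random.default_rng(14)
        obs = make_long_obs(rng, n_subjects=120, interaction=0.01)
        fit = gs.fit_random_intercepts(obs)
        shuffled = obs.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled["subject_id"] = "Z" + shuffled["subject_id"].astype(str)
        fit2 = gs.fit_random_intercepts(shuffled)
        np.testing.assert_allclose(fit.params.to_numpy(), fit2.params.to_numpy(), atol=1e-8)
        # variance components agree to optimizer precision
        assert fit.sigma_u == pytest.approx(fit2.sigma_u, abs=1e-6)

    def test_singleton_groups_fall_back_to_ols(self):
        rng = np.random.default_rng(15)
        obs = make_long_obs(rng, n_subjects=200, ages=(9.0,))
        obs["age_years"] += rng.normal(0, 0.05, len(obs))
        with pytest.warns(UserWarning, match="replication"):
            fit = gs.fit_random_intercepts(obs)
        assert fit.method == "ols_fallback"
        assert fit.sigma_u == 0.0


class TestPiecewiseSlopes:
    def test_slope_ordering_recovered(self):
        """Steep infancy slope vs slow childhood slope on one dataset."""
        rng = np.random.default_rng(16)
        ages = (0.0, 42 / 365.25, 0.75, 1.5, 3.5, 7.0, 9.0, 11.0)
        rows = []
        for i in range(3000):
            score = rng.binomial(2, 0.4, 8).sum()
            u = rng.normal(0, 0.8)
            for t in ages:
                g = 0.12 * min(t, 42 / 365.25) + 0.004 * max(t - 42 / 365.25, 0.0)
                rows.append({"subject_id": i, "age_years": t, "score": float(score),
                             "sex": "male" if i % 2 else "female",
                             "sds": u + g * score + rng.normal(0, 0.6)})
        obs = pd.DataFrame(rows)
        early, late = gs.piecewise_slopes(obs)
        assert early.params["score:age_years"] > late.params["score:age_years"]
        assert late.params["score:age_years"] == pytest.approx(0.004, abs=0.002)

    def test_single_window_degenerates_to_plain_fit(self):
        rng = np.random.default_rng(17)
        obs = make_long_obs(rng, n_subjects=100, ages=(1.0, 3.0, 7.0))
        with pytest.warns(UserWarning, match="one age window"):
            early, late = gs.piecewise_slopes(obs, breakpoint_years=0.5)
        full = gs.fit_random_intercepts(obs)
        np.testing.assert_allclose(early.params.to_numpy(), full.params.to_numpy())
        np.testing.assert_allclose(late.params.to_numpy(), full.params.to_numpy())


class TestPolynomialInteraction:
    def test_degree_one_empty(self):
        rng = np.random.default_rng(18)
        obs = make_long_obs(rng, n_subjects=50)
        assert gs.polynomial_interaction_test(obs, max_degree=1).empty

    def test_quadratic_interaction_detected(self):
        rng = np.random.default_rng(19)
        obs = make_long_obs(rng, n_subjects=1500, ages=(0.0, 1.0, 3.0, 5.0, 7.0, 9.0, 11.0))
        obs["sds"] += 0.006 * obs["score"] * obs["age_years"] ** 2
        p = gs.polynomial_interaction_test(obs)
        assert p["score:age_years^2"] < 0.05

    def test_returns_requested_terms(self):
        rng = np.random.default_rng(20)
        obs = make_long_obs(rng, n_subjects=300, ages=(0.0, 2.0, 5.0, 8.0, 11.0))
        p = gs.polynomial_interaction_test(obs, max_degree=3)
        assert list(p.index) == ["score:age_years^2", "score:age_years^3"]
        assert ((p >= 0) & (p <= 1)).all()
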