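import numpy as np
import pandas as pd
import pytest

import growthscore as gs


@pytest.fixture(scope="session")
def reference():
    return gs.simulate_reference()


@pytest.fixture(scope="session")
def small_cohort(reference):
    """A modest seeded cohort shared across read-only tests."""
    cfg = gs.SimulationConfig(n_subjects=800, seed=42)
    meas, geno, body = gs.simulate_cohort(cfg, reference)
    sds = gs.standardize_cohort(meas, reference)
    scores = gs.risk_allele_score(geno, cfg.panel)
    return {"config": cfg, "measurements": meas, "genotypes": geno, "body": body,
            "sds": sds, "scores": scores}


@pytest.fixture(scope="session")
def null_cohort(reference):
    """No genetic effect, unit total SDS variance (0.8^2 + 0.6^2)."""
    cfg = gs.SimulationConfig(
        n_subjects=1500,
        seed=7,
        weight_effect_sds=(0.0, 0.0, 0.0),
        length_effect_sds=(0.0, 0.0, 0.0),
        missingness_prob=0.0,
    )
    meas, geno, body = gs.simulate_cohort(cfg, reference)
    sds = gs.standardize_cohort(meas, reference)
    return {"config": cfg, "measurements": meas, "genotypes": geno, "sds": sds}


def make_long_obs(rng, n_subjects=300, ages=(0.0, 1.0, 3.0, 7.0, 11.0),
                  interaction=0.0, score_effect=0.0, sigma_u=0.8, sigma_e=0.6):
    """Direct latent-scale long-format data (no LMS round trip)."""
    rows = []
    for i in range(n_subjects):
        score = rng.binomial(2, 0.4, 8).sum()
        u = rng.normal(0, sigma_u)
        sex = "female" if rng.random() < 0.5 else "male"
        for t in ages:
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "age_years": t,
                    "sds": u + score_effect * score + interaction * score * t
                    + rng.normal(0, sigma_e),
                    "score": float(score),
                    "sex": sex,
                }
            )
    return pd.DataFrame(rows)
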