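"""Synthetic birth-cohort generator.

Emulates the statistical structure of a population birth cohort with
repeated infant/child growth measurements and candidate-gene dosages:

* an LMS growth reference (stand-in for the licensed national
  reference) with smooth monotone median curves for weight and
  length/height from birth to 12 y;
* 8-10 biallelic SNPs drawn independently in Hardy-Weinberg
  equilibrium at configurable risk-allele frequencies, with optional
  call failures;
* latent growth on the SDS scale,
  ``z_i(t) = u_i + g(t) * score_i + e_it``, with a subject-level random
  intercept ``u_i``, visit-level measurement noise, and a per-allele
  effect profile ``g(t)`` that is piecewise linear in age — large over
  the first six weeks and accumulating slowly thereafter, mirroring the
  early-infancy signal the analysis is designed to detect;
* raw measurement values obtained by inverting the LMS reference at the
  visit's precise (jittered) age, so injected and estimated effects
  live on the same scale;
* visit-level missingness completely at random, and DXA-style body
  composition (fat mass, fat-free mass) at the age-9 visit.

Randomness is keyed per (seed, subject): each subject owns an
independent stream, so enlarging the cohort never perturbs existing
subjects, and identical seeds give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .anthropometry import CutoffCurves
from .genetics import VariantDef
from .growth_reference import LMSReference, from_sds

logger = logging.getLogger(__name__)

SIX_WEEKS = 42 / 365.25
NINE_MONTHS = 0.75

DEFAULT_VISITS = (0.0, SIX_WEEKS, NINE_MONTHS, 1.5, 3.5, 7.0, 8.0, 9.0, 10.0, 11.0)

#: candidate obesity-risk loci with literature-scale risk-allele
#: frequencies (the source tables do not print frequencies; these are
#: configuration defaults, not estimates)
_PANEL_ROWS = (
    ("rs9939609", "FTO", "A", "T", 0.40),
    ("rs17782313", "MC4R", "C", "T", 0.24),
    ("rs6548238", "TMEM18", "C", "T", 0.83),
    ("rs10938397", "GNPDA2", "G", "A", 0.43),
    ("rs368794", "KCTD15", "C", "T", 0.67),
    ("rs2568958", "NEGR1", "A", "G", 0.62),
    ("rs925946", "BDNF", "T", "G", 0.30),
    ("rs7647305", "ETV5", "C", "T", 0.79),
    ("rs7498665", "SH2B1", "G", "A", 0.38),
    ("rs10838738", "MTCH2", "G", "A", 0.34),
)


def default_panel(n_variants: int = 8) -> list[VariantDef]:
    """The 8-variant panel, or the 10-variant extension."""
    if n_variants not in (8, 10):
        raise ValueError("default panel has 8 or 10 variants")
    return [
        VariantDef(rsid, locus, risk, other, freq)
        for rsid, locus, risk, other, freq in _PANEL_ROWS[:n_variants]
    ]


@dataclass
class SimulationConfig:
    """All parameters of the synthetic cohort.

    Effect profiles are piecewise-linear in age through the listed
    (age, SDS-per-allele) nodes; between the 6-week node and 11 y the
    default weight profile accumulates slowly while the length profile
    is flat after 6 weeks.  ``random_intercept_sd`` and ``residual_sd``
    default to 0.8 / 0.6 SDS, i.e. unit total variance with a
    within-subject correlation of 0.64 (strong tracking of weight SDS).
    """

    n_subjects: int = 7000
    seed: int = 0
    panel: list[VariantDef] = field(default_factory=lambda: default_panel(8))
    weight_effect_ages: tuple = (0.0, SIX_WEEKS, 11.0)
    weight_effect_sds: tuple = (0.010, 0.0237, 0.0672)
    length_effect_ages: tuple = (0.0, SIX_WEEKS, 11.0)
    length_effect_sds: tuple = (0.010, 0.0282, 0.0282)
    random_intercept_sd: float = 0.8
    residual_sd: float = 0.6
    visit_ages: tuple = DEFAULT_VISITS
    age_jitter_sd: float = 0.03
    missingness_prob: float = 0.15
    genotype_missing_prob: float = 0.02
    sex_ratio: float = 0.5
    birth_weight_median: tuple = (3.49, 3.38)  # male, female (kg)
    fmi_median: tuple = (3.7, 4.9)  # fat mass index at 9 y (kg/m^2)
    ffmi_mean: tuple = (13.0, 12.1)  # fat-free mass index at 9 y
    fmi_log_slope: float = 0.30  # d log(FMI) per latent weight SDS
    fmi_log_sd: float = 0.35
    ffmi_slope: float = 0.45  # kg/m^2 per latent weight SDS
    ffmi_sd: float = 1.1

    def __post_init__(self):
        if not 0 <= self.missingness_prob <= 1:
            raise ValueError("missingness_prob must be in [0, 1]")
        if not 0 <= self.genotype_missing_prob <= 1:
            raise ValueError("genotype_missing_prob must be in [0, 1]")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def weight_effect(self, age):
        """Per-allele weight-SDS effect g(t), piecewise linear in age."""
        return np.interp(age, self.weight_effect_ages, self.weight_effect_sds)

    def length_effect(self, age):
        return np.interp(age, self.length_effect_ages, self.length_effect_sds)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["panel"] = [dataclasses.asdict(v) for v in self.panel]
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "panel" in d:
            d["panel"] = [VariantDef(**v) for v in d["panel"]]
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list) and f.name != "panel":
                d[f.name] = tuple(d[f.name])
        return cls(**d)


# ---------------------------------------------------------------------------
# reference and cutoff stand-ins

# monotone median anchors (age in years) per sex, loosely matched to a
# contemporary UK cohort; interpolated by shape-preserving cubics
_WEIGHT_KNOTS = {
    "male": [
        (0.0, 3.49), (SIX_WEEKS, 5.22), (0.75, 9.53), (1.5, 12.2), (3.5, 16.7),
        (5.0, 19.8), (7.0, 25.8), (8.0, 30.1), (9.0, 34.3), (10.0, 37.6),
        (11.0, 42.5), (12.0, 47.0),
    ],
    "female": [
        (0.0, 3.38), (SIX_WEEKS, 4.84), (0.75, 8.88), (1.5, 11.6), (3.5, 16.2),
        (5.0, 19.5), (7.0, 25.8), (8.0, 30.3), (9.0, 34.9), (10.0, 38.3),
        (11.0, 44.5), (12.0, 49.0),
    ],
}
_LENGTH_KNOTS = {
    "male": [
        (0.0, 51.1), (SIX_WEEKS, 58.0), (0.75, 73.2), (1.5, 84.5), (3.5, 100.9),
        (5.0, 110.0), (7.0, 126.2), (8.0, 132.9), (9.0, 139.7), (10.0, 143.9),
        (11.0, 150.1), (12.0, 156.0),
    ],
    "female": [
        (0.0, 50.4), (SIX_WEEKS, 56.9), (0.75, 71.4), (1.5, 83.1), (3.5, 100.0),
        (5.0, 109.0), (7.0, 125.5), (8.0, 132.1), (9.0, 139.4), (10.0, 144.1),
        (11.0, 151.5), (12.0, 158.0),
    ],
}

_L_BY_MEASURE = {"weight": -0.2, "length_height": 1.0, "bmi": -1.3}
_S_BY_MEASURE = {"weight": 0.12, "length_height": 0.09, "bmi": 0.10}


def _reference_age_grid() -> np.ndarray:
    return np.unique(
        np.concatenate(
            [np.linspace(0.0, 1.0, 21), np.linspace(1.0, 3.0, 17), np.linspace(3.0, 12.0, 37)]
        )
    )


def simulate_reference(config: SimulationConfig | None = None) -> LMSReference:
    """Synthetic LMS growth reference for weight, length/height and BMI.

    Median curves are shape-preserving cubics through monotone anchors
    (birth medians taken from the config); L is fixed per measure and S
    is a constant coefficient of variation per measure.  The BMI median
    is derived from the weight and length medians for internal
    consistency.  This is a synthetic stand-in, not a licensed national
    reference.
    """
    config = config or SimulationConfig()
    grid = _reference_age_grid()
    rows = []
    for si, sex in enumerate(("male", "female")):
        wk = list(_WEIGHT_KNOTS[sex])
        wk[0] = (0.0, float(config.birth_weight_median[si]))
        w_ages, w_vals = zip(*wk)
        l_ages, l_vals = zip(*_LENGTH_KNOTS[sex])
        w_curve = PchipInterpolator(w_ages, w_vals)(grid)
        l_curve = PchipInterpolator(l_ages, l_vals)(grid)
        bmi_curve = w_curve / (l_curve / 100.0) ** 2
        for measure, curve in (
            ("weight", w_curve),
            ("length_height", l_curve),
            ("bmi", bmi_curve),
        ):
            for age, m in zip(grid, curve):
                rows.append(
                    {
                        "sex": sex,
                        "measure": measure,
                        "age_years": float(age),
                        "L": _L_BY_MEASURE[measure],
                        "M": float(m),
                        "S": _S_BY_MEASURE[measure],
                    }
                )
    return LMSReference(pd.DataFrame(rows))


_CUTOFF_KNOTS = {
    # age: (overweight, obese) anchors, pinned to 25/30 kg/m^2 at 18 y
    2.0: (18.4, 20.1),
    4.0: (17.6, 19.3),
    6.0: (17.55, 19.8),
    8.0: (18.44, 21.3),
    10.0: (19.84, 23.4),
    12.0: (21.22, 25.5),
    14.0: (22.62, 27.3),
    16.0: (23.90, 28.8),
    18.0: (25.0, 30.0),
}


def simulate_cutoff_curves() -> CutoffCurves:
    """Internally consistent stand-in for the IOTF BMI cutoff curves."""
    ages = np.array(sorted(_CUTOFF_KNOTS))
    over = PchipInterpolator(ages, [_CUTOFF_KNOTS[a][0] for a in ages])
    obese = PchipInterpolator(ages, [_CUTOFF_KNOTS[a][1] for a in ages])
    grid = np.arange(2.0, 18.25, 0.25)
    rows = []
    for sex in ("male", "female"):
        for age in grid:
            rows.append(
                {
                    "sex": sex,
                    "age_years": float(age),
                    "bmi_overweight_cutoff": float(over(age)),
                    "bmi_obese_cutoff": float(obese(age)),
                }
            )
    return CutoffCurves(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort simulation

def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(subject_index))))


def _draw_subject(rng: np.random.Generator, config: SimulationConfig):
    """All random draws for one subject, in a fixed order."""
    p = len(config.panel)
    n_v = len(config.visit_ages)
    freqs = np.array([v.risk_allele_freq for v in config.panel])
    sex = "male" if rng.random() < config.sex_ratio else "female"
    dosages = rng.binomial(2, freqs).astype(float)
    geno_missing = rng.random(p) < config.genotype_missing_prob
    u = rng.normal(0.0, config.random_intercept_sd)
    jitter = rng.normal(0.0, config.age_jitter_sd, n_v)
    visit_missing = rng.random(n_v) < config.missingness_prob
    eps_weight = rng.normal(0.0, config.residual_sd, n_v)
    eps_length = rng.normal(0.0, config.residual_sd, n_v)
    fat_noise = rng.normal(0.0, 1.0, 2)
    return sex, dosages, geno_missing, u, jitter, visit_missing, eps_weight, eps_length, fat_noise


def simulate_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Observed dosage matrix (risk-allele counts, NaN for failed calls)."""
    _, geno, _ = simulate_cohort(config, measurements=False)
    return geno


def simulate_cohort(
    config: SimulationConfig,
    ref: LMSReference | None = None,
    measurements: bool = True,
):
    """Generate (measurements, genotypes, body composition).

    Measurements are long-format rows (subject_id, sex, age_years,
    measure, value, visit_age) at each non-missing visit; values are the
    inverse-LMS transform of the latent SDS at the precise jittered age.
    Genotypes carry the observational call failures while the latent
    effects always act through the complete true dosages.  Body
    composition is emitted for subjects observed at the 9-year visit.
    """
    ref = ref or simulate_reference(config)
    n = config.n_subjects
    n_v = len(config.visit_ages)
    p = len(config.panel)
    visits = np.asarray(config.visit_ages, float)

    sexes = np.empty(n, object)
    dosage = np.empty((n, p))
    observed = np.empty((n, p))
    ages = np.empty((n, n_v))
    miss = np.empty((n, n_v), bool)
    zw = np.empty((n, n_v))
    zl = np.empty((n, n_v))
    u_arr = np.empty(n)
    fat = np.empty((n, 2))

    for i in range(n):
        rng = _subject_rng(config.seed, i)
        sex, dos, gmiss, u, jit, vmiss, ew, el, fnoise = _draw_subject(rng, config)
        score = dos.sum()
        age_i = np.clip(visits + jit, 0.0, None)
        age_i[visits == 0.0] = 0.0  # birth measures are taken at birth
        sexes[i] = sex
        dosage[i] = dos
        observed[i] = np.where(gmiss, np.nan, dos)
        ages[i] = age_i
        miss[i] = vmiss
        u_arr[i] = u
        zw[i] = u + config.weight_effect(age_i) * score + ew
        zl[i] = u + config.length_effect(age_i) * score + el
        fat[i] = fnoise

    subject_ids = np.array([f"S{i:06d}" for i in range(n)])
    geno = pd.DataFrame(
        observed, index=pd.Index(subject_ids, name="subject_id"),
        columns=[v.rsid for v in config.panel],
    )
    if not measurements:
        return None, geno, None

    # back-transform latent SDS to raw units, vectorized per sex x measure
    rows = []
    for si, sex in enumerate(("male", "female")):
        sel = np.where(sexes == sex)[0]
        if not len(sel):
            continue
        for measure, z in (("weight", zw), ("length_height", zl)):
            keep = ~miss[sel]
            subj = np.repeat(subject_ids[sel], n_v).reshape(-1, n_v)[keep]
            age_flat = ages[sel][keep]
            visit_flat = np.tile(visits, (len(sel), 1))[keep]
            z_flat = z[sel][keep]
            L, M, S = ref.lookup(sex, measure, age_flat)
            value = _inverse_with_resample(z_flat, L, M, S, config, sex)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subj,
                        "sex": sex,
                        "age_years": age_flat,
                        "measure": measure,
                        "value": value,
                        "visit_age": visit_flat,
                    }
                )
            )
    meas = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["subject_id", "visit_age", "measure"], kind="mergesort")
        .reset_index(drop=True)
    )

    body = _body_composition(
        config, subject_ids, sexes, dosage, u_arr, ages, miss, fat, meas
    )
    return meas, geno, body


def _inverse_with_resample(z, L, M, S, config, sex):
    """from_sds with out-of-domain SDS redrawn toward 0 (logged)."""
    base = 1.0 + L * S * z
    bad = (np.abs(L) >= 1e-12) & (base <= 0)
    if bad.any():
        logger.warning(
            "simulate_cohort: %d latent SDS outside the inverse-LMS domain (%s); resampled",
            int(bad.sum()), sex,
        )
        z = z.copy()
        z[bad] = np.sign(z[bad]) * 0.999 * (1.0 / np.abs(L[bad] * S[bad]))
    return from_sds(z, L, M, S)


def _body_composition(config, subject_ids, sexes, dosage, u_arr, ages, miss, fat, meas):
    visits = np.asarray(config.visit_ages, float)
    nine = np.where(visits == 9.0)[0]
    if not len(nine):
        return pd.DataFrame(
            columns=["subject_id", "sex", "age_years", "fat_mass_kg", "fat_free_mass_kg",
                     "height_m"]
        )
    v9 = int(nine[0])
    heights = (
        meas[(meas["measure"] == "length_height") & (meas["visit_age"] == 9.0)]
        .set_index("subject_id")["value"]
    )
    score = dosage.sum(axis=1)
    rows = []
    sex_index = {"male": 0, "female": 1}
    for i, sid in enumerate(subject_ids):
        if miss[i, v9] or sid not in heights.index:
            continue
        si = sex_index[sexes[i]]
        z9 = u_arr[i] + config.weight_effect(9.0) * score[i]
        h = heights.loc[sid] / 100.0
        fmi = config.fmi_median[si] * np.exp(
            config.fmi_log_slope * z9 + config.fmi_log_sd * fat[i, 0]
        )
        ffmi = max(config.ffmi_mean[si] + config.ffmi_slope * z9 + config.ffmi_sd * fat[i, 1], 6.0)
        rows.append(
            {
                "subject_id": sid,
                "sex": sexes[i],
                "age_years": float(ages[i, v9]),
                "fat_mass_kg": float(fmi * h**2),
                "fat_free_mass_kg": float(ffmi * h**2),
                "height_m": float(h),
            }
        )
    return pd.DataFrame(rows)
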