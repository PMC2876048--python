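"""Config-driven orchestration of the full analysis chain.

``run_all`` executes every stage on user-supplied CSV inputs or, where
paths are absent, on a simulated cohort: genotype QC, risk-allele
scoring, SDS standardization, conditional infancy weight gain and
failure-to-thrive flagging, cross-sectional association at 9 y,
per-age coefficient profiles, overweight/obesity odds, variance
explained, and the longitudinal random-intercept models with their
piecewise and polynomial variants.  Every table is written as tidy CSV
plus a human-readable run log that reconciles all exclusion counts;
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anthropometry, association, genetics, longitudinal
from .conditional_gain import conditional_gain_analysis
from .growth_reference import LMSReference, standardize_cohort
from .synthetic_data import (
    SimulationConfig,
    default_panel,
    simulate_cohort,
    simulate_cutoff_curves,
    simulate_reference,
)

logger = logging.getLogger(__name__)

SIX_WEEKS = 42 / 365.25


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, panel choice and analysis settings for a full run.

    Any input path left as None is simulated from ``sim`` (which also
    receives the top-level seed).  ``panel_choice`` selects the
    8-variant primary panel, the 10-variant extension, or a custom
    panel CSV.
    """

    outdir: str = "growthscore_out"
    seed: int = 0
    panel_choice: str = "eight"  # eight | ten | custom
    panel_path: str | None = None
    measurements_path: str | None = None
    genotypes_path: str | None = None
    reference_path: str | None = None
    cutoffs_path: str | None = None
    body_composition_path: str | None = None
    baseline_age: float = 0.0
    followup_age: float = SIX_WEEKS
    crosssection_age: float = 9.0
    ftt_quantile: float = 0.05
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if self.panel_choice not in ("eight", "ten", "custom"):
            raise ValueError("panel_choice must be eight, ten or custom")
        if self.panel_choice == "custom" and not self.panel_path:
            raise ValueError("custom panel requires panel_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d:
            sim = d.pop("sim")
            if "panel" in sim:
                sim["panel"] = [genetics.VariantDef(**v) for v in sim["panel"]]
            for key, value in list(sim.items()):
                if isinstance(value, list) and key != "panel":
                    sim[key] = tuple(value)
            d["sim"] = SimulationConfig(**sim)
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # output location does not change the analysis
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_panel(config: PipelineConfig) -> list[genetics.VariantDef]:
    if config.panel_choice == "eight":
        return default_panel(8)
    if config.panel_choice == "ten":
        return default_panel(10)
    return genetics.read_panel(config.panel_path)


def load_inputs(config: PipelineConfig):
    """Load (or simulate) all inputs; returns a dict of tables."""
    panel = _resolve_panel(config)
    sim = dataclasses.replace(config.sim, seed=config.seed, panel=panel)
    ref = (
        LMSReference.from_csv(config.reference_path)
        if config.reference_path
        else simulate_reference(sim)
    )
    curves = (
        anthropometry.CutoffCurves.from_csv(config.cutoffs_path)
        if config.cutoffs_path
        else simulate_cutoff_curves()
    )
    if config.measurements_path and config.genotypes_path:
        meas = pd.read_csv(config.measurements_path)
        geno = genetics.read_genotypes_csv(config.genotypes_path)
        body = (
            pd.read_csv(config.body_composition_path)
            if config.body_composition_path
            else pd.DataFrame()
        )
    else:
        meas, geno, body = simulate_cohort(sim, ref)
    return {"panel": panel, "reference": ref, "cutoffs": curves,
            "measurements": meas, "genotypes": geno, "body_composition": body}


def derive_bmi_measurements(meas: pd.DataFrame) -> pd.DataFrame:
    """BMI rows computed from weight and length/height at the same visit."""
    key = ["subject_id", "sex", "visit_age"] if "visit_age" in meas.columns else [
        "subject_id", "sex", "age_years"]
    w = meas[meas["measure"] == "weight"]
    h = meas[meas["measure"] == "length_height"]
    joined = w.merge(h, on=key, suffixes=("_w", "_h"))
    out = pd.DataFrame(
        {
            "subject_id": joined["subject_id"],
            "sex": joined["sex"],
            "age_years": joined.get("age_years_w", joined.get("age_years")),
            "measure": "bmi",
            "value": anthropometry.bmi(
                joined["value_w"].to_numpy(float), joined["value_h"].to_numpy(float) / 100.0
            ),
        }
    )
    if "visit_age" in meas.columns:
        out["visit_age"] = joined["visit_age"]
    return out


def score_distribution_table(scores: pd.Series, outcome_sds: pd.Series) -> pd.DataFrame:
    """Per score value: n, mean outcome, Wald 95% CI of the mean.

    Score values carried by a single subject get an undefined CI and a
    flag rather than a spurious zero-width interval.
    """
    df = pd.DataFrame({"score": scores, "outcome": outcome_sds}).dropna()
    rows = []
    for value, block in df.groupby("score"):
        n = len(block)
        mean = float(block["outcome"].mean())
        if n > 1:
            half = 1.96 * float(block["outcome"].std(ddof=1)) / np.sqrt(n)
            ci_low, ci_high, flagged = mean - half, mean + half, False
        else:
            ci_low = ci_high = np.nan
            flagged = True
        rows.append(
            {"score": float(value), "n": n, "mean_outcome": mean,
             "ci_low": ci_low, "ci_high": ci_high, "single_subject": flagged}
        )
    return pd.DataFrame(rows)


def _sds_at_age(sds: pd.DataFrame, measure: str, age: float, tol: float = 0.25) -> pd.DataFrame:
    if "visit_age" in sds.columns:
        block = sds[(sds["measure"] == measure) & (sds["visit_age"] == age)]
    else:
        block = sds[(sds["measure"] == measure) & (np.abs(sds["age_years"] - age) <= tol)]
    return block.drop_duplicates("subject_id").set_index("subject_id")


def _sex_numeric(series: pd.Series) -> pd.Series:
    return (series == "female").astype(float)


def run_all(config: PipelineConfig, write: bool = True) -> dict:
    """Run every stage; returns a dict of result tables (and writes CSVs)."""
    log_lines = [
        f"growthscore run, seed={config.seed}, panel={config.panel_choice}, "
        f"config_hash={config.config_hash()}"
    ]
    results: dict = {}

    def stage(name):
        log_lines.append(f"[stage] {name}")
        return name

    try:
        stage("inputs")
        inputs = load_inputs(config)
        panel, ref, curves = inputs["panel"], inputs["reference"], inputs["cutoffs"]
        meas, geno, body = inputs["measurements"], inputs["genotypes"], inputs["body_composition"]
        n_subjects = geno.shape[0]
        log_lines.append(f"  subjects with genotype rows: {n_subjects}")
        log_lines.append(f"  measurement rows: {len(meas)}")

        stage("genotype_qc")
        qc = genetics.qc_table(geno, panel)
        results["qc"] = qc
        log_lines.append(f"  variants passing HWE p>0.1: {(qc['hwe_p'] > 0.1).sum()}/{len(qc)}")

        stage("risk_score")
        scores = genetics.risk_allele_score(geno, panel, require_complete=True)
        n_excluded_geno = n_subjects - len(scores)
        results["scores"] = scores
        log_lines.append(
            f"  complete-genotype subjects: {len(scores)} "
            f"(excluded {n_excluded_geno} with missing calls)"
        )

        stage("standardize")
        meas_all = pd.concat([meas, derive_bmi_measurements(meas)], ignore_index=True)
        sds, excluded = standardize_cohort(meas_all, ref, return_excluded=True)
        results["sds"] = sds
        log_lines.append(
            f"  SDS rows: {len(sds)} (excluded {len(excluded)} outside reference ages)"
        )

        stage("conditional_gain")
        gains, r = conditional_gain_analysis(
            sds, config.baseline_age, config.followup_age, config.ftt_quantile
        )
        results["conditional_gain"] = gains
        results["baseline_followup_r"] = r
        log_lines.append(
            f"  complete birth/6wk pairs: {len(gains)}; r = {r:.4f}; "
            f"failure-to-thrive flagged: {int(gains['ftt_flag'].sum())}"
        )

        score_s = scores["score"]

        stage("score_distribution")
        bmi9 = _sds_at_age(sds, "bmi", config.crosssection_age)
        joined9 = bmi9.join(score_s, how="inner")
        results["score_distribution"] = score_distribution_table(
            joined9["score"], joined9["sds"]
        )

        stage("cross_sectional")
        cross_rows = []
        for measure, label in (
            ("bmi", "BMI SDS"), ("weight", "Weight SDS"), ("length_height", "Height SDS"),
        ):
            block = _sds_at_age(sds, measure, config.crosssection_age).join(score_s, how="inner")
            cov = pd.DataFrame(
                {"sex": _sex_numeric(block["sex"]), "age_years": block["age_years"]}
            ).reset_index(drop=True)
            res = association.linear_assoc(
                block["sds"].to_numpy(float), block["score"].to_numpy(float), cov, label
            )
            cross_rows.append(res.as_dict())
        if len(body):
            bc = body.set_index("subject_id").join(score_s, how="inner")
            for col, label in (
                ("fat_mass_kg", "Fat mass index (kg/m^2)"),
                ("fat_free_mass_kg", "Fat-free mass index (kg/m^2)"),
            ):
                index_vals = anthropometry.mass_index(
                    bc[col].to_numpy(float), bc["height_m"].to_numpy(float)
                )
                cov = pd.DataFrame(
                    {
                        "sex": _sex_numeric(bc["sex"]),
                        "age_years": bc["age_years"].to_numpy(float),
                        "height_m": bc["height_m"].to_numpy(float),
                    }
                ).reset_index(drop=True)
                res = association.linear_assoc(
                    index_vals, bc["score"].to_numpy(float), cov, label
                )
                cross_rows.append(res.as_dict())
        gain_join = gains.set_index("subject_id").join(score_s, how="inner")
        cross_rows.append(
            association.linear_assoc(
                gain_join["sds_gain"].to_numpy(float),
                gain_join["score"].to_numpy(float),
                None,
                "Conditional weight gain SDS",
            ).as_dict()
        )
        results["cross_sectional"] = pd.DataFrame(cross_rows)

        stage("age_profile")
        ages = sorted(sds["visit_age"].unique()) if "visit_age" in sds.columns else sorted(
            sds["age_years"].round(1).unique()
        )
        results["age_profile"] = association.per_age_profile(sds, score_s, ages)

        stage("odds")
        odds_rows = []
        ftt = gains.set_index("subject_id").join(score_s, how="inner")
        odds_rows.append(
            association.logistic_assoc(
                ftt["ftt_flag"].to_numpy(float), ftt["score"].to_numpy(float),
                None, "Failure to thrive (birth to 6 wk)",
            ).as_dict()
        )
        bmi_meas = derive_bmi_measurements(meas).rename(columns={"value": "bmi"})
        if "visit_age" in bmi_meas.columns:
            bmi9_vals = bmi_meas[bmi_meas["visit_age"] == config.crosssection_age]
        else:
            bmi9_vals = bmi_meas[
                np.abs(bmi_meas["age_years"] - config.crosssection_age) <= 0.25
            ]
        cls_frame = (
            bmi9_vals.drop_duplicates("subject_id")
            .set_index("subject_id")
            .join(score_s, how="inner")
            .reset_index()
        )
        category = anthropometry.classify_cohort(cls_frame, curves)
        for outcome, label in (
            (np.isin(category, ("overweight", "obese")), "Overweight or obese at 9 y"),
            (category == "obese", "Obese at 9 y"),
        ):
            cov = pd.DataFrame(
                {"sex": _sex_numeric(cls_frame["sex"]).to_numpy(),
                 "age_years": cls_frame["age_years"].to_numpy(float)}
            )
            odds_rows.append(
                association.logistic_assoc(
                    np.asarray(outcome, float), cls_frame["score"].to_numpy(float), cov, label
                ).as_dict()
            )
        results["odds"] = pd.DataFrame(odds_rows)

        stage("variance_explained")
        ve_rows = []
        for measure, label in (("bmi", "BMI SDS at 9 y"), ("weight", "Weight SDS at 9 y")):
            block = _sds_at_age(sds, measure, config.crosssection_age).join(
                score_s, how="inner"
            )
            cov = pd.DataFrame(
                {"sex": _sex_numeric(block["sex"]), "age_years": block["age_years"]}
            ).reset_index(drop=True)
            delta_r2 = association.variance_explained(
                block["sds"].to_numpy(float), block["score"].to_numpy(float), cov
            )
            ve_rows.append(
                {"outcome": label, "delta_r2": delta_r2,
                 "percent": 100 * delta_r2, "n": len(block)}
            )
        results["variance_explained"] = pd.DataFrame(ve_rows)

        stage("longitudinal")
        long_rows = []
        poly_rows = []
        for measure, label in (
            ("weight", "Weight SDS"), ("length_height", "Height SDS"), ("bmi", "BMI SDS"),
        ):
            obs = (
                sds[sds["measure"] == measure]
                .join(score_s, on="subject_id", how="inner")
                .dropna(subset=["score", "sds"])
            )
            fit = longitudinal.fit_random_intercepts(obs)
            early, late = longitudinal.piecewise_slopes(obs)
            for window, f in (("birth to 11 y", fit), ("birth to 6 wk", early),
                              ("6 wk to 11 y", late)):
                long_rows.append(
                    {
                        "outcome": label,
                        "window": window,
                        "slope_sds_per_allele_per_year": f.params["score:age_years"],
                        "se": f.se["score:age_years"],
                        "ci_low": f.ci_low["score:age_years"],
                        "ci_high": f.ci_high["score:age_years"],
                        "p_value": f.p_values["score:age_years"],
                        "sigma_u": f.sigma_u,
                        "sigma_e": f.sigma_e,
                        "n_obs": f.n_obs,
                        "n_subjects": f.n_subjects,
                        "method": f.method,
                    }
                )
            poly = longitudinal.polynomial_interaction_test(obs)
            for term, p in poly.items():
                poly_rows.append({"outcome": label, "term": term, "p_value": p})
        results["longitudinal"] = pd.DataFrame(long_rows)
        results["polynomial_interactions"] = pd.DataFrame(poly_rows)

        stage("reconciliation")
        log_lines.append(
            f"  cross-sectional BMI n = {int(results['cross_sectional'].iloc[0]['n'])} "
            f"= complete-genotype subjects with a BMI SDS at 9 y"
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        current = log_lines[-1] if log_lines else "?"
        raise PipelineError(f"pipeline failed at {current!r}: {exc}") from exc

    results["run_log"] = "\n".join(log_lines) + "\n"
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in results.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "run_log.txt").write_text(results["run_log"])
    return results
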