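"""Genotype QC and obesity-risk-allele scores.

Genotypes are held as a pandas DataFrame indexed by subject with one
column per variant, each entry the dosage of the *risk* allele (0, 1, 2
or NaN for a failed call).  The unweighted risk-allele score is the sum
of dosages across a fixed SNP panel; the weighted variant multiplies
each dosage by a per-variant effect-size weight.  QC covers per-variant
call rates and a one-degree-of-freedom chi-square test of Hardy-Weinberg
equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


class GeneticsError(ValueError):
    """Invalid panel configuration or genotype input."""


@dataclass(frozen=True)
class VariantDef:
    """A biallelic candidate SNP, oriented to its obesity risk allele.

    ``risk_allele_freq`` is the population frequency of the risk allele
    (a simulation parameter); ``weight`` is the per-allele effect on
    adult BMI used by the weighted score (1.0 reproduces the unweighted
    analysis).
    """

    rsid: str
    locus_label: str
    risk_allele: str
    other_allele: str
    risk_allele_freq: float
    weight: float | None = 1.0  # None = no weight supplied

    def __post_init__(self):
        if self.risk_allele == self.other_allele:
            raise GeneticsError(f"{self.rsid}: risk and other allele identical")
        if self.risk_allele not in _BASES or self.other_allele not in _BASES:
            raise GeneticsError(f"{self.rsid}: alleles must be single bases")
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise GeneticsError(f"{self.rsid}: risk_allele_freq must be in (0, 1)")
        if self.weight is not None and not self.weight >= 0:
            raise GeneticsError(f"{self.rsid}: weight must be >= 0")


def read_panel(path) -> list[VariantDef]:
    """Read a variant panel CSV (columns matching VariantDef fields)."""
    df = pd.read_csv(path)
    panel = []
    for row in df.itertuples(index=False):
        kwargs = row._asdict()
        kwargs.setdefault("weight", 1.0)
        if pd.isna(kwargs.get("weight")):
            kwargs["weight"] = 1.0
        panel.append(VariantDef(**kwargs))
    return panel


def write_panel(panel: list[VariantDef], path) -> None:
    pd.DataFrame([v.__dict__ for v in panel]).to_csv(path, index=False)


def read_genotypes_csv(path) -> pd.DataFrame:
    """Read a dosage CSV: subject_id column then one column per rsid.

    Blank cells are missing calls.  Present dosages must be integral and
    in {0, 1, 2}.
    """
    geno = pd.read_csv(path, index_col="subject_id")
    return _validate_dosages(geno.astype(float))


def read_genotypes_vcf(path, panel: list[VariantDef]) -> pd.DataFrame:
    """Read risk-allele dosages from a (minimal, uncompressed) VCF.

    Each panel rsid must appear as a VCF record whose REF/ALT alleles
    match the panel's risk/other alleles in either orientation; any
    other allele pair is a hard error (no silent strand flips).  GT
    fields are mapped to risk-allele counts; missing GT becomes NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    wanted = {v.rsid: v for v in panel}
    data: dict[str, np.ndarray] = {}
    for rec in vcf:
        if rec.ID not in wanted:
            continue
        v = wanted[rec.ID]
        alleles = {rec.REF, rec.ALT[0] if rec.ALT else None}
        if alleles != {v.risk_allele, v.other_allele}:
            raise GeneticsError(
                f"{rec.ID}: VCF alleles {alleles} do not match panel "
                f"({v.risk_allele}/{v.other_allele})"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        alt_dose = np.array(
            [{0: 0.0, 1: 1.0, 3: 2.0}.get(t, np.nan) for t in rec.gt_types], float
        )
        data[rec.ID] = alt_dose if rec.ALT and rec.ALT[0] == v.risk_allele else 2.0 - alt_dose
    missing = set(wanted) - set(data)
    if missing:
        raise GeneticsError(f"panel rsids absent from VCF: {sorted(missing)}")
    geno = pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))
    return _validate_dosages(geno)


def _validate_dosages(geno: pd.DataFrame) -> pd.DataFrame:
    values = geno.to_numpy(float)
    present = ~np.isnan(values)
    ok = np.isin(values[present], (0.0, 1.0, 2.0))
    if not ok.all():
        raise GeneticsError("dosages must be 0, 1, 2 or missing")
    return geno


def _check_panel_columns(geno: pd.DataFrame, panel: list[VariantDef]) -> list[str]:
    rsids = [v.rsid for v in panel]
    missing = [r for r in rsids if r not in geno.columns]
    if missing:
        raise GeneticsError(f"panel rsids missing from genotype matrix: {missing}")
    if not rsids:
        raise GeneticsError("empty variant panel")
    return rsids


def risk_allele_score(
    geno: pd.DataFrame,
    panel: list[VariantDef],
    require_complete: bool = True,
) -> pd.DataFrame:
    """Unweighted obesity-risk-allele score: sum of risk-allele dosages.

    With ``require_complete`` (the primary analysis rule), subjects with
    any missing panel genotype are excluded and the exclusion count is
    logged; otherwise the score sums over the available variants.

    Returns a DataFrame indexed by subject with columns
    ``n_variants_used`` and ``score``.
    """
    rsids = _check_panel_columns(geno, panel)
    sub = geno[rsids]
    n_used = sub.notna().sum(axis=1)
    if require_complete:
        complete = n_used == len(rsids)
        n_excluded = int((~complete).sum())
        if n_excluded:
            logger.info(
                "risk_allele_score: excluded %d subject(s) with incomplete genotypes",
                n_excluded,
            )
        sub = sub.loc[complete]
        n_used = n_used.loc[complete]
    return pd.DataFrame(
        {"n_variants_used": n_used.astype(int), "score": sub.sum(axis=1)},
        index=sub.index,
    )


def weighted_score(
    geno: pd.DataFrame,
    panel: list[VariantDef],
    require_complete: bool = True,
) -> pd.DataFrame:
    """Effect-size-weighted risk score: sum of weight x dosage.

    Every panel variant must carry a weight; with all weights equal to 1
    this reduces to :func:`risk_allele_score`.
    """
    for v in panel:
        if v.weight is None or (isinstance(v.weight, float) and np.isnan(v.weight)):
            raise GeneticsError(f"{v.rsid}: weighted score requires a weight")
    rsids = _check_panel_columns(geno, panel)
    weights = pd.Series({v.rsid: float(v.weight) for v in panel})
    sub = geno[rsids]
    n_used = sub.notna().sum(axis=1)
    if require_complete:
        complete = n_used == len(rsids)
        n_excluded = int((~complete).sum())
        if n_excluded:
            logger.info(
                "weighted_score: excluded %d subject(s) with incomplete genotypes", n_excluded
            )
        sub = sub.loc[complete]
        n_used = n_used.loc[complete]
    score = sub.mul(weights, axis=1).sum(axis=1)
    return pd.DataFrame({"n_variants_used": n_used.astype(int), "score": score}, index=sub.index)


def hwe_test(n_rr: int, n_rh: int, n_hh: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value from genotype counts.

    ``n_rr``, ``n_rh``, ``n_hh`` are counts of risk-homozygote,
    heterozygote and other-homozygote subjects.  The test is the 1-df
    chi-square of observed counts against the HWE expectation at the
    sample allele frequency, without continuity correction.  A
    monomorphic sample returns p = 1 by convention (logged).
    """
    counts = np.array([n_rr, n_rh, n_hh], float)
    if np.any(counts < 0):
        raise GeneticsError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise GeneticsError("hwe_test requires at least one genotype")
    p = (2 * n_rr + n_rh) / (2 * n)
    if p in (0.0, 1.0):
        logger.info("hwe_test: monomorphic sample, returning p = 1 by convention")
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_dosages(dosages: pd.Series) -> float:
    """HWE p-value from a dosage column (missing calls ignored)."""
    d = dosages.dropna().to_numpy(float)
    return hwe_test(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))


def call_rate(geno: pd.DataFrame, rsid: str) -> float:
    """Fraction of subjects with a non-missing call at ``rsid``."""
    if rsid not in geno.columns:
        raise GeneticsError(f"unknown rsid {rsid!r}")
    col = geno[rsid]
    return float(col.notna().sum() / len(col))


def qc_table(geno: pd.DataFrame, panel: list[VariantDef]) -> pd.DataFrame:
    """Per-variant QC summary: call rate, risk-allele frequency, HWE p."""
    rows = []
    for v in panel:
        d = geno[v.rsid].dropna().to_numpy(float)
        freq = float(d.mean() / 2) if len(d) else np.nan
        rows.append(
            {
                "rsid": v.rsid,
                "locus_label": v.locus_label,
                "call_rate": call_rate(geno, v.rsid),
                "risk_allele_freq_observed": freq,
                "hwe_p": hwe_test_dosages(geno[v.rsid]),
            }
        )
    return pd.DataFrame(rows)
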