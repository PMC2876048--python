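# growthscore

Tools for asking *when* a polygenic burden of obesity-risk alleles
begins to shape growth: standardized infant/child anthropometry,
risk-allele scoring, conditional infancy weight gain, and
cross-sectional plus longitudinal gene-by-age association models for
birth-cohort data.

Common variants near loci such as *FTO*, *MC4R* and *TMEM18* each nudge
adult BMI only slightly, but summed into an unweighted risk-allele
count they form a score with enough power to trace its effect across
childhood. `growthscore` implements the full analysis chain needed for
that question on a cohort with repeated growth measurements and
candidate-SNP genotypes, plus a synthetic-cohort generator so every
stage is testable without access to restricted individual-level data.

## The models

**Growth standardization.** Raw weight, length/height and BMI are
converted to age- and sex-specific standard deviation scores (SDS)
against an LMS reference: z = ((x/M)^L − 1)/(L·S), with L, M, S
interpolated linearly at the precise age of measurement (ln(x/M)/S in
the L → 0 limit). The transform is exactly invertible, which the
synthetic generator uses to inject effects on the SDS scale.

**Risk-allele score.** score_i = Σ_j dosage_ij over a fixed SNP panel
(0–16 for eight biallelic variants), complete cases only; an
effect-weighted variant Σ_j w_j·dosage_ij is available. QC covers call
rates and a 1-df chi-square Hardy-Weinberg test.

**Conditional weight gain.** gain = (SDS_6wk − r·SDS_birth)/√(1 − r²),
where r is the birth/6-week correlation estimated in-sample; this
removes regression to the mean, and "failure to thrive" is the slowest
5% of gain.

**Association.** OLS (continuous) and ML logistic (binary) models of
each outcome on the score with per-outcome covariates, Wald 95% CIs;
per-age coefficient profiles; incremental R² of the score.

**Longitudinal.** Random-intercept mixed models
y_it = β₀ + β₁·score + β₂·age + β₃·score×age + β₄·sex + u_i + e_it,
fitted by exact maximum likelihood via a profiled 1-D search over
σ_u²/σ_e². β₃ is the change in the per-allele effect per year of age;
piecewise fits split at 6 weeks separate the steep infancy rate from
the slow childhood rate, and score×age²/age³ Wald tests check that the
linear interaction suffices.

## Worked example

Run the whole pipeline on a simulated 7,000-child cohort (or point the
config at your own measurement/genotype/reference CSVs):

```python
import growthscore as gs

cfg = gs.PipelineConfig(outdir="demo_out", seed=1)
results = gs.run_all(cfg)
print(results["cross_sectional"])
```

which prints (seed 1):

```
                     outcome    n  effect_per_allele  ci_low  ci_high  p_value
                     BMI SDS 5057             0.0252  0.0048   0.0456   0.0156
                  Weight SDS 5057             0.0578  0.0426   0.0731   0.0000
                  Height SDS 5057             0.0257  0.0105   0.0409   0.0009
     Fat mass index (kg/m^2) 5057             0.0736  0.0392   0.1080   0.0000
Fat-free mass index (kg/m^2) 5057             0.0195  0.0025   0.0366   0.0246
 Conditional weight gain SDS 4294             0.0114 -0.0052   0.0281   0.1770
```

Each additional risk allele is associated with ~0.06 SDS greater weight
at age 9 in this cohort (the generator's injected per-allele effect at
that age is 0.059, so the estimate and its CI recover the truth), with
weaker height and BMI associations. The longitudinal table for weight
SDS from the same run:

```
       window  slope_sds_per_allele_per_year  ci_low  ci_high
birth to 11 y                         0.0045  0.0038   0.0052
birth to 6 wk                         0.0472 -0.0661   0.1604
 6 wk to 11 y                         0.0042  0.0035   0.0050
```

i.e. an overall gain rate of ~0.005 SDS/allele/year with a much larger
(and much less precise — only two visits contribute) infancy rate, the
early-vs-late contrast the method is designed to expose. The report
bundle in `demo_out/` also contains genotype QC, the score
distribution with per-score mean BMI SDS, per-age coefficient
profiles, failure-to-thrive and overweight/obesity odds, variance
explained, and a run log reconciling every exclusion.

The same stages are available from the shell:

```bash
growthscore simulate --seed 1 --outdir sim_out
growthscore all --seed 1 --outdir report_out
```

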