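# Methods

## Scope and model

`growthscore` implements the analysis chain used to ask when, across
infancy and childhood, a polygenic burden of adult-obesity risk alleles
begins to shape growth. Its stages are:

1. **Growth standardization (LMS).** A reference distribution for each
   sex and measure (weight, length/height, BMI) is represented by
   age-varying triples (L, M, S): median M, coefficient of variation S,
   and Box-Cox power L. A raw value x at precise age t maps to a
   standard deviation score z = ((x/M)^L − 1)/(L·S), or ln(x/M)/S in
   the L→0 limit. Both branches are computed with `expm1`/`log1p`, so
   the transform and its inverse are accurate to machine precision for
   any |L| and round-trip to better than 1e-9 (they are exact inverses
   analytically). L, M and S are interpolated linearly in age between
   grid rows — the standard convention for LMS tables, exact at grid
   points — and the package refuses to extrapolate beyond the grid:
   out-of-range rows are excluded with a logged count.

2. **Risk-allele score.** Dosages are stored pre-oriented to the risk
   allele (a VCF reader maps GT fields, and any allele-pair mismatch is
   a hard error — there are no silent strand flips). The primary score
   is the unweighted count of risk alleles over a fixed 8-SNP panel,
   restricted to subjects with complete panel genotypes (the exclusion
   count is logged and reconciled in the run log); a weighted variant
   multiplies dosages by user-supplied per-allele adult-BMI effects and
   reduces to the count when all weights are 1. QC reports per-variant
   call rates and a 1-df chi-square Hardy-Weinberg test without
   continuity correction (samples here are large; monomorphic variants
   return p = 1 by convention, logged).

3. **Conditional infancy weight gain.** Raw SDS change from birth
   regresses to the mean, so gain is computed conditionally:
   gain = (SDS_6wk − r·SDS_birth)/√(1 − r²), with r the Pearson
   correlation between birth and 6-week weight SDS estimated within the
   analysis sample itself. With within-sample standardized inputs this
   gain is exactly uncorrelated with birth SDS and has unit variance
   (an algebraic identity the tests verify to 1e-10). Failure to
   thrive is membership in the slowest 5% of conditional gain; the
   threshold is the empirical quantile with linear interpolation
   between order statistics, ties flagged inclusively, and fewer than
   20 values are refused.

4. **Cross-sectional association.** OLS for continuous outcomes and
   ML logistic regression for binary ones, always complete-case, with
   per-outcome covariate sets (sex and precise age for SDS outcomes;
   sex, age and height for the fat- and fat-free-mass indices).
   Intervals are Wald, estimate ± 1.96·SE. Variance explained is the
   increment in R² from adding the score to the covariate-only model.
   Complete separation in the logistic model raises rather than
   returning a non-converged fit.

5. **Longitudinal mixed models.** For repeated SDS the model is
   y_it = x_it'β + u_i + e_it with a subject random intercept, fixed
   effects including score, age, score×age (the per-year change in the
   per-allele effect) and sex. Estimation is full maximum likelihood,
   not REML, so models with different fixed effects (the polynomial
   interaction checks) have comparable likelihoods. The likelihood is
   profiled to the single variance ratio θ = σ_u²/σ_e²: for fixed θ,
   GLS is an OLS on partially group-mean-centred data and σ_e²
   maximizes in closed form; a coarse log-grid plus bounded Brent
   search (absolute tolerance 1e-10 on θ, 500 evaluations cap) then
   yields the exact ML optimum. This matches `statsmodels` MixedLM
   (ML) to ~1e-5 on every dataset tested while being an order of
   magnitude faster, which is what makes the replicated simulation
   checks affordable. Design columns are rescaled to unit RMS before
   solving, so polynomial interaction terms do not degrade
   conditioning; reported effects are on the original scale.

   Piecewise infancy/childhood rates come from two independent
   window-restricted fits split at 6 weeks (42/365.25 y), with the
   boundary visit included in both windows. When the data carry a
   nominal visit schedule (`visit_age`), windows are defined on it, so
   a 6-week measurement whose precise age jittered past the breakpoint
   still belongs to the infancy window. A window averaging fewer than
   two observations per subject triggers a warning but is still fitted
   by ML whenever any subject is replicated — the random-intercept ML
   is well defined for unbalanced clusters, and falling back to pooled
   OLS there would discard the within-subject information the infancy
   window depends on. Pooled OLS is used only when no subject has two
   observations, where the intercept variance is unidentified. If all
   supplied data fall in one window the function degenerates, with a
   warning, to a single fit returned for both slots.

## Synthetic cohort

The generator emulates the design of a population birth cohort with
~7,000 children measured at birth, 6 weeks, 9 months, 1.5, 3.5 and
7–11 years:

- **Reference stand-in.** Monotone median curves for weight and length
  are shape-preserving cubics through anchors typical of a contemporary
  UK cohort (birth medians 3.49/3.38 kg by sex); the BMI median is
  derived from them. L is fixed per measure (−0.2 weight, 1.0 length,
  −1.3 BMI) and S is a constant CV per measure within 0.08–0.15. The
  licensed national reference is deliberately not shipped; users supply
  their own CSV for real analyses. Similarly the overweight/obesity
  cutoff curves are an internally consistent stand-in pinned to
  25/30 kg/m² at age 18, not the published tables.

- **Genotypes.** 8 or 10 biallelic SNPs drawn independently as
  Binomial(2, f_j) (Hardy-Weinberg by construction) at literature-scale
  risk-allele frequencies, with optional per-call missingness (default
  2%) to emulate imperfect call rates. The resulting 8-SNP score is
  centred near 8.6 of 16, approximately normal.

- **Growth.** Latent weight SDS is z_i(t) = u_i + g(t)·score_i + e_it
  with u_i ~ N(0, 0.8²), e ~ N(0, 0.6²) — unit total variance and a
  within-subject correlation of 0.64, i.e. strong tracking. The
  per-allele profile g(t) is piecewise linear in age; the default rises
  steeply over the first 6 weeks (0.119 SDS/allele/y) and slowly
  thereafter (0.004 SDS/allele/y), reaching ≈0.06 SDS/allele by age 9.
  The length profile is flat after 6 weeks. Raw values are the inverse
  LMS transform at the visit's precise age (visits jitter by
  N(0, 0.03²) years, birth exact), so injected and estimated effects
  live on the same SDS scale. Visit-level missingness is completely at
  random (default 15%), which keeps complete-case estimators unbiased
  and isolates estimator behaviour from missingness mechanisms.
  Effects always act through the complete true dosages; call failures
  are purely observational.

- **Randomness.** Each subject owns a stream keyed by (seed, subject
  index), with a fixed draw order across visits: identical seeds give
  byte-identical cohorts, and enlarging the cohort never perturbs
  existing subjects.

- **Body composition.** At the 9-year visit, fat mass index is
  lognormal around a sex-specific median (3.7/4.9 kg/m²) with a
  log-slope of 0.30 per latent weight SDS; fat-free mass index is
  normal (13.0/12.1 kg/m²) with slope 0.45. Both convert to masses via
  the simulated height squared, so FMI + FFMI relates to BMI the way
  the derived indices require.

A consequence of the stand-in reference worth knowing: BMI is not
simulated directly but emerges as weight/height², so its per-allele
SDS effect is roughly (S_w·g_w − 2·S_l·g_l)/S_bmi. Because the
stand-in uses a length CV of 0.09 (real references sit near 0.04), the
persistent length effect cancels more of the weight effect than it
would against a real reference, and BMI-based quantities (BMI SDS
effect, BMI variance explained, overweight odds) are attenuated
relative to their weight-based counterparts. Weight-based outputs are
the ones to compare across settings.

What the generator does *not* emulate: secular trends, twins/siblings,
informative dropout, population stratification, genotyping error beyond
random missingness, or realistic skew in infancy length. Passing tests
therefore demonstrate correctness of the estimators under the assumed
data-generating model, not robustness to these real-data features.

## Numerical and design choices

- Ages are decimal years: 6 weeks = 42/365.25 y, 9 months = 0.75 y.
- Birth values are accepted as already gestational-age-adjusted; an
  optional gestational-age column is carried through but unused.
- The L branch switch is |L| < 1e-12; with the `expm1` form the two
  branches agree to ~1e-15 at the switch point.
- Cutoff classification interpolates the curves at exact age and treats
  boundaries inclusively, so the age-18 anchors classify exactly.
- Per-age association profiles assign each measurement to the nearest
  nominal age within 0.25 y and require ≥50 complete cases per fit.
- All pipeline randomness flows from one top-level seed; reports embed
  the seed and a config hash (excluding the output directory).

## Simulation sizes in the checks

The replicated acceptance checks use 100–500 replicates at cohort sizes
of 1,000–7,000 subjects — the scale at which a birth-cohort design of
this kind has its intended power — chosen so the whole suite runs
comfortably on a single CPU. Coverage-style checks are inherently stochastic: a
correctly calibrated 95% Wald interval yields a Binomial(100, ≈0.95)
count of covered replicates, so occasional counts of 92–93 are expected
behaviour, not miscalibration; longer diagnostics (300+ replicates) put
the interaction-coefficient coverage at ≈94.7%.

## Known limitations

- Wald intervals from ML slightly understate variance-parameter
  uncertainty; for the fixed effects studied here the Kackar-Harville
  correction is numerically negligible, but small-sample users should
  prefer more replication over trusting a single 95% CI.
- Conditional gain is defined only for the birth → 6-week pair.
- No imputation, robust variances, random slopes or serial correlation
  structures; these are out of scope by design.
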