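# Methods

This note documents the statistical content of the package: what each
stage computes, the choices made where the design was genuinely open, and
what the synthetic cohorts can and cannot establish.

## Gene score

The score is the raw weighted sum of risk-allele dosages,
`GS = Σ_j w_j · c(g_j)` with `w_j = ln OR_j` taken from the published
per-allele odds ratios in the shipped panel file
(`src/grs/data/panel_19snp.tsv`). Coding `c` is additive (`c(g) = g`) for
every variant except *NOS3* rs1799983, which is scored recessively
(`c(g) = 1{g = 2}`). *APOE* rs7412 is scored on its protective allele
(OR 0.80), so its weight is negative and the attainable score range for
the 19-SNP panel is `[2 ln 0.80, 9.2109]`. No division by SNP count or
other rescaling is applied; the published group means (~3.3 for the
19-SNP score) are consistent with a raw sum.

Two open points were resolved as follows. The *SORT1* locus is
represented by rs599839, the variant actually genotyped as a proxy
(r² = 0.95 in Europeans) for the originally reported rs646776; rs646776
in input files is accepted as an alias of the same panel entry. The two
*APOE* variants (rs429358, rs7412) are scored per-allele as independent
SNPs — the literal reading of the published weight table — rather than as
ε2/ε3/ε4 haplotypes, which would require phase information the pipeline
does not model.

Missing genotypes are never imputed. Individuals missing any panel SNP
receive a flag and a partial score over their available SNPs, but all
cohort-level statistics are complete-case, matching the source analysis's
reduced analysis n.

## Genotype input

Dosages are stored as counts of the panel risk allele. A VCF reader
(pysam) resolves orientation against REF/ALT at load: the risk allele may
be either, a site where it is neither is an error naming the rsid, and
multi-allelic sites are rejected. Strand-ambiguous sites (A/T, C/G allele
pairs) are rejected rather than guessed at, since the orientation of such
sites cannot be established from a single file. The VCF *writer* (used
for simulated cohorts) pairs each risk allele with a transition partner;
the non-risk alleles of the real variants are not part of the panel
definition, so these partners are synthetic placeholders chosen never to
form an ambiguous pair.

## Framingham 10-year risk

Risk is the parametric survival form `risk10 = 1 − S0^exp(LP − L̄)`. The
coefficients are configuration, not code: the shipped file
(`src/grs/data/framingham_chd_1998.yaml`) encodes the sex-specific 1998
risk-factor-category CHD functions (total-cholesterol variant, CHD
endpoint), the standard published form matching the covariates this
cohort model carries. Which variant (categorical vs fully continuous) the
source analysis used is not recoverable; the categorical variant is
shipped and declared in the file header. The engine works in mmol/l and
mmHg and applies the unit conversions (× 38.67 to mg/dl for cholesterol)
declared in the file. The female equation's age² term required one
extension of the transform vocabulary (`squared`) beyond
identity/log/category-table. Blood pressure is staged jointly on systolic
and diastolic values, the higher category winning, as the published
functions specify. Out-of-range covariates trigger a warning (guard
ranges in the file), never silent truncation; missing covariates yield a
missing risk and complete-case exclusion downstream.

## Reclassification and NRI

Categories come from strictly increasing probability cutpoints; the
boundary belongs to the higher category (a 10.0% risk is "high" under a
10% cut-off). The default cut-off is 10%, with 20% as the documented
alternative — the two thresholds in current UK guidance history.

The combined risk model is a logistic recalibration
`logit P = a + b·logit(risk10) + c·GS` refitted in the analysis cohort.
The source analysis never states its combination rule; refitting is the
conservative standard choice because it nests the identity configuration
(a = 0, b = 1, c = 0), so the combined model can never be miscalibrated
relative to the conventional score by construction. Degenerate fits
(zero-variance predictor, separation) raise explicit errors.

The categorical NRI uses the per-stratum net-movement form with the
binomial-variance standard error

    se² = [ p_moved,e − net_e² ] / n_e + [ p_moved,ne − net_ne² ] / n_ne

(`p_moved` the stratum's fraction reclassified in either direction,
`net` its signed net fraction). This is the formula-selection oracle of
the test suite: it reproduces both published CI pairs and p-values
exactly at one-decimal rounding from the published counts, whereas the
simpler form without the squared-term correction does not. When nobody is
reclassified the NRI is 0 with zero SE and undefined z/p, reported as
such. p-values are two-sided normal throughout, with no multiplicity
adjustment (none was applied in the source analysis).

The "up-classified only" comparison is not uniquely recoverable from the
source text; the implemented choice — a pooled two-proportion z-test of
the event rate among up-classified individuals against those whose
category did not change — is documented here as this package's
definition, and the corresponding published cells are deliberately not
used as test oracles.

ROC areas are computed from midranks (Mann-Whitney form) and compared
with the DeLong structural-components covariance for paired AUCs,
implemented directly and unit-tested against exhaustive pair enumeration
on small instances.

## Cohort statistics

* Allele frequencies: `raf = Σg/2n` with Wilson score 95% intervals on 2n
  allele trials (Wald intervals misbehave at the panel's near-boundary
  frequencies, e.g. 0.01 and 0.99; the source's interval method is
  unstated).
* Hardy-Weinberg: Pearson 1-df χ² against `n p², 2npq, n q²` with p
  estimated from allele counts; monomorphic sites report χ² = 0, p = 1;
  significance at unadjusted α = 0.05.
* Cross-population frequency comparison: two-sample pooled-variance
  z-test of proportions; `z²` equals the Pearson χ² of the corresponding
  2×2 allele table (a property test enforces the identity to 1e-9).
* Group comparisons: Welch's unequal-variance t-test (with a
  summary-statistic variant for published mean/SD/n rows) and Pearson χ²
  without continuity correction for categorical variables. Welch is used
  everywhere because it nests the equal-variance case; the source names
  Welch explicitly for one table and is silent for the other.
* Quintile trend: quintile boundaries are the empirical 20/40/60/80
  percentiles of the pooled analysis sample (cases plus non-cases — the
  pooling choice is not stated in the source and is fixed here), with
  boundary ties assigned to the lower quintile. Per-quintile odds ratios
  come from a maximum-likelihood logistic model with quintile indicators
  (bottom quintile reference) plus age (and sex where relevant); the
  trend p is the Wald p of a single ordinal quintile term in a second
  model. Fits start at zero coefficients with a 1e-8 convergence
  tolerance.
* Power: the normal-approximation two-means formula
  `n = 2 (z_{1−α/2} + z_{power})² σ̄²/δ²`, `σ̄² = (sd1² + sd2²)/2`,
  ceiling-rounded, with a nearest-ten reporting helper. With the
  published score summaries (δ = 0.10, SDs 0.48/0.45) this gives 339.8 →
  340 per group.

## Synthetic cohorts

The generator draws independent loci, `g ~ Binomial(2, RAF)` — in
Hardy-Weinberg equilibrium by construction — at the published risk-allele
frequency profiles (UK cohort; Islamabad and Lahore control groups).
Outcomes follow a logistic model whose genetic term uses the panel
weights under the same additive/recessive coding as the score, scaled by
`effect_multiplier` (0 = null, 1 = published effects), plus independent
conventional-risk-factor effects; the intercept is calibrated by Brent
root-finding so the cohort-average event probability matches the target
prevalence to 1e-6. The prospective design keeps outcomes as drawn
(2775 men at event fraction 284/2775 for the UK scenario); the
case-control design samples the requested numbers of cases and controls
(321/228 and 414/219) from a larger simulated population.

Parameter choices not derivable from published tables, fixed once:

* UK genotype missingness 4% per genotype, which reproduces roughly the
  published complete-case fraction for score-plus-risk analyses
  ((1−0.04)¹⁹ ≈ 0.46 of 2775 ≈ the published ~1164/2775 with covariate
  missingness on top); the Pakistani scenarios default to complete
  genotypes.
* UK HDL cholesterol 1.30 ± 0.35 mmol/l (not published for that cohort;
  typical for middle-aged UK men); Pakistani blood-pressure and some
  lipid moments likewise unpublished and set to typical values, as noted
  in each scenario's docstring.
* Covariate log-odds effects (age 0.07/y, SBP 0.015/mmHg, total
  cholesterol 0.30 and HDL −0.50 per mmol/l, smoking 0.55, diabetes
  0.60) chosen once to give case/control covariate contrasts of the size
  seen in middle-aged CHD cohorts.
* The Lahore case count is printed inconsistently in the source (414 in
  the abstract, 404 in the characteristics table); the scenario uses
  414/219 and records the variant here.

What the simulator deliberately does **not** model: linkage
disequilibrium (the score treats SNPs independently), population
substructure (the suggested cause of the real Islamabad HWE failures —
simulated genotypes are always in HWE, so equilibrium rejections in
simulated data reflect only the test's level), covariate correlation
(joint moments are unpublished; marginals are independent normals or
Bernoullis, lightly floored at physiologic minima), survivor bias in the
retrospective designs, age-dependent covariate drift, and measurement
error. Consequently passing pipeline tests on synthetic data shows the
machinery is correct under the assumed generating model; it does not
certify performance of the scores in real populations, where the
simulator's independence assumptions fail. The synthetic NRI and AUC
gains are systematically larger than the published ones because the
simulated gene score is exactly causal.

## Problem sizes and numerics

The test suite and the acceptance script use cohorts of 2,775 (study
size), 20,000 × 50 replicates for parameter-recovery coverage (test
suite; 20 replicates in the acceptance script), and 50,000 for analytic
mean checks and the cross-population contrast — sizes chosen so every
stochastic assertion sits at least three standard errors from its
boundary under the generating model. All randomness flows through
`numpy.random.default_rng` seeds carried in the simulation specs.
Logistic fits are statsmodels maximum likelihood (Newton) from zero
starts; intercept calibration uses Brent's method on [−40, 40] with
1e-10 bracket tolerance. Scores and risks are kept at full float
precision internally; reporting rounds to two decimals.
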