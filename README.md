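# grs — coronary heart disease gene scores and their clinical utility

`grs` implements a complete analysis pipeline for asking whether a small
multi-SNP **gene score** adds clinical value to conventional coronary heart
disease (CHD) risk prediction, and whether the same score transfers across
populations. It is written for epidemiologists and statistical geneticists
who want the whole chain — panel definition, genotype I/O, score
construction, Framingham-form 10-year risk, risk-category reclassification
with the net reclassification improvement (NRI), ROC comparison,
population-genetic checks, quintile trend analysis and power calculation —
as tested, reusable library code with a thin CLI and a set of narrative
analysis scripts.

## The model

For individual *i* with risk-allele dosage `g_ij ∈ {0, 1, 2}` at panel SNP
*j* with published per-allele odds ratio `OR_j`, the weighted gene score is

    GS_i = Σ_j  w_j · c(g_ij),      w_j = ln OR_j

where `c(g) = g` for additive SNPs and `c(g) = 1{g = 2}` for the single
recessively scored variant (*NOS3* rs1799983). The shipped panel has 19
variants; 13 of them (the GWAS-consortium loci) form the 13-SNP subset.
One variant (*APOE* rs7412, OR 0.80) is protective and contributes
negatively.

Conventional risk is the Framingham parametric survival form

    risk10 = 1 − S0 ^ exp(LP − L̄),

with sex-specific coefficients shipped as a documented YAML file. Combined
risk is obtained by logistic recalibration,
`logit P(event) = a + b·logit(risk10) + c·GS`, fitted by maximum
likelihood; individuals are then re-classified against 10% (or 20%)
ten-year-risk cut-offs and the categorical NRI

    NRI = (up_e − down_e)/n_e − (up_ne − down_ne)/n_ne

is reported with its binomial-variance standard error, 95% CI and normal
p-value. Discrimination is compared by the DeLong test for paired ROC
areas.

Because no individual-level cohort is distributed, the package ships a
synthetic cohort generator (`grs.simulate`) that reproduces the assumed
structure: independent Hardy-Weinberg loci at published risk-allele
frequencies, a logistic disease model with the panel log-odds ratios as
effects, and conventional risk factors at published group moments — with
ready-made UK prospective and two Pakistani case-control scenarios.

## Worked example

```python
import grs

panel = grs.default_panel()                      # 19 SNPs, 13-SNP subset
geno, cohort = grs.simulate_cohort(grs.nphsii_scenario(seed=1))
scores = grs.compute_scores(geno, panel, subset=19)
risk = grs.framingham_risk10(cohort)

ids = scores.index[scores["complete"]].intersection(risk.dropna().index)
updated, _ = grs.combine_risk(risk.loc[ids], scores.loc[ids, "score"],
                              cohort.loc[ids, "outcome"])
old = grs.classify_risk(risk.loc[ids].to_numpy())     # 10% cut-off
new = grs.classify_risk(updated.loc[ids].to_numpy())
res = grs.nri(grs.reclassification_table(old, new,
                                         cohort.loc[ids, "outcome"]))
print(f"NRI {100*res.nri:.1f}% "
      f"({100*res.ci95[0]:.1f}%–{100*res.ci95[1]:.1f}%), "
      f"p = {res.p_two_sided:.3f}")
```

prints

```
NRI 13.5% (3.4%–23.5%), p = 0.009
```

i.e. on this synthetic cohort of 2775 men (1297 with complete genotypes
and risk factors), adding the 19-SNP score moves a net 13.5% of events up
and non-events down relative to the Framingham classification. The NRI is
larger than in real data because the simulated score is exactly causal
with the published effect sizes and the simulator has no survivor bias,
measurement error or linkage structure.

The same steps are available from the shell:

```
grs simulate --scenario nphsii --seed 1 --out-prefix cohort
grs score --genotypes cohort.dosage.tsv --subset 19 --out scores.tsv
grs framingham --pheno cohort.pheno.tsv --out risk.tsv
grs reclassify --risk risk.tsv --scores scores.tsv \
    --pheno cohort.pheno.tsv --thresholds 0.10 --out reclass.tsv
grs power --delta 0.10 --sd1 0.48 --sd2 0.45
```

The numbered scripts under `analysis/` run the full study narrative
(simulate cohorts → score distributions → reclassification → population
genetics → quintiles and power) and write their tables under `results/`;
bulky regenerable cohort files go to `scratch/`.

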