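# apoekit

Tools for the APOE epsilon-haplotype dementia analysis in cohort studies:
diplotype calling from phased genotypes, survival and logistic
genotype–dementia models, stratified population attributable fractions
(PAF) with an allele-level ε3/ε4 decomposition, and a phenome-wide
association screen. A bundled synthetic-cohort generator reproduces the
statistical structure of a large two-population South Asian biobank
(~51 000 participants, ~600 dementia cases), so the entire pipeline is
exercisable and testable without access-controlled cohort data.

## The science in brief

Two coding SNPs in *APOE* — rs429358 (chr19:44908684 T/C) and rs7412
(chr19:44908822 C/T, GRCh38) — define the epsilon haplotypes on each
phased chromosome: T–T = ε2, T–C = ε3, C–C = ε4 (C–T is the rare ε1,
called here with a warning). A person's unordered pair is their
diplotype. ε4 raises dementia risk dose-dependently; ε2 is protective.

**Association.** Cox proportional-hazards models on an age time scale
with origin at 16 years (cases: age at diagnosis − 16; controls:
administrative censoring age − 16), adjusted for age at recruitment,
gender, ten genetic principal components and binary genetic ancestry.
Genotypic (each diplotype vs ε3/ε3), additive (ε4 dose 0/1/2) and
dominant (any ε4) codings; logistic regression, gender-stratified fits
and a late-life (origin 60) configuration as sensitivity analyses;
Schoenfeld-residual diagnostics for proportional hazards.

**Attributable fractions.** With the low-risk ε2/ε2 genotype as
reference, each exposed genotype stratum *g* contributes the case-load
PAF

    PAF_g = CF_g · (OR_g − 1) / OR_g

where CF_g is the fraction of all cases with genotype *g* and OR_g the
fitted odds ratio versus ε2/ε2. The joint PAF sums the five ε3/ε4-
containing strata; the mixed ε3/ε4 stratum is split between the two
alleles with weight w = R/(R+1), R = OR(ε2/ε4)/OR(ε2/ε3), so that
PAF_ε3 + PAF_ε4 equals the joint PAF exactly. Confidence bounds
recompute each stratum at OR·exp(±1.96·SE) and sum.

**PheWAS.** Binary traits with ≥ 500 cases and quantitative traits with
N > 1000 are screened against each genotype (reference ε3/ε3) with the
same covariates, under a study-wide Bonferroni threshold α/m and
Benjamini–Hochberg FDR flags.

## Worked example

```bash
apoekit simulate --n 20000 --seed 11 --out cohort/
apoekit call-apoe cohort/genotypes.vcf --out cohort/diplotypes.tsv
apoekit associate cohort/phenotypes.tsv cohort/diplotypes.tsv --coding additive
```

which prints (abridged; 256 events in this cohort):

```
   term  estimate       se  ci95_low  ci95_high    ratio        p  n_samples  n_events        model
e4_dose  0.411674 0.123661  0.169298   0.654051 1.509343 0.000871      20000       256 cox_additive
```

The `e4_dose` row is the per-ε4-allele log hazard ratio: each ε4 copy
multiplies the dementia hazard by exp(0.412) ≈ 1.51 (95% CI 1.18–1.92),
consistent with the generator's genotype hazard ratios (1.5 for ε3/ε4,
2.7 for ε4/ε4). The same cohort can
be pushed through `describe`, `paf` and `phewas`, or everything at once
with `apoekit run-all --seed 11`, which writes a markdown + JSON report
with genotype tables, fitted models, the PAF decomposition and the
PheWAS screen.

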