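# Methods

This note documents the models, generative assumptions, numerical
choices and known limitations of `apoekit`. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Diplotype calling

Haplotypes are called from the phased allele pair at rs429358
(chr19:44908684 T/C) and rs7412 (chr19:44908822 C/T, GRCh38):
T–T → ε2, T–C → ε3, C–C → ε4, C–T → ε1. Sites are located by
chromosome and position with the rs identifier as a fallback, and the
file's REF/ALT orientation is validated; a mismatch is a fatal error
because silently flipping alleles would exchange ε3 and ε2/ε4 calls.
Phase matters only for double heterozygotes (ε2/ε4 versus ε1/ε3), so
"/" separators are accepted at homozygous sites. Policy decisions:

- **ε1** (the fourth corner of the 2×2 allele square) is called and
  counted but excluded from association stages by default; the
  three-haplotype analysis has no category for it, and silent
  misclassification would be worse than exclusion.
- **Missing or ambiguous calls** are excluded listwise with a logged
  reason (complete-case analysis). An optional policy resolves
  unphased double heterozygotes as ε2/ε4, the only configuration not
  requiring an ε1 haplotype when ε1 is vanishingly rare.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis stages
assume, with defaults matching the cohort conditions the package
replicates:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 51 104 | cohort size |
| `hap_freqs` | ε2 .044 / ε3 .852 / ε4 .104 | i.i.d. haplotype draws (so genotypes are at Hardy–Weinberg) |
| `ancestry_props` | .587 / .413 | two-population mix |
| `true_log_hr` | log{0.8, 0.8, 1.6, 1, 1.5, 2.7} | genotype hazard ratios vs ε3/ε3 |
| `baseline_hazard` | 3.6e-4 /person-year | constant ε3/ε3 hazard from age 16 |
| `recruitment_age_median/iqr` | 39 / 17.5 years | log-normal recruitment age |
| `censor_date` | 2024.92 | administrative censoring (December 2024) |
| `pc1_ancestry_shift` | 1.0 SD | deliberate ancestry–PC confounding |
| `trait_effects` | LDL +.12, TG +.10, TC +.12, HDL −.05, CRP −.08 per ε4 allele (SD units) | lipid-like traits |

Onset is drawn from the proportional-hazards model with cumulative
baseline hazard λ·t^k from age 16 (k = 1, the exponential default;
a Weibull shape is available via `weibull_shape`). The event is
observed iff latent onset age ≤ censoring age (censor date − birth
year). `baseline_hazard` was set from the closed-form expectation
`events ≈ n · λ · E[HR] · E[censor age − 16]` so a study-scale cohort
yields roughly 600 events, matching the emulated case load.

All randomness descends from one seed through named substreams
(haplotypes, covariates, onset, traits), making runs byte-reproducible
and stage-toggling non-interfering.

**What the generator does not emulate.** Constant hazard from age 16
spreads onsets uniformly over follow-up, so simulated cases are *not*
concentrated in old age as real dementia is (real median onset ~73;
the generator's is decades younger unless a Weibull shape ≫ 1 is
configured). It has no linkage disequilibrium beyond the two sites, no
genotype missingness, no masked small cells, and traits have no
covariate structure beyond the ε4 dose effect. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data pathologies such as ascertainment bias or
informative censoring.

## Survival and logistic models

- **Time axis**: age from the origin (16 primary, 60 for the late-life
  sensitivity configuration, which also restricts to participants
  recruited at or after the origin). Left truncation at recruitment is
  available (`left_truncation=True`) but off by default, mirroring the
  replicated construction; without it, a recruited cohort contributes
  immortal person-time before recruitment. This is documented rather
  than silently "fixed" — the option exists precisely so both
  constructions can be compared.
- **Covariates**: age at recruitment, gender, PC1–10, binary ancestry.
  Age at recruitment is retained as a covariate even on the age-based
  clock, for fidelity to the replicated specification; it is droppable
  via `covariates`.
- **Ties**: Efron partial likelihood (lifelines). Simulated ages are
  continuous so ties are rare anyway.
- **Non-estimable categories**: a genotype with zero events is dropped
  from the design and reported as `non_estimable` rather than letting
  the partial likelihood diverge; its samples merge into the reference.
- **ε2/ε2-referenced logistic fits**: with ~1 expected reference case
  at study scale, a substantial fraction of simulated cohorts have
  *zero* ε2/ε2 cases, making every contrast non-identifiable. Such
  fits are flagged (`reference_no_events`) and the PAF stage refuses
  them with an informative error instead of propagating divergent odds
  ratios. This is the rare-reference precision problem taken to its
  extreme, and it dominates the width of the PAF intervals.
- **Gender stratification** is implemented as fully separate
  per-stratum fits (all covariate effects free per stratum), not a
  stratified baseline hazard with shared coefficients.
- Convergence: lifelines defaults (Newton-Raphson on the log partial
  likelihood, zero initialisation); p-values are normal-approximation
  Wald tests; intervals use ±1.96·SE throughout.

## Schoenfeld diagnostics

Per-covariate proportional-hazards tests use the classic
Grambsch–Therneau score test on scaled Schoenfeld residuals with a
rank time transform (lifelines). The **global** test — absent from
lifelines — is implemented here from raw Schoenfeld residuals:
T = u' D⁻¹ u with u = Σ(g_k − ḡ)s_k and D = Σ(g_k − ḡ)² · V̄, V̄ the
average per-event information, referred to χ² on p degrees of
freedom. Note that R's `survival::cox.zph` (≥ 3.0) uses a per-time
variance refinement and gives different statistics; the implementation
here is validated by null calibration and a time-varying-effect power
simulation instead of an equality check against R. Diagnostics are
skipped with a warning below 10 events.

## Attributable fractions

The stratum PAF is the case-load (Miettinen/Hanley) form
CF·(OR − 1)/OR with ORs taken as risk-ratio approximations (no
odds-to-risk conversion, appropriate for an outcome with ~1.2%
cumulative incidence; an exact-identity test verifies the formula
equals (observed − expected-under-reference)/observed cases when ORs
are true risk ratios). An alternative arrangement of the same
quantities, (OR − 1)/(OR·CF), is available behind `literal_formula`
for auditability; it is not a fraction of cases (it exceeds 1 for
small case fractions) and is never used by the pipeline.

Design choices inherited from the replicated analysis and kept
deliberately: the ε2/ε4 stratum is attributed wholly to ε4 (only the
mixed ε3/ε4 stratum is weight-split by w = R/(R+1)); bound propagation
recomputes each stratum at its Wald OR limits and sums, treating
strata as independent — a transparent bound, not a delta-method or
bootstrap interval (the latter are possible extensions, not needed for
replication). The decomposition's bounds move the split weight to the
ratio's own Wald limits, with SE(log R) = √(SE₄² + SE₃²).

## PheWAS

Eligibility (binary ≥ 500 cases; quantitative N > 1000, strict) is
fixed before fitting and defines the multiplicity count m; failed fits
keep their slot so the Bonferroni threshold α/m is never inflated by
data-dependent exclusions. The multiplicity unit is *traits* by
default (genotype terms within a trait share its slot), with a
`pairs` switch counting trait×genotype tests. Quantitative traits are
analysed untransformed by default (a rank-based transform would be a
natural extension); binary traits use logistic fits with
normal-approximation p-values. Benjamini–Hochberg flags are computed
at the same α, and a Bonferroni pass always implies an FDR pass.

## Problem sizes used by the test suite and acceptance script

Chosen as the smallest designs that make each check statistically
meaningful: hazard-ratio recovery uses 20 replicate cohorts at the
full study scale (51 104 samples, ~600 events each); null calibration
uses 200 fits on 4000-sample cohorts with the baseline hazard raised
to 3e-3 so each fit retains ~350 events; the PheWAS family-wise error
uses 200 replicates of 20 null traits on 2000-sample cohorts; PAF
engine checks are exact arithmetic plus 1000 fuzzed stratum tables.

## Known limitations

- The acceptance surface for the PAF decomposition is qualitative: the
  per-genotype odds ratios versus ε2/ε2 that feed it are not part of
  the generator's truth set (the generator is parameterised by hazard
  ratios versus ε3/ε3), and the rare reference makes per-seed
  estimates extremely noisy — which is itself the faithful behaviour.
- No competing risks, frailty, time-varying coefficients (beyond the
  diagnostic), imputation dosages, or rare *APOE* coding variants
  beyond the two defining SNPs.
- The binomial carrier-enrichment reference proportion (default 0.288)
  is an external numeric parameter, not re-derived from any reference
  cohort.
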