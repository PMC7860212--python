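# Methods

## The statistical problem

A polygenic risk score (PRS) for heel speed of sound (SOS) — a continuous
skeletal measure predictive of osteoporotic fracture — is a weighted sum of
genotype dosages. `polyfrax` covers the three stages such a score passes
through on its way to clinical use: construction from individual-level
genotypes and phenotypes, integration with an absolute-risk tool (FRAX)
whose 10-year probabilities are taken as an input, and evaluation of what
the score adds to discrimination and reclassification.

## PRS construction

**GWAS.** Each variant is tested by OLS of SOS on (dosage, covariates,
intercept), computed jointly via Frisch–Waugh–Lovell residualization;
two-sided p-values come from the t distribution with n − p − 2 degrees of
freedom. Covariates default to age, sex and the top 10 principal
components of the column-standardized dosage matrix (configurable). A
linear mixed model is the field standard at biobank scale, but the random
effect models cryptic relatedness, which the synthetic cohorts do not
contain; the fixed-effects fit preserves the adjustment structure at desk
scale. Monomorphic variants get beta 0, infinite standard error and p = 1,
so thresholding drops them without special-casing.

**LD pruning.** Greedy pass over variants in ascending p-value order
(variant id as a stable tie-break), retaining a variant iff its squared
dosage correlation with every retained variant on the same chromosome is
≤ r²_max (default 0.05). Ordering by p keeps the strongest signal of each
LD clump, matching standard clumping logic.

**Thresholded LASSO.** For each threshold in
{5×10⁻³, 5×10⁻⁴, 5×10⁻⁵, 5×10⁻⁶, 5×10⁻⁷, 5×10⁻⁸}, an L1-penalized least
squares fit (coordinate descent, via scikit-learn's `lasso_path`) on the
pruned passing variants. Dosage columns are standardized for the fit and
weights are reported back on the raw 0–2 dosage scale, so scoring needs no
standardization step. The penalty path is 50 log-spaced values from
λ_max = max|X'y|/n down to λ_max·10⁻³; λ is chosen to maximize R² on the
model-selection split (the within-threshold tuning rule is an artifact
convention; the source analyses do not state one). Between thresholds, the
candidate with the highest selection-set R² wins; ties go to the smaller
(less permissive) threshold. Zero passing variants yield a null model with
a warning, not an error.

**Scoring.** score_i = Σ_j w_j·d_ij over model variants present in the
target genotypes. Allele flips (target effect allele = model other allele)
use 2 − d; variants with an unresolvable allele pair are skipped with a
logged count (losing > 50% of the model is an error); absent variants
contribute nothing — a subset sum without rescaling, replicating how a
score built on one imputation panel is applied to a cohort imputed to
another (an optional flag rescales by the weight mass present, off by
default). Sporadically missing genotypes at present variants are imputed
as 2 × reference allele frequency (training frequency if none supplied).
Models round-trip through tab-delimited PGS-Catalog-layout scoring files
(`rsID, chr_name, chr_position, effect_allele, other_allele,
effect_weight`, `#` comment headers); unknown columns are ignored,
non-numeric weights are rejected with the line number.

## Odds-space integration

gSOS is standardized per cohort (mean 0, sample n−1 SD 1; an option reuses
training-set parameters). With baseline probability p and standardized
score z, the adjusted probability is (o/f^z)/(1 + o/f^z) with o = p/(1−p).
The per-SD factors default to 1.42 (major osteoporotic fracture, MOF) and
1.80 (hip), the meta-analytic per-SD-of-SOS odds ratios the method keys
on. Three properties are exact algebra, and tested as such: odds change by
f-fold per SD for any p; the map is invertible; it is strictly monotone in
both arguments. Probabilities are clamped to [10⁻⁶, 1 − 10⁻⁶] before the
odds transform to keep odds finite (boundary handling is unstated in the
source analyses; clamping is this package's convention, and clamps are
logged).

## Evaluation

- **Percentile groups:** average ranks; individual in group g iff rank/n ∈
  (edge_{g−1}, edge_g]; default edges (1, 5, 20, 40, 60, 80, 95, 99)% give
  the canonical nine groups. Incidence is a plain proportion with a Wilson
  interval by default (Clopper–Pearson optional) — the source reporting
  names only "binomial proportion CIs".
- **Logistic associations:** statsmodels GLM (IRLS); Wald CIs on the OR
  scale; likelihood-ratio test p from the χ² upper tail. Complete
  separation is flagged (|standardized coefficient| > 15), not silently
  returned.
- **Prevalence-matched binarization:** indicator of the ⌊n·target⌋ lowest
  scores, stable tie order, for comparing a continuous score to a binary
  risk factor at matched frequency.
- **AUROC** is the normalized Mann–Whitney U with half-credit ties;
  **AUPRC** a step integral of precision over recall at distinct
  thresholds with no interpolation (PR-space interpolation is biased).
  Bootstrap CIs are percentile intervals over 200 outcome-stratified
  resamples, seeded. **DeLong's test** uses placement-value components;
  degenerate variance returns p = 1 with a log message.
- **Survival:** age is the time scale, so subjects enter the risk set at
  baseline age (left truncation) and the Kaplan-Meier estimator
  (lifelines) censors at 90 years by default. The Cox partial likelihood
  with Breslow ties and delayed entry is implemented directly
  (Newton-Raphson to gradient < 10⁻⁸) because no installed package exposes
  that combination; it is cross-checked against lifelines'
  start-stop Cox fit on tie-free data, where Breslow and Efron coincide.
  Harrell's C counts a pair as usable iff the earlier exit is an event and
  the other member is at risk at that age.
- **Reclassification:** two categories at the clinical cutoff (20% MOF,
  3% hip, above which treatment is recommended); probabilities exactly at
  the cutoff count as high-risk. NRI = [P(up|event) − P(down|event)] +
  [P(down|nonevent) − P(up|nonevent)]; the continuous variant reads "up"
  as any increase. IDI is the change in the mean-risk gap between events
  and nonevents. CIs are asymptotic normal by default with a bootstrap
  option.

## Synthetic cohort: what it emulates, and what it does not

Defaults state a mixed-age European-biobank-like world:

- **Genotypes:** biallelic dosages as sums of two haplotypes whose allele
  indicators follow a latent Gaussian AR(1) within blocks of 10 variants
  (block-wise LD with controllable decay; blocks independent, 22
  chromosomes assigned cyclically by block). MAF uniform on (0.05, 0.5);
  pipeline default ρ = 0.3 gives pruning something to do.
- **Phenotype:** sos = G·w + ε with round(prop_causal·m) Gaussian weights
  (default 5% causal) and noise scaled to a target heritability h²
  (default 0.25, the variance fraction a genome-wide SOS score is known to
  be able to capture); returned standardized.
- **Risk factors:** independent Bernoulli columns at prevalences near
  published cohort tables (prior fracture 10%, smoking 8.6%,
  corticosteroids 1.2%, rheumatoid arthritis 1.0%, parental fracture 14%,
  at-risk drinking 3%, falls 21%); age uniform on 40–69; 54.6% female. By
  default risk factors are independent of genotype, matching the observed
  near-zero correlations between gSOS and clinical risk factors; a knob
  (`correlate_risk_factor`) tilts a column's Bernoulli probability on the
  logit scale to induce the modest negative gSOS–prior-fracture
  correlation (~ −0.1) seen in real cohorts.
- **Baseline probabilities:** a logistic surrogate of FRAX —
  logit(frax) = logit(base rate) + Σ coef·column with literature-scale
  log-odds (age 0.06/yr, prior fracture ln 1.8, ...). The FRAX algorithm
  itself is proprietary and out of scope; real baseline probabilities are
  accepted as input columns.
- **Outcomes:** logistic with log-odds linear in −standardized SOS (slope
  ln 1.42 MOF / ln 1.80 hip by default) plus centered age and sex terms;
  base rates 3.1% MOF and 1.3% hip, the pooled incidence proportions of
  the four European evaluation cohorts the method was reported on. Cases
  get an event age uniform within the 10-year follow-up; non-cases are
  censored at entry age + follow-up. This supports the KM/Cox machinery
  but is deliberately not a realistic hazard shape.
- **Split:** 80% train / 1.25% select / 18.75% test by seeded permutation
  (floor for select, then train, remainder to test); an optional flag
  column forces individuals (e.g. those with a gold-standard BMD measure)
  into the test split.

A green test on this world establishes that the machinery is correct and
calibrated — not that real-cohort effect sizes are reproduced. Biobank
headline values (AUROC ≈ 0.73/0.80, 23% variance explained) require
hundreds of thousands of individuals and millions of variants and are not
desk-reproducible. One structural consequence worth knowing: because
fractures are driven by the *true* SOS, the per-SD odds ratio of the
*score* is attenuated to roughly f^corr(gSOS, SOS); pipeline reports
therefore carry both the gSOS association (the clinical analogue) and the
true-SOS association (the generative recovery check).

## Numerical conventions

- All randomness flows from explicit `numpy` `default_rng` seeds; a fixed
  seed reproduces runs byte-for-byte.
- Probability clamp 10⁻⁶; logistic IRLS tolerance 10⁻¹⁰, ≤ 100
  iterations; Cox gradient tolerance 10⁻⁸, |β| > 50 flags a monotone
  likelihood; LASSO coordinate-descent tolerance 10⁻⁶.
- Pruning and selection tie-breaks are deterministic (variant id, smaller
  threshold), so results are invariant to input order.

## Known limitations

- No relatedness, population structure, imputation uncertainty or
  genotyping batch effects in the generator, hence the PC adjustment is
  exercised but not stressed.
- The uniform-event-age survival structure has no age-increasing hazard;
  C-indices on synthetic data are modest by construction.
- No recalibration of adjusted absolute risks to national fracture rates,
  no competing risks, no FRAX-BMD computation (BMD-based probabilities are
  accepted as inputs when present).
- NRI/IDI intervals are asymptotic by default; at very low event counts
  the bootstrap option is preferable.
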