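# Methods

This note documents the statistical procedures, the synthetic-data world
the package tests against, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or the
acceptance script does not itself compute.

## Subgrouping

**Scaling.** Clustering operates on z-scored indicators, with location and
scale (sample SD, ddof = 1) estimated *per sex* on the baseline sample.
Z-scoring makes Euclidean distance unit-free; estimating it within the
analysed cohort (rather than importing another cohort's scaling) is a
deliberate choice, exposed through `ScalingParams`.

**Sex-stratified k-means with pooling.** Men and women are clustered
separately (Lloyd's algorithm via scikit-learn, k-means++ initialisation,
`n_init = 25` restarts, tolerance 1e-6, seeded) to avoid sex differences in
the indicator distributions driving the partition. Female clusters are
matched to male clusters by one-to-one optimal assignment
(`linear_sum_assignment`) on centroid distance — optimal rather than greedy,
because greedy matching can be suboptimal when centroids are close. The
pooled centre of a matched pair is the arithmetic mean of the scaled
vectors of *all* members of both sexes; this is re-verified post hoc in the
tests. An empty cluster triggers a re-run with a new sub-seed (logged), up
to ten attempts.

**Naming.** Fitted centres are named SIDD/SIRD/MOD/MD/MDH by the one-to-one
assignment minimising total Euclidean distance to five named reference
centres. The default reference is the published per-subgroup baseline mean
vector of the chosen registry style (DCS or GoDARTS), in raw units; it is
scaled with each sex's current ScalingParams and the two scaled vectors are
averaged, mirroring how pooled centres average both sexes. Externally
supplied centres (raw or already scaled) are accepted. The 5×5 distance
matrix is stored in the model metadata for audit.

**Assignment.** A later observation is assigned to the named centre at
minimum Euclidean distance in scaled space; exact ties break by the fixed
order SIDD < SIRD < MOD < MD < MDH. Because the pooled centres are not the
fixed point of either sex's k-means, nearest-centre reassignment of the
fitting sample is only guaranteed to reproduce the fitted partition when
clusters are well separated; the tests check it there.

**Agreement.** For a reference and candidate partition: confusion matrix
(reference rows), accuracy = trace/n with exact Clopper–Pearson 95% CI
(the CI method is unstated upstream; exact binomial is the conservative
choice), Cohen's κ with chance agreement from marginal products, and per
class: sensitivity n_cc/R_c, specificity (n−R_c−C_c+n_cc)/(n−R_c), and
positive specific agreement 2·n_cc/(R_c+C_c) — the per-class,
chance-uncorrected index.

## Longitudinal consistency

Windows are half-open duration intervals, default [0,2), [2,4), [4,6),
[6,8) years. Within a window, BMI/HbA1c/HDL are the means of available
values (the windowed summary statistic is not specified upstream; the mean
is robust to visit timing), age is the age at the first in-window visit,
and C-peptide is carried forward from baseline — follow-up C-peptide is
assumed unavailable, a faithful implementation of the analysis's own
limitation, with a switch to use measured values when present.

Two reallocation algorithms are compared: *de novo* re-clustering
(re-scale within the window, re-fit the sex-stratified k-means, name the
shifted centres against the baseline model's centres) and *centre-based*
reallocation (nearest baseline centre under the frozen baseline scaling,
no re-fitting). The asymmetry — per-window re-scaling for de novo, frozen
scaling for centre-based — is intentional: re-scaling is part of
"repeating the clustering", while centre-based reallocation is defined
relative to the baseline model.

Transition tables count label sequences of individuals observed in every
window; top-N ranking breaks count ties lexicographically. The severe/mild
dichotomy groups SIDD+SIRD as severe and MOD+MD+MDH as mild.

## Trajectory models

Annual summaries bin visits by floor(duration) and report n, mean and
sample SD per (subgroup, year); singleton bins report SD 0 with a
degeneracy flag. The longitudinal model is a linear random-intercept model
(statsmodels MixedLM) fitted by **maximum likelihood, not REML**: the
model comparison below contrasts fixed-effect structures, and REML
likelihoods are not comparable across them. AIC = 2k − 2ℓ with k counting
fixed effects plus the two variance parameters. Subgroup enters as four
contrasts against a configurable reference (SIDD by default), duration
enters linearly (no spline structure is claimed upstream), sex as a male
indicator. The optimiser tries lbfgs, then cg, then powell; a boundary
(zero) random-intercept variance is reported with the fit, not treated as
an error.

## Outcome models

All survival machinery operates on the diabetes-duration scale with
delayed entry: an individual joins the risk set at their baseline
observation duration. Cumulative incidence is 1 − Kaplan–Meier survival
(no competing-risk estimator — the upstream description is "Kaplan–Meier
methods"). Group differences use the logrank test; the statistic is
computed in-package with entry-aware risk sets (the available
implementations do not accept entry times) and reduces exactly to the
classical logrank at entry 0. Pairwise p-values are Benjamini–Hochberg
adjusted within the 10 pairs of one outcome (not across outcomes; recorded
in the output metadata). Cox models use lifelines with `entry_col`, Efron
tie handling (accurate default; ties are not discussed upstream) and Wald
95% CIs; constant covariates are dropped with a warning. The
proportional-hazards diagnostic is the Grambsch–Therneau scaled-Schoenfeld
test with rank-transformed event times, implemented in-package for the
delayed-entry case and matching lifelines exactly at entry 0; violation is
flagged at p < 0.05.

## Treatment patterns

ATC codes map to one of six mutually exclusive steps with precedence
Step3 > Step2 > Step1 > OtherOAD > OnlyCVD > NoTreatment. The "adding"
language of the step definitions implies a cumulative ladder, so the
observed step is the highest rung present; OtherOAD applies only when no
ladder drug is present. The alternative precedence (OtherOAD above the
ladder) is selectable, and outputs record the rule used. Liraglutide
(A10BX07) and dapagliflozin (A10BX09) are carved out of the generic A10BX
glinide rule. Matching is case-insensitive string-prefix on canonical
codes; malformed codes are ignored with a warning. The step of a duration
year [y, y+1) is classified from the *first* visit of the year; years
without visits are absent — no carry-forward, accepting the known
underestimation of intensive steps near the end of follow-up. Multinomial
logistic models (statsmodels MNLogit; newton with bfgs/lbfgs fallback,
since newton can overflow on sparse categories) use NoTreatment as the
reference category and MD as the reference subgroup, so the
insulin-vs-no-treatment SIDD contrast is directly the coefficient of
interest.

## Predictor-set comparison

Each target (trajectory parameter, outcome Cox model, treatment
multinomial) is fitted three times on identical data with fixed effects
{indicators, subgroups, both} and compared by AIC (partial-likelihood AIC
for Cox). Relative likelihood RL_i = exp((AIC_min − AIC_i)/2); RL ≤ 0.1 is
flagged significant. "Scaled AIC" is per-target min–max normalisation to
[0,1] (the heatmap colour scale); the definition was open and is recorded
in the output. A failed fit leaves its cell missing and keeps the row.

## Synthetic cohort generator

The generator is a stated world, not a tuning knob. Its defaults are:

* **Mixture.** Five subgroups with the published DCS (or GoDARTS) mixing
  proportions, per-subgroup male fractions, and per-indicator baseline
  means/SDs (all eleven clinical parameters). Marginals are independent
  truncated normals (truncated at 0 for positivity); no published
  within-subgroup covariances exist, so none are imposed — a documented
  limitation, with an acknowledged hook for a correlation matrix.
* **Baseline duration.** Uniform on [0, 0.5] years for DCS-style, a point
  mass at 0.02 for GoDARTS-style, reflecting the two registries' very
  different printed baseline durations (~0.3–0.5 vs ~0.02 years).
* **Trajectories.** value(t) = baseline + slope·(t − t₀) + individual
  random intercept + residual, with visits yearly to 10 years. Slopes are
  free parameters (no published values): HbA1c +0.6 mmol/mol/year for most
  subgroups but −4.0 for SIDD, representing intensive glucose-lowering
  treatment of the high-HbA1c subgroup; creatinine +0.8 µmol/l/year;
  small lipid and blood-pressure drifts. Random-intercept and residual SDs
  are 0.5 and 0.25 of the cross-sectional SD. C-peptide is constant at its
  baseline value, matching the carry-forward assumption downstream.
* **Events.** Per outcome, exponential first-event times conditional on
  survival past study entry, hazard exp(base + subgroup offset), with
  exponential censoring and an administrative end at follow-up. Base
  hazards put 10-year incidences on the registry scale (CKD common,
  PVD/ESRD rare). The one quantitatively anchored offset is SIRD-vs-MDH
  for AMI at ln(1.65); the remaining offsets are qualitative (SIRD excess
  CHF/PVD/CKD, MDH excess stroke).
* **Medication.** A monotone ladder (NoTreatment/OnlyCVD → Step1 → Step2 →
  Step3) with per-year escalation probability increasing in current HbA1c
  above the 53 mmol/mol target, initial state drawn from the published
  baseline treatment distribution per subgroup, and a parallel other-OAD
  branch whose entry rate differs by registry style (rare in DCS-style,
  common in GoDARTS-style).

What a green test establishes, therefore, is that the pipeline recovers
the structure this world actually contains — mixture components, hazard
offsets, escalation gradients, drift-driven subgroup migration — not that
it reproduces any registry's numbers. Real registries add features the
generator omits: within-subgroup correlations, non-linear and
treatment-responsive trajectories beyond SIDD, competing mortality,
informative visit schedules and missingness, and coding noise in ATC
records.

## Numerical choices and degenerate inputs

Determinism: every stochastic step is seeded; the pipeline expands one
master seed into fixed per-stage seeds recorded in the manifest, and
identical configurations reproduce outputs byte-for-byte. Baseline ties on
duration keep the first record in input order (logged). Missing
measurements are empty cells on disk, NaN in memory, never coded numbers;
missing GAD status excludes by default (conservative), with a
missing-as-negative switch. Zero variance in a scaling stratum, strata
smaller than k, event times at or before entry, empty label sequences and
out-of-range p-values all raise informative errors. RL can underflow to
exactly 0.0 for AIC gaps beyond ~1400 although it is mathematically
positive.

## Known limitations

No competing-risk (Fine–Gray) modelling, no random slopes or splines in
the mixed models, no imputation, no time-varying Cox covariates, no
alternative cluster counts (k is fixed at 5), and no GAD-based autoimmune
subgroup (excluded by design). The synthetic generator matches first
moments only.
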