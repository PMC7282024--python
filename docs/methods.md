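# Methods

This note documents the models, default parameters and design choices
behind `dietsurv`, and what the synthetic-data tests do and do not
establish about real survey data.

## Dietary TAC

Dietary total antioxidant capacity is a linear functional of the
antioxidant intake profile: `TAC = Σᵢ xᵢ·vᵢ`, where `xᵢ` is the daily
intake of compound *i* in mg and `vᵢ` its vitamin-C-equivalent (VCE)
antioxidant capacity in mg VCE per mg, as assayed against the ABTS
radical cation in the source literature. Linearity and additivity are
exact contracts (property-tested), so aggregation of compounds into
classes is the caller's concern; the table is one row per compound.

The shipped coefficient file is a **placeholder** (all 1.0, under which
TAC degenerates to total antioxidant mass). The package deliberately
does not invent coefficient values; they are configuration with
per-entry provenance, and vitamin C is 1.0 by definition of the unit.

### Energy adjustment (residual method)

`energy_adjust` regresses the quantity on total energy by OLS and
returns residual + prediction at the cohort-mean energy. Contracts:
correlation of the adjusted values with energy is 0 to 1e-8; the
cohort mean is preserved; the operation is idempotent and
translation-equivariant. The regression runs on the untransformed scale
by default; a log-scale variant (regress log-intake, exponentiate back)
is available via `log_scale=True` for heavily skewed intakes, since the
plain residual method can produce negative adjusted values in the left
tail. Constant energy raises a degeneracy error (undefined slope).

## Diet-quality indexes

Component inputs are resolved through a crosswalk file
(`data/crosswalk.yaml`) because the four indexes group foods
differently (aMED scores fish alone; HEI-2015 pools seafood with plant
proteins). Serving-unit conversions are encoded there as scales
(1 cup eq = 2 servings, 1 oz eq whole grains = 28.35 g, 237 g SSB = 1
serving, 4 oz meat = 1 serving, ¼ cup legumes = 1 oz eq protein).

* **HEI-2015** — 13 components on a per-1000 kcal density basis except
  the (MUFA+PUFA)/SFA ratio; each scored linearly between a 0-point and
  a full-point standard (5 or 10 points; totals 0–100). The standards
  CSV ships the source publication's values and is editable. Legumes
  are counted in total vegetables, greens-and-beans, *and*
  seafood/plant proteins via fixed crosswalk entries; the original
  index's protein-first legume reallocation algorithm is not
  reproduced — a simplification that slightly favours legume-heavy
  diets. Zero saturated fat with positive unsaturated fat scores the
  ratio component at its maximum (ratio → ∞ → clipped).
* **AHEI-2010** — the study's 10-component variant (no trans fat), each
  worth 10 points, linear between cutoffs; whole-grain cutoffs and the
  alcohol window are gender-specific. Sodium, decile-based in the
  source cohort, uses fixed mg/day cutoffs equal to that cohort's
  extreme-decile medians (1112 full / 3337 zero). Alcohol: 10 points
  inside the moderate window (0.5–2.0 drinks/day men, 0.5–1.5 women),
  0 at/above the heavy cutoff (3.5 / 2.5), abstainers 2.5; between 0
  and the window's lower edge the score interpolates linearly from 2.5
  to 10 (the source does not pin this segment down), and linearly from
  10 to 0 between window top and heavy cutoff. Scored in drinks/day.
* **aMED** — 1 point per component for intake strictly above the
  cohort median (below, for red/processed meat; inside 10–25 g/day for
  men and 5–15 g/day for women, for alcohol). Medians are cohort-wide
  by default (`gender_specific_medians` switches to within-gender
  medians); cutpoints are computed on raw servings, not energy-adjusted
  ones. Totals 0–9.
* **DASH** — adequacy components earn their cohort quintile (1–5),
  moderation components the reverse (6 − quintile); totals 8–40.

### Quintiles and ties

All cohort fifths (DASH components, exposure quintiles) use stable-rank
assignment: sort stably in input order and cut at n/5 boundaries, so a
tie block spanning a boundary is split deterministically by position.
This matters because heaped serving counts (and zero-inflated SSB or
alcohol intakes) make large tie blocks common; group sizes then deviate
from n/5 by at most the tie-block size. Weighted quintiles place each
participant by the weight mass strictly below it, which reduces exactly
to the unweighted rule under equal weights. Weighted cutpoints default
off (survey weights are applied in the models, not the cutpoints), with
a switch.

## Exclusion cascade

Rules run in the study order (mortality eligibility → recall
reliability → energy in (500, 5000) kcal/day, bounds *exclusive* →
cancer history → pregnancy/breastfeeding → TAC > mean + 3 SD), each
participant charged to the first rule it violates, so counts are
sequential. The TAC threshold is computed on the cohort surviving the
prior rules, on raw TAC by default (the energy-adjusted variant is a
switch). A ledger records (rule, excluded, remaining) and supports
being seeded directly from printed counts for arithmetic audits.

A small-sample caveat: a mean + 3 SD rule cannot fire in very small
cohorts (the largest attainable z-score in a sample of n is
(n−1)/√n), so toy fixtures need ≳11 survivors for the rule to be
triggerable at all.

## Synthetic cohort generator

The generator emulates the *joint structure* the analysis assumes, not
any particular survey's food coding:

* **Intakes** are log-normal with a shared latent energy factor.
  Defaults put each food group and nutrient at typical US-adult
  24h-recall levels (e.g. total fruits ≈ 1.3 cup eq, sodium ≈ 3.2 g,
  energy ≈ 2030 ± 650 kcal truncated to [600, 6500]) and flavonoids
  dominate the antioxidant profile with the largest log-scale spread,
  so summed TAC is strongly right-skewed, as observed in practice.
  SSBs and alcohol are zero-inflated (35% / 60% non-consumers).
  Because Pearson correlation attenuates under exponentiation, the
  latent normal correlation is inflated in closed form
  (r = ρ·√(e^{σ²}−1)/σ) so that the *configured* ρ is the realized
  intake–energy correlation (verified to ±0.05 at n = 5,000).
* **Covariates** are drawn independently from a configured category mix
  (defaults approximating a US adult cohort aged 30+); age and BMI are
  truncated normals. Dependence between diet and covariates is *not*
  modelled by default — the real-data joint distribution is unknown —
  so passing tests establish the correctness of the scoring and fitting
  machinery, not robustness to diet–covariate confounding patterns
  beyond those explicitly configured via `confounder_log_hr`.
* **Flags** (ineligible mortality, unreliable recall, cancer history,
  pregnancy/breastfeeding) fire independently at rates scaled from the
  study's printed exclusion counts.
* **Survival** times are exponential: hazard = baseline ×
  exp(quintile log-HR + confounder terms), administratively censored at
  the follow-up horizon (14.9 years, baseline 0.023 events/person-year
  by default, matching the study's overall death rate). Constant
  baseline hazard satisfies proportional hazards exactly, so
  parameter-recovery tests isolate the fitting code. Numeric
  confounders enter centred at the cohort mean, making the baseline the
  hazard of an average reference-group participant. Calendar time is
  not modelled; follow-up is a duration.

## Survival models

Weighted Cox partial likelihood (Efron ties, via lifelines) with
quintile indicators (first fifth reference) and three nested covariate
tiers: (1) age in 5-year bands, gender, race/ethnicity, BMI, energy;
(2) + income band, marital status, physical activity, CVD/diabetes/
hypertension histories; (3) + smoking (3 levels). Constant covariate
columns (e.g. an empty category) are dropped with a log message.

Variance is the Lin–Wei robust sandwich `A⁻¹BA⁻¹`, computed in-package
from vectorised score residuals (Breslow form — identical to Efron when
event times are untied, as simulated continuous times are), with
optional cluster summation; it reproduces lifelines' `robust=True`
standard errors to machine precision on untied data at a fraction of
the cost. This weighted-plus-cluster-robust approximation stands in for
full multistage stratified survey variance, which is a documented
limitation. Scaling all weights by a constant leaves estimates
unchanged; equal weights reproduce the unweighted fit.

Both trend statistics are Wald tests with robust SEs from refits with a
single continuous covariate: each participant's group-median exposure,
or the group index 1–5. They are reported side by side because a
right-skewed exposure makes the group-median spacing extremely uneven,
and the two constructions can then disagree materially. The
proportional-hazards check is deliberately visual: `ph_diagnostic`
emits per-group log(−log S(t)) tables from weighted Kaplan–Meier fits
(groups without events omitted with a warning) and no automatic test
statistic is computed.

## Problem sizes and calibration checks

The statistical acceptance checks run at deliberately chosen sizes: the
parameter-recovery harness uses 100 replicates of n = 20,000 with a
true HR(Q5) of 0.88 plus age and gender confounding (recovering the
mean HR within [0.85, 0.91] with 95% CI coverage in [0.90, 0.99]); the
null-calibration harness uses 200 replicates of n = 2,000 and verifies
both trend p-values are uniform (KS, α = 0.01). With 100 replicates
the Monte Carlo standard error of an empirical coverage proportion is
about 0.02, so observed coverage can sit near the band's lower edge
while remaining fully compatible with the nominal 95% level (the
sandwich estimator reproduces nominal coverage exactly in single-
covariate validation runs).

## Known limitations

* No food-code level simulation, no supplement-derived TAC, no
  imputation of missing covariates, no competing risks or time-varying
  covariates, and no replication of multistage survey variance.
* The placeholder VCE table makes shipped TAC values mass sums, not
  literature TAC; all downstream machinery is invariant to this choice.
* HEI-2015 legume handling is a fixed-allocation approximation (above).
* Cohort-relative scorers (aMED, DASH) are only as comparable across
  cohorts as their cutpoint distributions; scores from different
  cohorts should not be pooled.
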