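# dietsurv

Dietary **total antioxidant capacity** (TAC), four **diet-quality index
scorers** (HEI-2015, AHEI-2010, aMED, DASH), and quintile-based
**weighted Cox proportional-hazards** survival analysis for 24-hour
dietary-recall cohorts — with a synthetic cohort generator so the whole
pipeline is testable without restricted survey data.

## Who this is for

Nutritional epidemiologists comparing a single summary exposure —
dietary TAC, in mg vitamin C equivalents (VCE) per day — against a
priori diet-quality indexes as predictors of all-cause mortality. The
package implements the full analytic chain such studies use:

1. **Exposure construction.** TAC is the VCE-weighted sum over
   antioxidant compounds: `TAC = Σᵢ intakeᵢ · VCEᵢ` (mg VCE/day),
   energy-adjusted by the Willett residual method (residual from an OLS
   regression on total energy, plus the predicted value at mean energy).
2. **Index scoring.** HEI-2015 (13 components, per-1000 kcal density
   standards, total 0–100), AHEI-2010 (10 components without trans fat,
   linear 0–10 each, total 0–100), aMED (9 dichotomous median-based
   components with gender-specific alcohol windows, total 0–9), and DASH
   (8 quintile-based components, total 8–40).
3. **Exclusion cascade.** Ordered rules — mortality eligibility, recall
   reliability, implausible energy (<500 or >5000 kcal/day), cancer
   history, pregnancy/breastfeeding, TAC > mean + 3 SD — with an
   auditable participant-flow ledger.
4. **Survival modelling.** Exposure quintiles (Q1 reference) in weighted
   Cox models with cluster-robust variance, three nested covariate
   tiers, two linear-trend constructions (group-median and ordinal), and
   log(−log S) curves for visual proportional-hazards checking.

The fitting surface follows the statsmodels convention: build a
`CoxQuintileModel` from a DataFrame, call `.fit()`, get a
`CoxQuintileResults` with estimates, robust CIs, trend tests and a
`summary()` table.

## Worked example

```python
import numpy as np
import dietsurv as ds

# a synthetic cohort of 5,000 adults with energy-correlated intakes
df = ds.generate_cohort(ds.CohortConfig(n_participants=5000, seed=20))

# TAC, exclusions, energy adjustment, quintiles
df = ds.add_tac(df)                       # placeholder VCE table: all 1.0
df, ledger = ds.apply_exclusions(df)
print(ledger.summary())
df["tac_energy_adjusted"] = ds.energy_adjust(df["tac_raw"], df["energy"])
df["tac_group"] = ds.assign_quintiles(df["tac_energy_adjusted"]).groups

# simulate follow-up with a protective top quintile (HR 0.88)
sim = ds.SurvivalSimConfig(quintile_log_hr=(0, 0, 0, 0, np.log(0.88)), seed=21)
df = ds.simulate_survival(df, sim, quintile_col="tac_group")

res = ds.CoxQuintileModel(df, "tac_group", tier=1,
                          exposure_values="tac_energy_adjusted").fit()
print(res.summary())
```

Output (abridged):

```
initial cohort: n = 5000
  - ineligible_mortality: excluded 5, remaining 4995
  - unreliable_recall: excluded 667, remaining 4328
  - implausible_energy: excluded 0, remaining 4328
  - cancer_history: excluded 246, remaining 4082
  - pregnant_or_breastfeeding: excluded 60, remaining 4022
  - tac_outlier: excluded 44, remaining 3978
final analytic sample: n = 3978 (sequential accounting)

Cox PH model: exposure='tac_group' tier=1 (weights=on, cluster=none)
  Q1 (median 127.2, range -184.5-185.0): deaths/n = 218/796, person-years = 10,101.9, HR = 1.00 (reference)
  Q2 (median 229.3, range 185.2-274.2): deaths/n = 250/796, person-years = 9,869.0, HR = 1.14 (0.93-1.38)
  Q3 (median 315.0, range 274.3-363.7): deaths/n = 249/795, person-years = 9,949.2, HR = 1.08 (0.88-1.32)
  Q4 (median 433.8, range 363.9-544.3): deaths/n = 208/796, person-years = 10,176.4, HR = 0.89 (0.72-1.09)
  Q5 (median 758.7, range 544.4-2387.8): deaths/n = 181/795, person-years = 10,415.3, HR = 0.75 (0.61-0.93)
  p for trend (group medians): 0.0001
  p for trend (ordinal groups): 0.0003
```

(The simulation planted a true HR of 0.88 in the top fifth only; the
fitted Q5 estimate of 0.75 with CI 0.61–0.93 recovers it within
sampling error at this cohort size. Negative adjusted-TAC values in Q1
are a known artefact of the untransformed residual method on skewed
intakes — see the methods note.)

Each quintile row gives the group's exposure median and range, its death
count, person-years, and the hazard ratio relative to the first fifth;
the two trend p-values test a linear dose–response on the group-median
exposure scale and on the ordinal group scale respectively — they can
disagree when the exposure is heavily right-skewed, which is exactly why
both are reported.

The same pipeline is scriptable from the shell:

```bash
dietsurv simulate --n 5000 --seed 20 --out cohort.csv
dietsurv score-tac --cohort cohort.csv --out scored.csv
dietsurv filter --cohort scored.csv --out analytic.csv --ledger ledger.csv
dietsurv all --config run.yaml     # full generate→score→filter→fit→report
```

**Note on VCE coefficients:** the shipped table
(`src/dietsurv/data/vce_default.csv`) is a placeholder with every
coefficient at 1.0 (TAC then equals total antioxidant mass). Supply
ABTS-assay literature values via `VCETable.from_csv` for substantive
work.

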