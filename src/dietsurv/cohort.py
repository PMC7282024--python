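"""Synthetic 24h-recall cohort generator.

Generates cohorts with the joint structure the downstream analysis
assumes: right-skewed (log-normal) food-group, nutrient and antioxidant
intakes that share a latent "energy scale" with total energy intake; a
US-adult covariate mix (age 30+, gender, race/ethnicity, income band,
smoking, physical activity, BMI, disease histories); eligibility flags
at the study's observed exclusion rates; and, separately, exponential
survival times under a proportional-hazards model with quintile-specific
log-hazards and administrative censoring.

The energy correlation is controlled exactly: for a log-normal intake
``exp(sigma*W)`` and standardized energy ``Z``, the latent normal
correlation is inflated to ``r = rho*sqrt(exp(sigma^2)-1)/sigma`` so the
*Pearson* correlation of the intake with energy comes out at the
configured ``rho``.

All randomness flows from a single integer seed; identical configs give
identical tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "IntakeDist",
    "CohortConfig",
    "SurvivalSimConfig",
    "generate_cohort",
    "simulate_survival",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntakeDist:
    """Log-normal intake: ``median`` (natural units/day), log-scale
    ``sigma``, target Pearson correlation with energy ``energy_rho``,
    and an optional point mass at zero (non-consumers)."""

    median: float
    sigma: float = 0.5
    energy_rho: float = 0.0
    zero_prob: float = 0.0


# Default intake levels emulate typical US-adult 24h-recall means
# (cup/oz equivalents per day, nutrients in their native units).
FOODGROUP_DEFAULTS: dict[str, IntakeDist] = {
    "fg_whole_fruits": IntakeDist(0.6, 0.9, 0.15),
    "fg_fruit_juice": IntakeDist(0.25, 1.0, 0.15),
    "fg_veg_except_potatoes": IntakeDist(1.3, 0.7, 0.30),
    "fg_potatoes": IntakeDist(0.4, 0.7, 0.25),
    "fg_dark_green_veg": IntakeDist(0.08, 1.0, 0.10),
    "fg_legumes": IntakeDist(0.10, 1.0, 0.15),
    "fg_whole_grains": IntakeDist(0.55, 0.9, 0.20),
    "fg_refined_grains": IntakeDist(5.0, 0.5, 0.50),
    "fg_dairy": IntakeDist(1.0, 0.7, 0.35),
    "fg_lowfat_dairy": IntakeDist(0.4, 0.9, 0.20),
    "fg_total_protein": IntakeDist(5.8, 0.5, 0.55),
    "fg_seafood": IntakeDist(0.5, 1.0, 0.15),
    "fg_red_processed_meat": IntakeDist(2.1, 0.7, 0.45),
    "fg_nuts_seeds": IntakeDist(0.25, 1.1, 0.20),
    "nut_sodium_mg": IntakeDist(3050.0, 0.35, 0.75),
    "nut_added_sugars_tsp": IntakeDist(13.5, 0.65, 0.55),
    "nut_sfa_pct": IntakeDist(10.2, 0.30, 0.0),
    "nut_mufa_pct": IntakeDist(11.8, 0.25, 0.0),
    "nut_pufa_pct": IntakeDist(6.7, 0.30, 0.0),
    "nut_epa_dha_mg": IntakeDist(60.0, 1.1, 0.10),
    "nut_ssb_g": IntakeDist(150.0, 1.0, 0.40, zero_prob=0.35),
    "nut_alcohol_g": IntakeDist(8.0, 1.2, 0.10, zero_prob=0.60),
}

# Antioxidant compound intakes (mg/day); flavonoids dominate and are the
# most heavily skewed, which makes the summed TAC right-skewed.
COMPOUND_DEFAULTS: dict[str, IntakeDist] = {
    "vitamin_c": IntakeDist(70.0, 0.8, 0.30),
    "vitamin_e": IntakeDist(7.0, 0.6, 0.50),
    "carotenoids": IntakeDist(6.0, 1.0, 0.20),
    "flavonoids": IntakeDist(120.0, 1.3, 0.15),
    "isoflavones": IntakeDist(0.6, 1.5, 0.10),
    "proanthocyanidins": IntakeDist(35.0, 1.0, 0.20),
}

COVARIATE_DEFAULTS: dict[str, dict[str, float]] = {
    "gender": {"man": 0.47, "woman": 0.53},
    "race_ethnicity": {"white": 0.755, "black": 0.115, "hispanic": 0.09, "other": 0.04},
    "pir_band": {"<1.3": 0.17, "1.3-<1.85": 0.095, ">=1.85": 0.735},
    "marital": {"married": 0.69, "unmarried": 0.31},
    "physical_activity": {"sufficient": 0.46, "insufficient": 0.54},
    "smoking": {"never_former_ge3y": 0.71, "former_lt3y": 0.04, "current": 0.25},
}

HISTORY_DEFAULTS = {
    "history_cvd": 0.085,
    "history_diabetes": 0.09,
    "history_hypertension": 0.31,
}

# Eligibility-flag rates scaled from the study's printed exclusion counts.
FLAG_DEFAULTS = {
    "flag_ineligible_mortality": 35 / 31487,
    "flag_unreliable_recall": 4399 / 31487,
    "flag_cancer_history": 1680 / 31487,
    "flag_pregnant_bf": 483 / 31487,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_participants: int
    seed: int = 0
    energy_mean_kcal: float = 2030.0
    energy_sd_kcal: float = 650.0
    energy_bounds: tuple[float, float] = (600.0, 6500.0)
    compound_params: dict[str, IntakeDist] = field(
        default_factory=lambda: dict(COMPOUND_DEFAULTS))
    foodgroup_params: dict[str, IntakeDist] = field(
        default_factory=lambda: dict(FOODGROUP_DEFAULTS))
    covariate_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in COVARIATE_DEFAULTS.items()})
    history_rates: dict[str, float] = field(default_factory=lambda: dict(HISTORY_DEFAULTS))
    flag_rates: dict[str, float] = field(default_factory=lambda: dict(FLAG_DEFAULTS))
    age_mean: float = 49.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (30.0, 90.0)
    bmi_mean: float = 27.9
    bmi_sd: float = 5.8
    bmi_range: tuple[float, float] = (15.0, 60.0)
    weight_sigma: float = 0.35
    n_clusters: int = 60

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError(
                f"n_participants must be >= 1, got {self.n_participants}")
        for fname in ("energy_mean_kcal", "energy_sd_kcal", "age_sd", "bmi_sd"):
            if getattr(self, fname) <= 0:
                raise ConfigurationError(f"{fname} must be > 0")
        for group, params in (("compound_params", self.compound_params),
                              ("foodgroup_params", self.foodgroup_params)):
            for name, dist in params.items():
                if dist.median <= 0 or dist.sigma <= 0:
                    raise ConfigurationError(
                        f"{group}[{name!r}]: median and sigma must be > 0")
                if not -1 <= dist.energy_rho <= 1:
                    raise ConfigurationError(
                        f"{group}[{name!r}]: energy_rho must be in [-1, 1]")
                if not 0 <= dist.zero_prob < 1:
                    raise ConfigurationError(
                        f"{group}[{name!r}]: zero_prob must be in [0, 1)")
        for cov, probs in self.covariate_mix.items():
            total = sum(probs.values())
            if any(p < 0 or p > 1 for p in probs.values()) or abs(total - 1) > 1e-8:
                raise ConfigurationError(
                    f"covariate_mix[{cov!r}]: probabilities must lie in [0,1] "
                    f"and sum to 1 (sum = {total})")
        for name, rate in {**self.history_rates, **self.flag_rates}.items():
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"rate {name!r} must be in [0, 1], got {rate}")
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("compound_params", "foodgroup_params"):
            if key in d:
                d[key] = {k: IntakeDist(**v) if isinstance(v, dict) else v
                          for k, v in d[key].items()}
        for key in ("energy_bounds", "age_range", "bmi_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _truncated_normal(rng, mean, sd, lo, hi, n):
    """Rejection-sample a truncated normal (vectorised redraws)."""
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _lognormal_with_energy_corr(rng, dist: IntakeDist, z_energy: np.ndarray) -> np.ndarray:
    n = len(z_energy)
    sigma = dist.sigma
    # closed-form attenuation correction so Pearson corr(intake, energy) ~ rho
    r = dist.energy_rho * math.sqrt(math.expm1(sigma**2)) / sigma
    r = float(np.clip(r, -0.999, 0.999))
    w = r * z_energy + math.sqrt(1 - r**2) * rng.normal(size=n)
    x = dist.median * np.exp(sigma * w)
    if dist.zero_prob > 0:
        x[rng.random(n) < dist.zero_prob] = 0.0
    return x


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy DataFrame.

    Column families: demographics/covariates, ``fg_*`` food groups
    (cup/oz eq per day), ``nut_*`` nutrients, ``aox_*`` antioxidant
    compounds (mg/day), eligibility ``flag_*`` booleans, survey
    ``weight`` and integer ``cluster``.  Derived totals
    (``fg_total_fruits``, ``fg_total_vegetables``, ``fg_greens_beans``,
    ``nut_alcohol_drinks``) are sums of their parts, so food-group
    accounting is internally consistent.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    log.info("generating cohort: n=%d seed=%d", config.n_participants, config.seed)
    n = config.n_participants
    df = pd.DataFrame({"id": np.arange(1, n + 1)})

    for cov, probs in config.covariate_mix.items():
        cats = list(probs)
        df[cov] = rng.choice(cats, size=n, p=[probs[c] for c in cats])
    df["age"] = _truncated_normal(rng, config.age_mean, config.age_sd,
                                  *config.age_range, n)
    df["bmi"] = _truncated_normal(rng, config.bmi_mean, config.bmi_sd,
                                  *config.bmi_range, n)
    for name, rate in config.history_rates.items():
        df[name] = rng.random(n) < rate

    energy = _truncated_normal(rng, config.energy_mean_kcal, config.energy_sd_kcal,
                               *config.energy_bounds, n)
    df["energy"] = energy
    z_energy = (energy - energy.mean()) / energy.std()

    for col, dist in config.foodgroup_params.items():
        df[col] = _lognormal_with_energy_corr(rng, dist, z_energy)
    for compound, dist in config.compound_params.items():
        df[f"aox_{compound}"] = _lognormal_with_energy_corr(rng, dist, z_energy)

    # derived totals (keep the parts and the sums consistent)
    df["fg_total_fruits"] = df["fg_whole_fruits"] + df["fg_fruit_juice"]
    df["fg_total_vegetables"] = df["fg_veg_except_potatoes"] + df["fg_potatoes"]
    df["fg_greens_beans"] = df["fg_dark_green_veg"] + df["fg_legumes"]
    df["nut_alcohol_drinks"] = df["nut_alcohol_g"] / 14.0

    for name, rate in config.flag_rates.items():
        df[name] = rng.random(n) < rate

    w = rng.lognormal(0.0, config.weight_sigma, n)
    df["weight"] = w / w.mean()
    df["cluster"] = rng.integers(0, config.n_clusters, n)
    return df


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Proportional-hazards simulation: constant baseline hazard
    (events/person-year), quintile-specific log hazard ratios (first
    entry is the reference and must be 0), optional confounder effects,
    and administrative censoring at ``max_followup_years``.

    ``confounder_log_hr`` keys are either ``"column"`` (numeric, log-HR
    per unit, covariate centred at its cohort mean) or
    ``"column=value"`` (log-HR for membership in that category).
    """

    baseline_hazard: float = 0.023
    max_followup_years: float = 14.9
    quintile_log_hr: tuple[float, float, float, float, float] = (0.0,) * 5
    confounder_log_hr: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0 events/person-year")
        if self.max_followup_years <= 0:
            raise ConfigurationError("max_followup_years must be > 0")
        if len(self.quintile_log_hr) != 5:
            raise ConfigurationError("quintile_log_hr needs exactly 5 values")
        if self.quintile_log_hr[0] != 0.0:
            raise ConfigurationError("quintile_log_hr[0] is the reference and must be 0")


def simulate_survival(
    cohort: pd.DataFrame,
    config: SurvivalSimConfig,
    *,
    quintile_col: str = "quintile",
) -> pd.DataFrame:
    """Draw exponential event times under the configured hazards.

    Each participant's hazard is ``baseline * exp(quintile log-HR +
    confounder terms)``; times beyond the follow-up horizon are censored
    there.  Returns a copy of ``cohort`` with ``person_years`` and
    ``event`` appended.
    """
    config.validate()
    if quintile_col not in cohort.columns:
        raise DataError(f"missing quintile column {quintile_col!r}")
    q = cohort[quintile_col].to_numpy()
    if np.any(pd.isna(q)) or not np.all(np.isin(q, [1, 2, 3, 4, 5])):
        raise DataError(f"{quintile_col!r} must contain labels 1..5 with no gaps")
    rng = np.random.default_rng(config.seed)
    lp = np.asarray(config.quintile_log_hr)[q.astype(int) - 1].astype(float)
    for key, beta in config.confounder_log_hr.items():
        if "=" in key:
            col, value = key.split("=", 1)
            if col not in cohort.columns:
                raise DataError(f"confounder column {col!r} not in cohort")
            lp += beta * (cohort[col].astype(str) == value).to_numpy(dtype=float)
        else:
            if key not in cohort.columns:
                raise DataError(f"confounder column {key!r} not in cohort")
            x = cohort[key].to_numpy(dtype=float)
            lp += beta * (x - x.mean())  # centred: baseline is an average person
    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    out = cohort.copy()
    out["event"] = t_event <= config.max_followup_years
    out["person_years"] = np.minimum(t_event, config.max_followup_years)
    return out
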