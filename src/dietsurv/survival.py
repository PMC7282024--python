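"""Weighted Cox proportional-hazards models over exposure quintiles.

The analysis fits three nested covariate tiers per exposure:

* tier 1 — age (5-year categories), gender, race/ethnicity, BMI
  (continuous), total energy (continuous);
* tier 2 — adds income band (PIR), marital status, physical activity,
  and histories of CVD, diabetes and hypertension;
* tier 3 — adds smoking (3 levels).

Exposure enters as quintile indicators with the first fifth as the
reference, so the headline estimates are per-quintile hazard ratios
with 95% CIs.  Two linear-trend constructions are provided, because
they can disagree when the exposure is heavily skewed: refitting with a
single covariate equal to each participant's *group-median* exposure,
and refitting with the *group index* (1..5) as a continuous covariate.

Survey design is approximated by weighted partial likelihood (Efron
ties, via lifelines) with a cluster-robust Lin-Wei sandwich variance
computed in-package from score residuals; full multistage stratified
variance is out of scope.  The proportional-hazards assumption is
inspected visually via per-group log(-log survival) curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import exceptions as ll_exceptions
from scipy import stats

from .errors import ConvergenceError, DataError, DegeneracyError, FitError

__all__ = [
    "CoxQuintileModel",
    "CoxQuintileResults",
    "fit_cox",
    "trend_median",
    "trend_ordinal",
    "ph_diagnostic",
    "build_tier_design",
    "TIER_COVARIATES",
]

log = logging.getLogger(__name__)

AGE_BINS = list(range(30, 90, 5)) + [np.inf]

TIER_COVARIATES = {
    1: ["age_5y", "gender", "race_ethnicity", "bmi", "energy"],
    2: ["age_5y", "gender", "race_ethnicity", "bmi", "energy",
        "pir_band", "marital", "physical_activity",
        "history_cvd", "history_diabetes", "history_hypertension"],
    3: ["age_5y", "gender", "race_ethnicity", "bmi", "energy",
        "pir_band", "marital", "physical_activity",
        "history_cvd", "history_diabetes", "history_hypertension", "smoking"],
}

_CATEGORICAL = {
    "gender": ["man", "woman"],
    "race_ethnicity": ["white", "black", "hispanic", "other"],
    "pir_band": ["<1.3", "1.3-<1.85", ">=1.85"],
    "marital": ["married", "unmarried"],
    "physical_activity": ["sufficient", "insufficient"],
    "smoking": ["never_former_ge3y", "former_lt3y", "current"],
}
_CONTINUOUS = ("bmi", "energy")
_BOOLEAN = ("history_cvd", "history_diabetes", "history_hypertension")


def build_tier_design(df: pd.DataFrame, tier: int) -> pd.DataFrame:
    """Covariate design matrix for one adjustment tier (dummy-coded,
    first category of each factor as reference)."""
    if tier not in TIER_COVARIATES:
        raise DataError(f"tier must be 1, 2 or 3, got {tier}")
    cols = {}
    for cov in TIER_COVARIATES[tier]:
        if cov == "age_5y":
            cats = pd.cut(df["age"], bins=AGE_BINS, right=False)
            dummies = pd.get_dummies(cats, prefix="age", drop_first=True, dtype=float)
            cols.update({c: dummies[c] for c in dummies.columns})
        elif cov in _CATEGORICAL:
            levels = _CATEGORICAL[cov]
            vals = df[cov].astype(str)
            for level in levels[1:]:
                cols[f"{cov}_{level}"] = (vals == level).astype(float)
        elif cov in _CONTINUOUS:
            cols[cov] = df[cov].astype(float)
        elif cov in _BOOLEAN:
            cols[cov] = df[cov].astype(float)
        else:  # pragma: no cover - guarded by TIER_COVARIATES
            raise DataError(f"unknown covariate {cov!r}")
    design = pd.DataFrame(cols, index=df.index)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        log.info("dropping constant covariate columns: %s", constant)
        design = design.drop(columns=constant)
    return design


# ---------------------------------------------------------------------------
# cluster-robust variance from score residuals


def _score_residuals(T, E, W, X, beta) -> np.ndarray:
    """Per-subject score residuals of the weighted Cox partial likelihood
    (Breslow form; identical to Efron when event times are untied)."""
    order = np.argsort(T, kind="stable")
    Ta, Ea, Wa, Xa = T[order], E[order].astype(float), W[order], X[order]
    n, p = Xa.shape
    risk = Wa * np.exp(Xa @ beta)
    # risk-set sums: every member of a tie block sees the whole block
    first = np.searchsorted(Ta, Ta, side="left")
    last = np.searchsorted(Ta, Ta, side="right") - 1
    rc0 = np.cumsum(risk[::-1])[::-1]
    rc1 = np.cumsum((risk[:, None] * Xa)[::-1], axis=0)[::-1]
    S0 = rc0[first]
    S1 = rc1[first]
    xbar = S1 / S0[:, None]
    # cumulative event-time sums up to and including each subject's time
    a = np.where(Ea > 0, Ea * Wa / S0, 0.0)
    A = np.cumsum(a)[last]
    B = np.cumsum(a[:, None] * xbar, axis=0)[last]
    U = Ea[:, None] * Wa[:, None] * (Xa - xbar) - risk[:, None] * (Xa * A[:, None] - B)
    out = np.empty_like(U)
    out[order] = U
    return out


def _sandwich_cov(T, E, W, X, beta, naive_cov, cluster=None) -> np.ndarray:
    """Lin-Wei robust covariance: ``A^-1 B A^-1`` with ``B`` the outer
    product of (cluster-summed) score residuals and ``A^-1`` the
    model-based covariance."""
    U = _score_residuals(T, E, W, X, beta)
    if cluster is not None:
        codes, _ = pd.factorize(cluster)
        M = np.zeros((codes.max() + 1, U.shape[1]))
        np.add.at(M, codes, U)
        U = M
    B = U.T @ U
    return naive_cov @ B @ naive_cov


# ---------------------------------------------------------------------------
# model / results


class CoxQuintileModel:
    """Weighted Cox PH model of mortality on an exposure's quintiles.

    Parameters
    ----------
    data:
        Cohort table with ``person_years``, ``event``, the exposure group
        column, and the tier's covariates.
    exposure:
        Column of group labels in 1..5 (quintiles or aMED score groups).
    tier:
        Adjustment tier (1, 2 or 3).
    exposure_values:
        Optional column of the underlying continuous exposure; needed for
        the median-of-quintile trend test and for range reporting.
    weight_col / cluster_col:
        Analysis weights (None = unweighted) and optional cluster labels
        for the robust variance.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str,
        *,
        tier: int = 3,
        exposure_values: str | None = None,
        duration_col: str = "person_years",
        event_col: str = "event",
        weight_col: str | None = "weight",
        cluster_col: str | None = None,
    ) -> None:
        for col in (exposure, duration_col, event_col):
            if col not in data.columns:
                raise DataError(f"missing column {col!r}")
        if (data[duration_col] <= 0).any():
            raise DataError("person_years must be > 0 for every participant")
        self.data = data
        self.exposure = exposure
        self.tier = tier
        self.exposure_values = exposure_values
        self.duration_col = duration_col
        self.event_col = event_col
        self.weight_col = weight_col
        self.cluster_col = cluster_col

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, exposure: str, **kwargs) -> "CoxQuintileModel":
        return cls(data, exposure, **kwargs)

    # -- internals ---------------------------------------------------------

    def _exposure_groups(self) -> np.ndarray:
        g = self.data[self.exposure].to_numpy()
        if np.any(pd.isna(g)) or not np.all(np.isin(g, [1, 2, 3, 4, 5])):
            raise DataError(f"{self.exposure!r} must contain group labels in 1..5")
        return g.astype(int)

    def _base_frame(self) -> tuple[pd.DataFrame, np.ndarray]:
        groups = self._exposure_groups()
        events = self.data[self.event_col].astype(bool)
        if events.sum() == 0:
            raise FitError("no events in the cohort")
        groups_with_events = np.unique(groups[events.to_numpy()])
        if len(groups_with_events) < 2:
            raise FitError(
                f"events present in only {len(groups_with_events)} exposure group(s)")
        frame = pd.DataFrame({
            "_T": self.data[self.duration_col].astype(float),
            "_E": events.astype(int),
        }, index=self.data.index)
        frame["_W"] = (self.data[self.weight_col].astype(float)
                       if self.weight_col else 1.0)
        if (frame["_W"] <= 0).any():
            raise DataError("analysis weights must be strictly positive")
        return frame, groups

    def _fit_partial_likelihood(self, frame: pd.DataFrame, design: pd.DataFrame):
        """Point estimates via lifelines; robust covariance in-package."""
        df_fit = pd.concat([frame, design], axis=1)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                # weighted partial likelihood with non-integer weights is
                # intentional; variance is replaced by the sandwich below
                warnings.simplefilter("ignore")
                cph.fit(df_fit, duration_col="_T", event_col="_E",
                        weights_col="_W", robust=False)
        except ll_exceptions.ConvergenceError as err:
            raise ConvergenceError(
                f"Cox partial likelihood failed to converge: {err}") from err
        beta = cph.params_.to_numpy()
        naive_cov = cph.variance_matrix_.to_numpy()
        cluster = (self.data[self.cluster_col].to_numpy()
                   if self.cluster_col else None)
        cov = _sandwich_cov(
            frame["_T"].to_numpy(), frame["_E"].to_numpy(),
            frame["_W"].to_numpy(), design.to_numpy(dtype=float),
            beta, naive_cov, cluster)
        return pd.Series(beta, index=design.columns), cov

    def _group_table(self, groups: np.ndarray) -> pd.DataFrame:
        rows = []
        values = (self.data[self.exposure_values].to_numpy(dtype=float)
                  if self.exposure_values else None)
        for g in sorted(np.unique(groups)):
            mask = groups == g
            row = {
                "group": g,
                "n": int(mask.sum()),
                "deaths": int(self.data.loc[mask, self.event_col].sum()),
                "person_years": float(self.data.loc[mask, self.duration_col].sum()),
            }
            if values is not None:
                sub = values[mask]
                row.update(median=float(np.median(sub)),
                           min=float(sub.min()), max=float(sub.max()))
            rows.append(row)
        return pd.DataFrame(rows)

    # -- public API --------------------------------------------------------

    def fit(self) -> "CoxQuintileResults":
        frame, groups = self._base_frame()
        design = build_tier_design(self.data, self.tier)
        ref = int(groups.min())
        q_cols = []
        for g in sorted(np.unique(groups)):
            if g == ref:
                continue
            col = f"Q{g}"
            design.insert(len(q_cols), col, (groups == g).astype(float))
            q_cols.append(col)
        params, cov = self._fit_partial_likelihood(frame, design)
        return CoxQuintileResults(
            model=self, params=params, cov=cov, quintile_cols=q_cols,
            reference=ref, group_table=self._group_table(groups))

    def fit_trend(self, kind: str) -> tuple[float, float, float]:
        """Refit with a single continuous trend covariate.

        ``kind='median'`` uses each participant's group-median exposure
        value (requires ``exposure_values``); ``kind='ordinal'`` uses the
        group index.  Returns (coef, robust SE, Wald p).
        """
        groups = self._exposure_groups()
        if kind == "ordinal":
            trend = groups.astype(float)
        elif kind == "median":
            if not self.exposure_values:
                raise DataError("median trend requires exposure_values column")
            values = self.data[self.exposure_values].to_numpy(dtype=float)
            medians = {g: float(np.median(values[groups == g]))
                       for g in np.unique(groups)}
            trend = np.array([medians[g] for g in groups])
        else:
            raise DataError(f"trend kind must be 'median' or 'ordinal', got {kind!r}")
        if np.ptp(trend) == 0:
            raise DegeneracyError("trend covariate is constant across groups")
        frame, _ = self._base_frame()
        design = build_tier_design(self.data, self.tier)
        design.insert(0, "trend", trend)
        params, cov = self._fit_partial_likelihood(frame, design)
        i = design.columns.get_loc("trend")
        coef = float(params.iloc[i])
        se = float(np.sqrt(cov[i, i]))
        p = float(2 * stats.norm.sf(abs(coef) / se))
        return coef, se, p


@dataclass
class CoxQuintileResults:
    """Fitted per-quintile hazard ratios with robust inference.

    ``summary()`` prints the familiar report layout: one row per group
    with deaths/n, person-years and HR (95% CI), plus both trend tests.
    """

    model: CoxQuintileModel
    params: pd.Series
    cov: np.ndarray
    quintile_cols: list[str]
    reference: int
    group_table: pd.DataFrame

    def __post_init__(self) -> None:
        self._trend_cache: dict[str, tuple[float, float, float]] = {}

    @property
    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        """HR per group, reference group = 1 exactly."""
        hrs = {f"Q{self.reference}": 1.0}
        for col in self.quintile_cols:
            hrs[col] = float(np.exp(self.params[col]))
        return pd.Series(hrs)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """HR confidence intervals per non-reference group."""
        z = stats.norm.ppf(1 - alpha / 2)
        rows = {}
        se = self.standard_errors
        for col in self.quintile_cols:
            lo = np.exp(self.params[col] - z * se[col])
            hi = np.exp(self.params[col] + z * se[col])
            rows[col] = (lo, hi)
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def _trend(self, kind: str) -> tuple[float, float, float]:
        if kind not in self._trend_cache:
            self._trend_cache[kind] = self.model.fit_trend(kind)
        return self._trend_cache[kind]

    @property
    def trend_p_median(self) -> float:
        return self._trend("median")[2]

    @property
    def trend_p_ordinal(self) -> float:
        return self._trend("ordinal")[2]

    def report(self, trend: bool = True) -> pd.DataFrame:
        """Tidy per-group report mirroring the study's table layout."""
        out = self.group_table.copy()
        hrs = self.hazard_ratios
        ci = self.conf_int()
        out["hr"] = [hrs.get(f"Q{g}", np.nan) for g in out["group"]]
        out["ci_lower"] = [1.0 if g == self.reference else ci.loc[f"Q{g}", "lower"]
                           for g in out["group"]]
        out["ci_upper"] = [1.0 if g == self.reference else ci.loc[f"Q{g}", "upper"]
                           for g in out["group"]]
        out["tier"] = self.model.tier
        if trend:
            out["trend_p_ordinal"] = self.trend_p_ordinal
            if self.model.exposure_values:
                out["trend_p_median"] = self.trend_p_median
        return out

    def summary(self) -> str:
        lines = [
            f"Cox PH model: exposure={self.model.exposure!r} "
            f"tier={self.model.tier} "
            f"(weights={'on' if self.model.weight_col else 'off'}, "
            f"cluster={self.model.cluster_col or 'none'})",
        ]
        ci = self.conf_int()
        for row in self.group_table.itertuples():
            g = row.group
            label = f"Q{g}"
            extra = ""
            if "median" in self.group_table.columns:
                extra = f" (median {row.median:.1f}, range {row.min:.1f}-{row.max:.1f})"
            if g == self.reference:
                hr_txt = "1.00 (reference)"
            else:
                hr = self.hazard_ratios[label]
                lo, hi = ci.loc[label]
                hr_txt = f"{hr:.2f} ({lo:.2f}-{hi:.2f})"
            lines.append(
                f"  {label}{extra}: deaths/n = {row.deaths}/{row.n}, "
                f"person-years = {row.person_years:,.1f}, HR = {hr_txt}")
        if self.model.exposure_values:
            lines.append(f"  p for trend (group medians): {self.trend_p_median:.4f}")
        lines.append(f"  p for trend (ordinal groups): {self.trend_p_ordinal:.4f}")
        return "\n".join(lines)

    def plot_loglog(self, ax=None):
        """Plot per-group log(-log survival) curves (PH diagnostic)."""
        import matplotlib.pyplot as plt

        table = ph_diagnostic(
            self.model.data, self.model.exposure,
            duration_col=self.model.duration_col,
            event_col=self.model.event_col,
            weight_col=self.model.weight_col)
        if ax is None:
            _, ax = plt.subplots()
        for g, sub in table.groupby("group"):
            ax.step(np.log(sub["time"]), sub["loglog_survival"], where="post",
                    label=f"Q{g}")
        ax.set_xlabel("log time")
        ax.set_ylabel("log(-log S(t))")
        ax.legend(title=self.model.exposure)
        return ax


# ---------------------------------------------------------------------------
# functional wrappers


def fit_cox(records: pd.DataFrame, exposure: str, tier: int = 3,
            weights: str | None = "weight", **kwargs) -> CoxQuintileResults:
    """Fit one tier for one exposure; see :class:`CoxQuintileModel`."""
    return CoxQuintileModel(records, exposure, tier=tier,
                            weight_col=weights, **kwargs).fit()


def trend_median(records: pd.DataFrame, exposure: str, exposure_values: str,
                 tier: int = 3, weights: str | None = "weight", **kwargs) -> float:
    """Wald p-value for the median-of-quintile linear trend."""
    model = CoxQuintileModel(records, exposure, tier=tier, weight_col=weights,
                             exposure_values=exposure_values, **kwargs)
    return model.fit_trend("median")[2]


def trend_ordinal(records: pd.DataFrame, exposure: str, tier: int = 3,
                  weights: str | None = "weight", **kwargs) -> float:
    """Wald p-value for the ordinal (group index) linear trend."""
    model = CoxQuintileModel(records, exposure, tier=tier,
                             weight_col=weights, **kwargs)
    return model.fit_trend("ordinal")[2]


def ph_diagnostic(
    records: pd.DataFrame,
    group_col: str,
    *,
    duration_col: str = "person_years",
    event_col: str = "event",
    weight_col: str | None = "weight",
) -> pd.DataFrame:
    """Per-group log(-log survival) curves for visual PH checking.

    Returns a table (group, time, survival, loglog_survival) from
    weighted Kaplan-Meier fits; no automatic verdict is produced.
    Groups without any event are omitted with a warning.
    """
    if len(records) == 0:
        raise DataError("empty cohort")
    tables = []
    for g in sorted(records[group_col].unique()):
        sub = records[records[group_col] == g]
        if sub[event_col].sum() == 0:
            log.warning("group %s has no events; omitted from PH diagnostic", g)
            continue
        km = KaplanMeierFitter()
        with warnings.catch_warnings():
            # non-integer survey weights are intentional here
            warnings.simplefilter("ignore")
            km.fit(sub[duration_col], sub[event_col],
                   weights=sub[weight_col] if weight_col else None)
        sf = km.survival_function_.iloc[:, 0]
        sf = sf[(sf > 0) & (sf < 1)]
        tables.append(pd.DataFrame({
            "group": g,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.to_numpy(),
            "loglog_survival": np.log(-np.log(sf.to_numpy())),
        }))
    if not tables:
        raise FitError("no group has any events")
    return pd.concat(tables, ignore_index=True)
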