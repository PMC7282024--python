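"""Diet-quality index scoring: HEI-2015, AHEI-2010, aMED, DASH.

Two scoring families are implemented.  HEI-2015 and AHEI-2010 are
*normative*: each component is scored linearly between fixed cutoffs
shipped as editable CSV configuration (HEI on a per-1000 kcal density
basis, AHEI on absolute daily amounts).  aMED and DASH are
*cohort-relative*: aMED awards 1 point per component for being on the
healthy side of the cohort median (with a gender-specific alcohol
window), DASH awards 1-5 points per component by cohort quintile
(reversed for moderation components).

Component inputs are resolved from cohort-table columns through a
crosswalk file, because the four indexes group foods differently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import CohortStatisticError, ConfigurationError, DataError
from .pipeline import stable_fifths

__all__ = [
    "IndexResult",
    "density",
    "load_crosswalk",
    "load_hei2015_standards",
    "load_ahei2010_standards",
    "score_hei2015",
    "score_ahei2010",
    "score_amed",
    "score_dash",
]

log = logging.getLogger(__name__)

INDEX_RANGES = {
    "hei2015": (0.0, 100.0),
    "ahei2010": (0.0, 100.0),
    "amed": (0.0, 9.0),
    "dash": (8.0, 40.0),
}


@dataclass
class IndexResult:
    """Scores for one index: per-component points, totals, and the
    cohort-derived cutpoints (medians / quintile boundaries) used, if any."""

    index_name: str
    components: pd.DataFrame  # one column per component, one row per participant
    total: pd.Series
    cutpoints: dict | None = None

    def __post_init__(self) -> None:
        lo, hi = INDEX_RANGES[self.index_name]
        t = self.total.to_numpy()
        if len(t) and (t.min() < lo - 1e-9 or t.max() > hi + 1e-9):
            raise DataError(
                f"{self.index_name} totals outside [{lo}, {hi}]: "
                f"min {t.min()}, max {t.max()}"
            )

    def to_frame(self) -> pd.DataFrame:
        out = self.components.copy()
        out["total"] = self.total
        return out


def density(intake, energy):
    """Intake per 1000 kcal. ``energy`` must be strictly positive."""
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0):
        raise DataError("energy must be > 0 kcal/day for density scoring")
    return np.asarray(intake, dtype=float) * 1000.0 / e


# ---------------------------------------------------------------------------
# configuration loading


def load_crosswalk(path: str | Path | None = None) -> dict:
    """Load the component -> column crosswalk (package default or user file)."""
    if path is None:
        path = files("dietsurv.data") / "crosswalk.yaml"
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_hei2015_standards(path: str | Path | None = None) -> pd.DataFrame:
    if path is None:
        path = files("dietsurv.data") / "hei2015_standards.csv"
    std = pd.read_csv(path, comment="#")
    if len(std) != 13:
        raise ConfigurationError(f"HEI-2015 needs 13 components, got {len(std)}")
    if int(std["max_points"].sum()) != 100:
        raise ConfigurationError("HEI-2015 component points must sum to 100")
    if not std["max_points"].isin([5, 10]).all():
        raise ConfigurationError("HEI-2015 max_points must be 5 or 10")
    if (std["min_standard"] == std["max_standard"]).any():
        raise ConfigurationError("HEI-2015 min and max standards must differ")
    return std


def load_ahei2010_standards(path: str | Path | None = None) -> pd.DataFrame:
    if path is None:
        path = files("dietsurv.data") / "ahei2010_standards.csv"
    std = pd.read_csv(path, comment="#")
    if len(std) != 10:
        raise ConfigurationError(
            f"AHEI-2010 (trans-fat-free variant) needs 10 components, got {len(std)}"
        )
    return std


# ---------------------------------------------------------------------------
# component-input resolution


def _col_spec(entry):
    if isinstance(entry, str):
        return entry, 1.0
    return entry["column"], float(entry.get("scale", 1.0))


def _sum_columns(df: pd.DataFrame, specs, component: str) -> np.ndarray:
    out = np.zeros(len(df))
    for entry in specs:
        col, scale = _col_spec(entry)
        if col not in df.columns:
            raise DataError(f"component {component!r}: missing input column {col!r}")
        out += df[col].to_numpy(dtype=float) * scale
    return out


def resolve_component(df: pd.DataFrame, component: str, spec: Mapping) -> np.ndarray:
    """Compute one component's input values from the cohort table."""
    value = _sum_columns(df, spec["columns"], component)
    basis = spec.get("basis", "raw")
    if basis == "raw":
        return value * float(spec.get("scale", 1.0))
    if basis == "density":
        if "energy" not in df.columns:
            raise DataError(f"component {component!r}: density basis needs 'energy'")
        return density(value, df["energy"]) * float(spec.get("scale", 1.0))
    if basis == "pct_energy":
        if "energy" not in df.columns:
            raise DataError(f"component {component!r}: pct_energy basis needs 'energy'")
        kcal = float(spec["kcal_per_unit"])
        e = df["energy"].to_numpy(dtype=float)
        if np.any(e <= 0):
            raise DataError("energy must be > 0 kcal/day")
        return value * kcal / e * 100.0
    if basis == "ratio":
        denom = _sum_columns(df, spec["denominator"], component)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, value / np.where(denom > 0, denom, 1.0), np.inf)
        # zero numerator and denominator: treat as worst case (ratio 0)
        ratio = np.where((denom <= 0) & (value <= 0), 0.0, ratio)
        return ratio
    raise ConfigurationError(f"unknown component basis {basis!r} for {component!r}")


def _linear_score(x, worst, best, max_points):
    """Linear interpolation between a 0-point level (worst) and a
    full-point level (best); works for either direction."""
    x = np.asarray(x, dtype=float)
    frac = (x - worst) / (best - worst)
    return max_points * np.clip(np.nan_to_num(frac, nan=0.0, posinf=1.0, neginf=0.0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# HEI-2015


def score_hei2015(df: pd.DataFrame, standards: pd.DataFrame | None = None,
                  crosswalk: Mapping | None = None) -> IndexResult:
    """Score the 13-component HEI-2015 (total 0-100).

    Adequacy components earn 0 points at/below ``min_standard`` and full
    points at/above ``max_standard`` of their per-1000 kcal density
    (ratio for fatty acids); moderation components are reversed, with
    full points at/below the best level.
    """
    standards = load_hei2015_standards() if standards is None else standards
    xwalk = (load_crosswalk() if crosswalk is None else crosswalk)["hei2015"]
    comps = {}
    for row in standards.itertuples():
        if row.name not in xwalk:
            raise DataError(f"HEI-2015 component {row.name!r} missing from crosswalk")
        x = resolve_component(df, row.name, xwalk[row.name])
        # min_standard is always the 0-point level and max_standard the
        # full-point level; for moderation components min > max, which
        # reverses the slope automatically.
        comps[row.name] = _linear_score(x, row.min_standard, row.max_standard, row.max_points)
    components = pd.DataFrame(comps, index=df.index)
    return IndexResult("hei2015", components, components.sum(axis=1))


# ---------------------------------------------------------------------------
# AHEI-2010


def _gendered(row, base: str, gender: np.ndarray):
    """Pick a cutoff, preferring gender-specific columns when present."""
    men = getattr(row, f"{base}_men", np.nan)
    women = getattr(row, f"{base}_women", np.nan)
    neutral = getattr(row, base, np.nan)
    out = np.where(gender == "man", men, women).astype(float)
    return np.where(np.isnan(out), neutral, out)


def _score_alcohol_window(x, row, gender):
    """Window scoring: 10 inside the gender's moderate-drinking window,
    2.5 for abstainers rising linearly to the window's lower edge, and
    declining linearly to 0 at the gender's heavy-drinking cutoff."""
    lo = np.where(gender == "man", row.window_low_men, row.window_low_women).astype(float)
    hi = np.where(gender == "man", row.window_high_men, row.window_high_women).astype(float)
    zero = np.where(gender == "man", row.zero_cutoff_men, row.zero_cutoff_women).astype(float)
    a = float(row.abstainer_points)
    x = np.asarray(x, dtype=float)
    below = a + (10.0 - a) * np.divide(x, lo, out=np.zeros_like(x), where=lo > 0)
    above = 10.0 * np.clip((zero - x) / (zero - hi), 0.0, 1.0)
    return np.select(
        [x == 0, x < lo, x <= hi],
        [np.full_like(x, a), below, np.full_like(x, 10.0)],
        default=above,
    )


def score_ahei2010(df: pd.DataFrame, standards: pd.DataFrame | None = None,
                   crosswalk: Mapping | None = None) -> IndexResult:
    """Score the 10-component AHEI-2010 without trans fat (total 0-100).

    Each component is worth 10 points, scored linearly between its
    zero-point and full-point cutoffs (reversed for the moderation
    components: SSBs + fruit juice, red/processed meat, sodium).
    Alcohol uses a gender-specific moderate-drinking window.  Requires a
    ``gender`` column with values ``man``/``woman``.
    """
    standards = load_ahei2010_standards() if standards is None else standards
    xwalk = (load_crosswalk() if crosswalk is None else crosswalk)["ahei2010"]
    if "gender" not in df.columns:
        raise DataError("AHEI-2010 needs a 'gender' column (man/woman)")
    gender = df["gender"].to_numpy()
    comps = {}
    for row in standards.itertuples():
        if row.name not in xwalk:
            raise DataError(f"AHEI-2010 component {row.name!r} missing from crosswalk")
        x = resolve_component(df, row.name, xwalk[row.name])
        if row.direction == "window":
            pts = _score_alcohol_window(x, row, gender)
        else:
            worst = _gendered(row, "zero_cutoff", gender)
            best = _gendered(row, "full_cutoff", gender)
            pts = 10.0 * np.clip((x - worst) / (best - worst), 0.0, 1.0)
        comps[row.name] = pts
    components = pd.DataFrame(comps, index=df.index)
    return IndexResult("ahei2010", components, components.sum(axis=1))


# ---------------------------------------------------------------------------
# aMED


def score_amed(df: pd.DataFrame, crosswalk: Mapping | None = None, *,
               gender_specific_medians: bool = False) -> IndexResult:
    """Score the 9-component alternate Mediterranean Diet index (0-9).

    One point per component for intake strictly greater than the cohort
    median — except red/processed meat (1 point *below* the median) and
    alcohol (1 point inside 10-25 g/day for men, 5-15 g/day for women).
    Medians are cohort-wide by default; ``gender_specific_medians``
    computes them within gender.
    """
    xwalk = (load_crosswalk() if crosswalk is None else crosswalk)["amed"]
    if len(df) < 2:
        raise CohortStatisticError("aMED needs >= 2 participants for cohort medians")
    if "gender" not in df.columns:
        raise DataError("aMED needs a 'gender' column (man/woman)")
    gender = df["gender"].to_numpy()
    comps = {}
    cutpoints: dict[str, float | dict] = {}
    for name, spec in xwalk.items():
        x = resolve_component(df, name, spec)
        direction = spec["direction"]
        if direction == "window":
            lo = np.where(gender == "man", spec["window_men"][0], spec["window_women"][0])
            hi = np.where(gender == "man", spec["window_men"][1], spec["window_women"][1])
            pts = ((x >= lo) & (x <= hi)).astype(float)
            cutpoints[name] = {"men": tuple(spec["window_men"]),
                               "women": tuple(spec["window_women"])}
        else:
            if gender_specific_medians:
                med = np.where(gender == "man",
                               np.median(x[gender == "man"]),
                               np.median(x[gender == "woman"]))
                cutpoints[name] = {
                    "men": float(np.median(x[gender == "man"])),
                    "women": float(np.median(x[gender == "woman"])),
                }
            else:
                med = np.median(x)
                cutpoints[name] = float(med)
            pts = ((x > med) if direction == "above_median" else (x < med)).astype(float)
        comps[name] = pts
    if len(comps) != 9:
        raise ConfigurationError(f"aMED needs exactly 9 components, got {len(comps)}")
    components = pd.DataFrame(comps, index=df.index)
    return IndexResult("amed", components, components.sum(axis=1), cutpoints)


# ---------------------------------------------------------------------------
# DASH


def score_dash(df: pd.DataFrame, crosswalk: Mapping | None = None) -> IndexResult:
    """Score the 8-component DASH adherence index (8-40).

    Adequacy components earn their cohort quintile (1-5, highest intake
    = 5); moderation components (red/processed meat, SSBs, sodium) are
    reversed (lowest intake = 5).  Quintiles are stable-rank fifths, so
    heavily tied serving counts split deterministically.
    """
    xwalk = (load_crosswalk() if crosswalk is None else crosswalk)["dash"]
    if len(df) < 5:
        raise CohortStatisticError("DASH needs >= 5 participants for cohort quintiles")
    comps = {}
    cutpoints = {}
    for name, spec in xwalk.items():
        x = resolve_component(df, name, spec)
        fifths = stable_fifths(x)
        if spec["direction"] == "adequacy":
            pts = fifths.astype(float)
        elif spec["direction"] == "moderation":
            pts = (6 - fifths).astype(float)
        else:
            raise ConfigurationError(f"DASH component {name!r}: bad direction")
        boundaries = [float(x[fifths == g].max()) for g in range(1, 5)]
        cutpoints[name] = boundaries
        comps[name] = pts
    if len(comps) != 8:
        raise ConfigurationError(f"DASH needs exactly 8 components, got {len(comps)}")
    components = pd.DataFrame(comps, index=df.index)
    return IndexResult("dash", components, components.sum(axis=1), cutpoints)
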