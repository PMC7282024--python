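"""Dietary total antioxidant capacity (TAC) in vitamin C equivalents.

TAC summarises the antioxidant power of a day's diet as a single number:
each antioxidant compound's intake (mg/day) is multiplied by its
vitamin-C-equivalent antioxidant capacity (VCE, mg VCE per mg compound,
assayed against the ABTS radical in the source literature) and the
products are summed.  Vitamin C itself has a coefficient of 1 by
definition of the unit.

Because total energy intake drives the absolute amount of everything
eaten, TAC is energy-adjusted by the residual method (Willett): regress
TAC on energy by OLS and replace each value with its residual plus the
predicted TAC at the cohort-mean energy.  The adjusted variable is
uncorrelated with energy and keeps the cohort mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, DataError, DegeneracyError, MappingError

__all__ = ["VCETable", "compute_tac", "add_tac", "energy_adjust"]

log = logging.getLogger(__name__)

#: Column used for raw (energy-unadjusted) TAC throughout the pipeline.
TAC_RAW_COL = "tac_raw"
#: Column used for energy-adjusted TAC.
TAC_ADJ_COL = "tac_energy_adjusted"

#: Prefix of per-compound antioxidant intake columns in cohort tables.
ANTIOXIDANT_PREFIX = "aox_"


@dataclass(frozen=True)
class VCETable:
    """Mapping from antioxidant compound to its VCE coefficient.

    Coefficients are mg vitamin C equivalents per mg of compound and must
    be strictly positive.  ``provenance`` carries a free-text citation per
    entry; the shipped defaults are placeholders (all 1.0) and real
    analyses should load literature values via :meth:`from_csv`.
    """

    coefficients: Mapping[str, float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ConfigurationError("VCE table is empty")
        for name, coef in self.coefficients.items():
            if not np.isfinite(coef) or coef <= 0:
                raise ConfigurationError(
                    f"VCE coefficient for {name!r} must be > 0, got {coef!r}"
                )

    def __getitem__(self, compound: str) -> float:
        return self.coefficients[compound]

    def __contains__(self, compound: str) -> bool:
        return compound in self.coefficients

    @classmethod
    def from_csv(cls, path: str | Path) -> "VCETable":
        """Read a two-column CSV ``compound,vce_mg_per_mg``.

        Lines starting with ``#`` are provenance/comment lines and are
        ignored.  Duplicate compound names are rejected.
        """
        df = pd.read_csv(path, comment="#")
        expected = {"compound", "vce_mg_per_mg"}
        if not expected.issubset(df.columns):
            raise ConfigurationError(
                f"VCE file {path} must have columns {sorted(expected)}, "
                f"got {list(df.columns)}"
            )
        if df["compound"].duplicated().any():
            dupes = df.loc[df["compound"].duplicated(), "compound"].tolist()
            raise ConfigurationError(f"duplicate VCE compounds: {dupes}")
        prov = {}
        if "provenance" in df.columns:
            prov = dict(zip(df["compound"], df["provenance"].fillna("")))
        return cls(dict(zip(df["compound"], df["vce_mg_per_mg"].astype(float))), prov)

    @classmethod
    def default(cls) -> "VCETable":
        """Placeholder table (all coefficients 1.0) shipped with the package."""
        from importlib.resources import files

        return cls.from_csv(files("dietsurv.data") / "vce_default.csv")


def compute_tac(profile: Mapping[str, float], table: VCETable, *, strict: bool = True) -> float:
    """TAC of one antioxidant intake profile, in mg VCE/day.

    ``profile`` maps compound name -> intake (mg/day).  Unknown compounds
    raise :class:`MappingError` under ``strict``; otherwise they are
    skipped with a logged warning.  Negative intakes are rejected.
    """
    missing = [c for c in profile if c not in table]
    if missing and strict:
        raise MappingError(f"compounds absent from VCE table: {sorted(missing)}")
    if missing:
        log.warning("skipping %d compounds absent from VCE table: %s", len(missing), sorted(missing))
    total = 0.0
    for compound, intake in profile.items():
        if intake < 0:
            raise DataError(f"negative intake for {compound!r}: {intake}")
        if compound in table:
            total += intake * table[compound]
    return total


def add_tac(
    df: pd.DataFrame,
    table: VCETable | None = None,
    *,
    prefix: str = ANTIOXIDANT_PREFIX,
    out_col: str = TAC_RAW_COL,
    strict: bool = True,
) -> pd.DataFrame:
    """Vectorised :func:`compute_tac` over a cohort table.

    Every column starting with ``prefix`` is treated as a compound intake
    in mg/day (column name without the prefix is the compound name).
    Returns a copy of ``df`` with ``out_col`` appended.
    """
    if table is None:
        table = VCETable.default()
    compounds = {c[len(prefix):]: c for c in df.columns if c.startswith(prefix)}
    if not compounds:
        raise DataError(f"no antioxidant columns with prefix {prefix!r}")
    missing = [c for c in compounds if c not in table]
    if missing and strict:
        raise MappingError(f"compounds absent from VCE table: {sorted(missing)}")
    if missing:
        log.warning("skipping compounds absent from VCE table: %s", sorted(missing))
    out = df.copy()
    tac = np.zeros(len(df))
    for name, col in compounds.items():
        vals = df[col].to_numpy(dtype=float)
        if (vals < 0).any():
            raise DataError(f"negative intakes in column {col!r}")
        if name in table:
            tac += vals * table[name]
    out[out_col] = tac
    return out


def energy_adjust(
    values,
    energy,
    *,
    log_scale: bool = False,
) -> np.ndarray:
    """Residual-method energy adjustment.

    OLS-regress ``values`` on ``energy``; the adjusted value is the
    residual plus the prediction at the cohort-mean energy, so the result
    is uncorrelated with energy and preserves the mean.  With
    ``log_scale`` the regression runs on log(values) (requires strictly
    positive values) and the adjusted values are exponentiated back.
    """
    y = np.asarray(values, dtype=float)
    e = np.asarray(energy, dtype=float)
    if y.shape != e.shape or y.ndim != 1:
        raise DataError("values and energy must be 1-d arrays of equal length")
    if len(y) < 3:
        raise DataError(f"residual adjustment needs >= 3 participants, got {len(y)}")
    if np.ptp(e) == 0:
        raise DegeneracyError("energy is constant; regression slope undefined")
    if log_scale:
        if (y <= 0).any():
            raise DataError("log-scale adjustment requires strictly positive values")
        y_work = np.log(y)
    else:
        y_work = y
    X = sm.add_constant(e)
    fit = sm.OLS(y_work, X).fit()
    adjusted = fit.resid + fit.predict([1.0, e.mean()])[0]
    if log_scale:
        adjusted = np.exp(adjusted)
    return np.asarray(adjusted)
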