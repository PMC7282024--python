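"""Exclusion cascade, exposure quintiles, and aMED score grouping.

The analytic sample is carved out of the raw cohort by an ordered rule
cascade (mortality eligibility, recall reliability, implausible energy,
cancer history, pregnancy/breastfeeding, TAC outliers); each excluded
participant is charged to the *first* rule it violates, and the ledger
records the running counts so the participant flow is auditable.

Exposures (diet-quality scores, energy-adjusted TAC) are then divided
into fifths of the analytic cohort.  aMED, being a coarse 0-9 integer
score, cannot be cut into equal fifths; it is grouped by score value
(0-1, 2, 3, 4, 5-9) as in the source analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DegeneracyError

__all__ = [
    "ExclusionLedger",
    "QuintileAssignment",
    "apply_exclusions",
    "assign_quintiles",
    "group_amed_scores",
    "stable_fifths",
    "DEFAULT_RULE_ORDER",
]

log = logging.getLogger(__name__)

#: Rule order of the study's exclusion cascade.
DEFAULT_RULE_ORDER = (
    "ineligible_mortality",
    "unreliable_recall",
    "implausible_energy",
    "cancer_history",
    "pregnant_or_breastfeeding",
    "tac_outlier",
)

# kcal/day bounds are exclusive: exactly 500 or 5000 kcal is retained.
ENERGY_LOW, ENERGY_HIGH = 500.0, 5000.0


@dataclass
class ExclusionLedger:
    """Ordered record of (rule, n excluded, n remaining) for one cascade run."""

    initial_n: int
    rows: list[tuple[str, int, int]] = field(default_factory=list)
    accounting: str = "sequential"

    @property
    def final_n(self) -> int:
        return self.rows[-1][2] if self.rows else self.initial_n

    @property
    def total_excluded(self) -> int:
        return sum(r[1] for r in self.rows)

    def append(self, rule: str, n_excluded: int) -> None:
        remaining = (self.rows[-1][2] if self.rows else self.initial_n) - n_excluded
        if remaining < 0:
            raise DataError(f"rule {rule!r} excludes more participants than remain")
        self.rows.append((rule, n_excluded, remaining))

    @classmethod
    def from_counts(cls, initial_n: int, counts, names=DEFAULT_RULE_ORDER) -> "ExclusionLedger":
        """Build a ledger from printed sequential exclusion counts."""
        ledger = cls(initial_n=initial_n)
        for name, n in zip(names, counts):
            ledger.append(name, int(n))
        return ledger

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "n_excluded", "n_remaining"])

    def summary(self) -> str:
        lines = [f"initial cohort: n = {self.initial_n}"]
        for rule, excl, remain in self.rows:
            lines.append(f"  - {rule}: excluded {excl}, remaining {remain}")
        lines.append(f"final analytic sample: n = {self.final_n} ({self.accounting} accounting)")
        return "\n".join(lines)


def _rule_masks(df: pd.DataFrame, tac_column: str):
    """Violation predicates, evaluated lazily (TAC rule depends on survivors)."""
    return {
        "ineligible_mortality": lambda d: d["flag_ineligible_mortality"].astype(bool),
        "unreliable_recall": lambda d: d["flag_unreliable_recall"].astype(bool),
        "implausible_energy": lambda d: (d["energy"] < ENERGY_LOW) | (d["energy"] > ENERGY_HIGH),
        "cancer_history": lambda d: d["flag_cancer_history"].astype(bool),
        "pregnant_or_breastfeeding": lambda d: d["flag_pregnant_bf"].astype(bool),
        "tac_outlier": lambda d: d[tac_column] > d[tac_column].mean() + 3 * d[tac_column].std(),
    }


def apply_exclusions(
    cohort: pd.DataFrame,
    rules=DEFAULT_RULE_ORDER,
    *,
    tac_column: str = "tac_raw",
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Run the exclusion cascade and return (analytic cohort, ledger).

    Rules are applied in order and each participant is removed by the
    first rule it violates, so the counts are sequential.  The TAC
    outlier threshold (mean + 3 SD) is computed on the cohort surviving
    all prior rules; ``tac_column`` selects raw (default) or
    energy-adjusted TAC.
    """
    masks = _rule_masks(cohort, tac_column)
    unknown = [r for r in rules if r not in masks]
    if unknown:
        raise ConfigurationError(
            f"unknown exclusion rules {unknown}; known: {sorted(masks)}"
        )
    current = cohort
    ledger = ExclusionLedger(initial_n=len(cohort))
    for rule in rules:
        violates = masks[rule](current)
        n_excl = int(violates.sum())
        if rule == "tac_outlier" and n_excl:
            thr = current[tac_column].mean() + 3 * current[tac_column].std()
            log.info("TAC outlier threshold (mean + 3 SD): %.2f mg VCE/day", thr)
        current = current.loc[~violates]
        ledger.append(rule, n_excl)
    return current.copy(), ledger


def stable_fifths(values, weights=None) -> np.ndarray:
    """Assign each value to a fifth (1..5) by weighted rank, stable under ties.

    Sorting is stable in input order, so tied values are split across the
    boundary deterministically by position; with unit weights group sizes
    differ by at most one.  With weights, each participant is placed by
    the weight mass strictly below it in sorted order, which reduces
    exactly to the unweighted assignment when all weights are equal.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 5:
        raise DegeneracyError(f"need >= 5 participants for fifths, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise DataError("weights must be strictly positive")
    order = np.argsort(v, kind="stable")
    cum_below = np.concatenate([[0.0], np.cumsum(w[order])[:-1]])
    total = w.sum()
    group_sorted = np.minimum((5 * cum_below / total).astype(int), 4) + 1
    groups = np.empty(n, dtype=int)
    groups[order] = group_sorted
    return groups


@dataclass
class QuintileAssignment:
    """Quintile labels for one exposure plus per-group boundary statistics."""

    exposure_name: str
    groups: np.ndarray
    boundaries: pd.DataFrame  # columns: group, n, min, median, max
    weighted: bool = False

    @property
    def group_medians(self) -> dict[int, float]:
        return dict(zip(self.boundaries["group"], self.boundaries["median"]))


def assign_quintiles(
    values,
    weights=None,
    *,
    exposure_name: str = "exposure",
) -> QuintileAssignment:
    """Divide an exposure into cohort fifths (optionally survey-weighted).

    Group medians are reported for the median-of-quintile trend test.
    Requires at least 5 distinct values; heavily tied data are split
    stably across boundaries (see :func:`stable_fifths`).
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 5:
        raise DegeneracyError(
            f"{exposure_name}: need >= 5 distinct values for quintiles, "
            f"got {len(np.unique(v))}"
        )
    groups = stable_fifths(v, weights)
    rows = []
    for g in range(1, 6):
        sub = v[groups == g]
        if len(sub) == 0:  # possible under extreme weight concentration
            continue
        rows.append((g, len(sub), sub.min(), float(np.median(sub)), sub.max()))
    boundaries = pd.DataFrame(rows, columns=["group", "n", "min", "median", "max"])
    log.info("%s quintile boundaries:\n%s", exposure_name, boundaries.to_string(index=False))
    return QuintileAssignment(exposure_name, groups, boundaries, weighted=weights is not None)


#: aMED score-value groups: (low, high) inclusive per ordinal group 1..5.
AMED_GROUPS = ((0, 1), (2, 2), (3, 3), (4, 4), (5, 9))


def group_amed_scores(scores) -> np.ndarray:
    """Map aMED totals (0-9) onto 5 ordinal groups: 0-1, 2, 3, 4, 5-9.

    Group sizes are unequal by construction; the grouping is by score
    value, not by cohort rank.
    """
    s = np.asarray(scores)
    if not np.issubdtype(s.dtype, np.integer):
        if not np.all(np.equal(np.mod(s, 1), 0)):
            raise DataError("aMED scores must be integers")
        s = s.astype(int)
    if s.size and (s.min() < 0 or s.max() > 9):
        raise DataError(f"aMED scores out of range 0-9: min {s.min()}, max {s.max()}")
    groups = np.zeros(s.shape, dtype=int)
    for g, (lo, hi) in enumerate(AMED_GROUPS, start=1):
        groups[(s >= lo) & (s <= hi)] = g
    return groups
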