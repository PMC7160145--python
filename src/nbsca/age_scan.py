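"""Age-cut-off enrichment scan with Stouffer meta-analysis.

The cohort of children older than 18 months is repeatedly split into a
younger and an older group at yearly cut-offs (default 3..10 years).
At each cut-off the association between group membership and the target
SCA is tested with a two-sided Pearson chi-square test, or a two-sided
Fisher exact test when any expected cell count is below 5.  Per-cohort
p-values are combined across cohorts with Stouffer's method (signed by
the direction of the odds ratio) and Bonferroni-corrected over the
number of cut-offs tested; the scan reports the lowest cut-off whose
corrected p-value is below alpha.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CHI_SQUARE = "chi_square"
FISHER_EXACT = "fisher_exact"

DEFAULT_CUTOFFS = tuple(range(3, 11))
DEFAULT_MIN_AGE_YEARS = 1.5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows (older, younger-or-equal) x columns (SCA, no SCA)."""

    a: int  # older, SCA present
    b: int  # older, SCA absent
    c: int  # younger-or-equal, SCA present
    d: int  # younger-or-equal, SCA absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is empty."""
        return 0 in (
            self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d,
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def expected(self) -> np.ndarray:
        rows = np.array([self.a + self.b, self.c + self.d], dtype=float)
        cols = np.array([self.a + self.c, self.b + self.d], dtype=float)
        return np.outer(rows, cols) / self.total


@dataclass(frozen=True)
class AgeScaCohort:
    """One cohort's per-sample ages (years) and binary target-SCA flags."""

    name: str
    ages: np.ndarray
    sca_flags: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "sca_flags", np.asarray(self.sca_flags, dtype=bool))
        if self.ages.shape != self.sca_flags.shape:
            raise ValueError(f"cohort {self.name}: ages and flags differ in length")


def build_contingency(
    ages: np.ndarray,
    sca_flags: np.ndarray,
    cutoff_years: float,
    min_age_years: float = DEFAULT_MIN_AGE_YEARS,
) -> ContingencyTable2x2:
    """Count (older, younger) x (SCA, no SCA) at a cut-off.

    Samples at or below ``min_age_years`` (18 months by default) are
    excluded before counting; "older" means age strictly greater than
    the cut-off.
    """
    ages = np.asarray(ages, dtype=float)
    flags = np.asarray(sca_flags, dtype=bool)
    eligible = ages > min_age_years
    n_excluded = int((~eligible).sum())
    if n_excluded:
        logger.info("excluded %d samples aged <= %.2f years", n_excluded, min_age_years)
    ages, flags = ages[eligible], flags[eligible]
    older = ages > cutoff_years
    return ContingencyTable2x2(
        a=int((older & flags).sum()),
        b=int((older & ~flags).sum()),
        c=int((~older & flags).sum()),
        d=int((~older & ~flags).sum()),
    )


@dataclass(frozen=True)
class AssociationResult:
    p: float
    method: str  # chi_square / fisher_exact
    direction: int  # +1 enrichment in the older group, -1 depletion, 0 balanced


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: the probability mass of all tables with
    the observed margins whose probability does not exceed the observed
    table's (with a small relative tolerance for ties)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def chi_square_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Pearson chi-square p (1 df, no continuity correction)."""
    return float(stats.chi2_contingency(table.as_array(), correction=False)[1])


def association_test(table: ContingencyTable2x2) -> AssociationResult:
    """Test a 2x2 table; Fisher when any expected count is below 5.

    Degenerate tables (an empty margin) carry no information and return
    p = 1 with direction 0.
    """
    if table.degenerate:
        return AssociationResult(p=1.0, method=FISHER_EXACT, direction=0)
    direction = int(np.sign(table.a * table.d - table.b * table.c))
    if (table.expected() < 5).any():
        return AssociationResult(fisher_exact_two_sided(table), FISHER_EXACT, direction)
    return AssociationResult(chi_square_two_sided(table), CHI_SQUARE, direction)


def stouffer_combine(
    results: Sequence[tuple[float, int]],
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Combine two-sided per-cohort p-values into one two-sided p.

    Each (p, direction) pair becomes a signed z-score
    ``z_i = direction_i * Phi^-1(1 - p_i / 2)``; the combined statistic
    is ``Z = sum(w_i z_i) / sqrt(sum(w_i^2))`` and the combined p-value
    ``2 (1 - Phi(|Z|))``.  Opposite directions cancel.
    """
    if not results:
        raise ValueError("no results to combine")
    p_values = np.array([p for p, _ in results], dtype=float)
    directions = np.array([d for _, d in results], dtype=float)
    if (p_values <= 0).any():
        raise ValueError("p = 0 maps to an infinite z-score")
    if (p_values > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.ones_like(p_values)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p_values.shape or (w <= 0).any():
            raise ValueError("weights must be positive, one per result")
    z = directions * stats.norm.isf(p_values / 2)
    combined_z = float(np.dot(w, z) / np.sqrt(np.dot(w, w)))
    return float(2 * stats.norm.sf(abs(combined_z)))


def bonferroni_correct(p: float, m: int) -> float:
    """Bonferroni family-wise correction: min(1, p * m)."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return min(1.0, p * m)


@dataclass(frozen=True)
class CutoffResult:
    cutoff_years: float
    tables: tuple[ContingencyTable2x2, ...]
    cohort_p: tuple[float, ...]
    methods: tuple[str, ...]
    directions: tuple[int, ...]
    combined_p: float
    corrected_p: float


@dataclass
class ScanResult:
    """Full per-cut-off report of an age-threshold scan."""

    cohort_names: tuple[str, ...]
    results: list[CutoffResult]
    alpha: float
    m: int
    lowest_significant_cutoff: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            row: dict = {"cutoff_years": res.cutoff_years}
            for name, table, p, method in zip(
                self.cohort_names, res.tables, res.cohort_p, res.methods
            ):
                row.update({
                    f"{name}_older_sca": table.a, f"{name}_older_no_sca": table.b,
                    f"{name}_younger_sca": table.c, f"{name}_younger_no_sca": table.d,
                    f"{name}_p": p, f"{name}_test": method,
                })
            row.update({"combined_p": res.combined_p, "corrected_p": res.corrected_p})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "cohorts": list(self.cohort_names),
            "alpha": self.alpha,
            "n_cutoffs_tested": len(self.results),
            "bonferroni_m": self.m,
            "lowest_significant_cutoff": self.lowest_significant_cutoff,
        }

    def write(self, tsv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        with open(json_path, "w") as handle:
            json.dump(self.summary(), handle, indent=2, sort_keys=True)
            handle.write("\n")


def run_age_scan(
    cohorts: Sequence[AgeScaCohort],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    alpha: float = 0.05,
    m: Optional[int] = None,
    min_age_years: float = DEFAULT_MIN_AGE_YEARS,
    weights: Optional[Sequence[float]] = None,
) -> ScanResult:
    """Scan age cut-offs for enrichment of the target SCA.

    ``m`` overrides the Bonferroni correction factor (defaults to the
    number of cut-offs actually tested).
    """
    if not cohorts:
        raise ValueError("at least one cohort is required")
    cutoffs = list(cutoffs)
    if not cutoffs or any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be non-empty and strictly increasing")
    for cohort in cohorts:
        if not (cohort.ages > min_age_years).any():
            raise ValueError(
                f"cohort {cohort.name}: no samples older than {min_age_years} years"
            )
    m_eff = len(cutoffs) if m is None else int(m)

    results: list[CutoffResult] = []
    for cutoff in cutoffs:
        tables = [
            build_contingency(c.ages, c.sca_flags, cutoff, min_age_years)
            for c in cohorts
        ]
        tests = [association_test(t) for t in tables]
        if len(tests) == 1:
            combined = tests[0].p
        else:
            combined = stouffer_combine(
                [(t.p, t.direction) for t in tests], weights=weights
            )
        results.append(CutoffResult(
            cutoff_years=cutoff,
            tables=tuple(tables),
            cohort_p=tuple(t.p for t in tests),
            methods=tuple(t.method for t in tests),
            directions=tuple(t.direction for t in tests),
            combined_p=combined,
            corrected_p=bonferroni_correct(combined, m_eff),
        ))

    lowest = next(
        (r.cutoff_years for r in results if r.corrected_p < alpha), None
    )
    return ScanResult(
        cohort_names=tuple(c.name for c in cohorts),
        results=results,
        alpha=alpha,
        m=m_eff,
        lowest_significant_cutoff=lowest,
    )


__all__ = [
    "AgeScaCohort", "AssociationResult", "CHI_SQUARE", "ContingencyTable2x2",
    "CutoffResult", "DEFAULT_CUTOFFS", "DEFAULT_MIN_AGE_YEARS", "FISHER_EXACT",
    "ScanResult", "association_test", "bonferroni_correct", "build_contingency",
    "chi_square_two_sided", "fisher_exact_two_sided", "run_age_scan",
    "stouffer_combine",
]
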