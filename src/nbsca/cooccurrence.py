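"""Pairwise co-occurrence / mutual-exclusivity analysis of SCAs.

Two aberrations are called mutually exclusive when they co-occur less
often than expected under independence (odds ratio < 1) at a two-sided
Fisher exact significance level, and co-occurring when the odds ratio
exceeds 1 at the same level; otherwise they are reported independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import age_scan
from .core_io import ClinicalRecord

CO_OCCURRING = "co_occurring"
MUTUALLY_EXCLUSIVE = "mutually_exclusive"
INDEPENDENT = "independent"


@dataclass(frozen=True)
class PairwiseResult:
    sca_a: str
    sca_b: str
    table: age_scan.ContingencyTable2x2  # rows: A present/absent; cols: B present/absent
    odds_ratio: Optional[float]  # None when 0/0 (undefined)
    p: float
    relation: str


def pairwise_test(
    matrix: pd.DataFrame, sca_a: str, sca_b: str, alpha: float = 0.05
) -> PairwiseResult:
    """Fisher exact test of co-occurrence between two SCA columns."""
    for column in (sca_a, sca_b):
        if column not in matrix.columns:
            raise KeyError(f"SCA column {column!r} missing from matrix")
    has_a = matrix[sca_a].astype(bool).to_numpy()
    has_b = matrix[sca_b].astype(bool).to_numpy()
    table = age_scan.ContingencyTable2x2(
        a=int((has_a & has_b).sum()),
        b=int((has_a & ~has_b).sum()),
        c=int((~has_a & has_b).sum()),
        d=int((~has_a & ~has_b).sum()),
    )
    ad, bc = table.a * table.d, table.b * table.c
    odds_ratio: Optional[float]
    if ad == 0 and bc == 0:
        odds_ratio = None
    elif bc == 0:
        odds_ratio = math.inf
    else:
        odds_ratio = ad / bc
    p = age_scan.fisher_exact_two_sided(table)
    if odds_ratio is None or odds_ratio == 1 or p >= alpha:
        relation = INDEPENDENT
    elif odds_ratio < 1:
        relation = MUTUALLY_EXCLUSIVE
    else:
        relation = CO_OCCURRING
    return PairwiseResult(sca_a, sca_b, table, odds_ratio, p, relation)


def pairwise_report(
    matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Tabulate pairwise tests; optional Bonferroni over the pairs tested."""
    results = [pairwise_test(matrix, a, b, alpha) for a, b in pairs]
    if bonferroni:
        m = len(results)
        adjusted = []
        for res in results:
            p_corr = age_scan.bonferroni_correct(res.p, m)
            relation = res.relation if p_corr < alpha else INDEPENDENT
            adjusted.append(PairwiseResult(
                res.sca_a, res.sca_b, res.table, res.odds_ratio, p_corr, relation
            ))
        results = adjusted
    return pd.DataFrame([
        {
            "sca_a": r.sca_a, "sca_b": r.sca_b,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "odds_ratio": np.nan if r.odds_ratio is None else r.odds_ratio,
            "p": r.p, "relation": r.relation,
        }
        for r in results
    ])


def stratum_prevalence(
    matrix: pd.DataFrame,
    clinical: Sequence[ClinicalRecord],
    age_cutoff: float,
) -> pd.DataFrame:
    """Per-SCA prevalence in the older (> cutoff) and younger strata.

    Each SCA row carries counts, fractions and the same chi-square /
    Fisher association test the age scan uses.
    """
    ages = {rec.sample_id: rec.age_at_diagnosis for rec in clinical}
    orphans = [s for s in matrix.index if s not in ages]
    if orphans:
        raise ValueError(f"samples missing from clinical table: {orphans[:10]}")
    age_vec = np.array([ages[s] for s in matrix.index])
    older = age_vec > age_cutoff
    n_older, n_younger = int(older.sum()), int((~older).sum())
    if n_older == 0 or n_younger == 0:
        raise ValueError(f"empty age stratum at cutoff {age_cutoff}")
    rows = []
    for sca in matrix.columns:
        flags = matrix[sca].astype(bool).to_numpy()
        table = age_scan.ContingencyTable2x2(
            a=int((older & flags).sum()),
            b=int((older & ~flags).sum()),
            c=int((~older & flags).sum()),
            d=int((~older & ~flags).sum()),
        )
        test = age_scan.association_test(table)
        rows.append({
            "sca": sca,
            "older_n": n_older, "older_count": table.a,
            "older_fraction": table.a / n_older,
            "younger_n": n_younger, "younger_count": table.c,
            "younger_fraction": table.c / n_younger,
            "direction": test.direction, "p": test.p, "test": test.method,
        })
    return pd.DataFrame(rows)


def write_pairwise_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


__all__ = [
    "CO_OCCURRING", "INDEPENDENT", "MUTUALLY_EXCLUSIVE", "PairwiseResult",
    "pairwise_report", "pairwise_test", "stratum_prevalence",
    "write_pairwise_report",
]
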