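"""Independent brute-force / closed-form oracles used by the tests.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates the hypergeometric support directly, the chi-square oracle
applies the Pearson formula, the log-rank and Cox-score oracles loop
over risk sets, and the MDR oracle does a quadratic containment scan.
"""

import numpy as np
from scipy.stats import chi2, hypergeom


def fisher_two_sided_enumeration(a, b, c, d):
    """Sum of probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (rel. tol 1e-7)."""
    row1, col1, total = a + b, a + c, a + b + c + d
    support = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, total, col1, row1)
    p_obs = hypergeom.pmf(a, total, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def pearson_chi2_p(a, b, c, d):
    observed = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
    statistic = ((observed - expected) ** 2 / expected).sum()
    return float(chi2.sf(statistic, 1))


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square via explicit risk-set bookkeeping."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dying = (times == t) & (events == 1)
        d = dying.sum()
        d1 = (dying & (group == 1)).sum()
        observed_minus_expected += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    statistic = observed_minus_expected**2 / variance
    return float(statistic), float(chi2.sf(statistic, 1))


def cox_score_statistic(times, events, x):
    """Cox partial-likelihood score test at beta = 0 (assumes no tied
    event times); for a binary covariate this equals the log-rank
    chi-square."""
    times, events, x = map(np.asarray, (times, events, x))
    score = 0.0
    information = 0.0
    for t in times[events == 1]:
        risk = x[times >= t]
        score += x[(times == t) & (events == 1)][0] - risk.mean()
        information += np.mean(risk**2) - risk.mean() ** 2
    return float(score**2 / information)


def mdr_by_quadratic_scan(footprints):
    """Shortest interval over all samples plus brute-force containment."""
    candidates = [
        (end - start, start, sample, (start, end))
        for sample, intervals in footprints.items()
        for start, end in intervals
    ]
    _, _, sample, (start, end) = min(candidates)
    recurrence = 0
    for intervals in footprints.values():
        if any(s <= start and e >= end for s, e in intervals):
            recurrence += 1
    return (start, end), sample, recurrence
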