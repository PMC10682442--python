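"""Kaplan-Meier estimation and log-rank screening of module mRNAs.

The screen splits each subtype's patients at a gene's mean expression
(strictly greater = high group) and compares the two groups' overall
survival with the standard two-group log-rank test (chi-square with one
degree of freedom, tie-corrected hypergeometric variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClinicalTable, ExpressionDataset, RNAClass
from .netops import ModuleSet

log = logging.getLogger(__name__)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns a frame with one row per distinct event time: ``time``,
    ``at_risk``, ``events``, ``survival`` (S(t) just after that time).
    S(0) = 1 is implicit; censored-only data yields S = 1 throughout.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0 or 1")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n = times.size
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: chi2 = (sum O - sum E)^2 / sum V, p from chi2(1).

    At each distinct event time the observed events in group A are compared
    with the hypergeometric expectation; V uses the tie-corrected variance.
    Groups with no events at all give (0, 1) with a warning.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        log.warning("log-rank: no events in either group")
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & group_a).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        log.warning("log-rank: zero variance (no between-group information)")
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class SurvivalScreenResult:
    gene: str
    subtype: str
    n_high: int
    n_low: int
    chi_square: float
    p: float
    significant: bool
    km_high: pd.DataFrame = field(repr=False, default=None)
    km_low: pd.DataFrame = field(repr=False, default=None)


def screen_module_mrnas(
    modules: ModuleSet,
    dataset: ExpressionDataset,
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> list[SurvivalScreenResult]:
    """Log-rank screen over the union of module mRNAs, split at mean expression.

    Samples with expression strictly greater than the gene's mean form the
    high group.  Genes whose split leaves a group empty (e.g. constant
    genes) are skipped with a warning.
    """
    clin = clinical.for_subtype(dataset.subtype)
    samples = [s for s in dataset.samples if s in clin.index]
    if not samples:
        raise ValueError(f"clinical table covers no samples of {dataset.subtype!r}")
    clin = clin.loc[samples]
    results: list[SurvivalScreenResult] = []
    for gene in sorted(modules.genes_of_class(RNAClass.MRNA)):
        x = dataset.values.loc[gene, samples].to_numpy(dtype=float)
        high = x > x.mean()
        if high.all() or not high.any():
            log.warning("%s/%s: degenerate mean split, gene skipped",
                        dataset.subtype, gene)
            continue
        t = clin["time"].to_numpy(dtype=float)
        e = clin["event"].to_numpy(dtype=int)
        chi2, p = logrank_test(t[high], e[high], t[~high], e[~high])
        results.append(SurvivalScreenResult(
            gene=gene, subtype=dataset.subtype,
            n_high=int(high.sum()), n_low=int((~high).sum()),
            chi_square=chi2, p=p, significant=bool(p < alpha),
            km_high=km_estimate(t[high], e[high]),
            km_low=km_estimate(t[~high], e[~high])))
    return results


def screen_frame(results: list[SurvivalScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.subtype, r.n_high, r.n_low, r.chi_square, r.p, r.significant)
         for r in results],
        columns=["gene", "subtype", "n_high", "n_low", "chi_square", "p", "significant"])
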