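"""Clinical statistics for a circRNA expression marker.

Covers the desk-side statistics of a tumour-marker study: median
dichotomization of expression into high/low groups, r×c contingency tests
of the marker against clinicopathological covariates (Yates-corrected
chi-square for 2×2 tables, uncorrected Pearson chi-square otherwise),
Kaplan–Meier survival curves with log-rank comparison, Pearson
correlation, and the ellipsoid xenograft tumour-volume formula
length × width² / 2.

The chi-square statistic is computed directly from the observed table
(X² = Σ(O−E)²/E with expected counts from the margins; Yates replaces
|O−E| by max(|O−E|−0.5, 0) per cell) so the continuity-correction
behaviour is explicit; survival estimation and the log-rank test are
delegated to lifelines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats


@dataclass
class ContingencyTable:
    """r×c integer counts: rows = covariate levels, columns = marker groups."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() <= 0:
            raise ValueError("grand total must be positive")


@dataclass
class SurvivalCurve:
    times: np.ndarray               # distinct event times, ascending
    survival: np.ndarray            # S(t) at each time, starting below 1.0
    at_risk: np.ndarray             # risk-set size just before each time
    median: float                   # earliest t with S(t) ≤ 0.5; inf if never


def dichotomize_by_median(values, tie_rule: str = "low") -> tuple[np.ndarray, float]:
    """Split expression values at the cohort median into high/low groups.

    With the default ``tie_rule="low"``, values strictly above the median
    are "high" and values equal to it go "low" (so for an odd sample size
    the middle observation is low and the low group is larger). With
    ``tie_rule="high"`` values equal to the median go high instead. Ties at
    the median are the only way an even-sized cohort splits unevenly.
    Returns (labels, median).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to dichotomize")
    if tie_rule not in ("low", "high"):
        raise ValueError(f"tie_rule must be 'low' or 'high', got {tie_rule!r}")
    med = float(np.median(x))
    if tie_rule == "low":
        labels = np.where(x > med, "high", "low")
    else:
        labels = np.where(x >= med, "high", "low")
    if (labels == labels[0]).all():
        import logging
        logging.getLogger(__name__).warning(
            "all values identical: single group after dichotomization")
    return labels, med


def chi_square(table: ContingencyTable | np.ndarray | list,
               correction: str = "yates") -> tuple[float, int, float]:
    """Pearson chi-square test of independence; returns (X², df, p).

    ``correction="yates"`` applies the continuity correction (2×2 tables
    only); ``"none"`` is the plain Pearson statistic for any r×c table.
    A zero row or column margin makes the expected counts degenerate and
    raises, naming the offending margin.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    obs = table.counts
    r, c = obs.shape
    if correction not in ("yates", "none"):
        raise ValueError(f"correction must be 'yates' or 'none', got {correction!r}")
    if correction == "yates" and (r, c) != (2, 2):
        raise ValueError("Yates continuity correction applies to 2×2 tables only")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if (row_sums == 0).any():
        i = int(np.argmax(row_sums == 0))
        label = table.row_labels[i] if table.row_labels else f"row {i}"
        raise ValueError(f"degenerate table: zero margin in {label}")
    if (col_sums == 0).any():
        j = int(np.argmax(col_sums == 0))
        label = table.col_labels[j] if table.col_labels else f"column {j}"
        raise ValueError(f"degenerate table: zero margin in {label}")
    expected = np.outer(row_sums, col_sums) / obs.sum()
    dev = np.abs(obs - expected)
    if correction == "yates":
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def km_estimate(durations, events) -> SurvivalCurve:
    """Product-limit (Kaplan–Meier) survival curve.

    Censored patients leave the risk set after their time. The reported
    median is the earliest time with S(t) ≤ 0.5 (infinity if the curve
    never reaches 0.5).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one patient")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = np.sort(np.unique(t[e == 1]))
    surv = np.array([float(kmf.survival_function_at_times(x).iloc[0])
                     for x in event_times])
    at_risk = np.array([int((t >= x).sum()) for x in event_times])
    median = float(kmf.median_survival_time_)
    return SurvivalCurve(event_times, surv, at_risk, median)


def logrank_test(durations, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    At each distinct event time the observed minus hypergeometric-expected
    events in group 1 accumulate with their variance; the statistic is
    (ΣO−E)²/ΣV on 1 df.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {levels.size}")
    if e.sum() == 0:
        raise ValueError("no events observed: log-rank test undefined")
    mask = g == levels[0]
    res = _lifelines_logrank(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided Student-t p-value on n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n ≥ 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def xenograft_volume(length: float, width: float) -> float:
    """Ellipsoid tumour volume in mm³: length × width² / 2."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive (mm)")
    return length * width ** 2 / 2.0


def crosstab_expression(clinical: pd.DataFrame, covariate: str,
                        expression_col: str = "expression") -> ContingencyTable:
    """Contingency table of a covariate against the median-split marker."""
    labels, _ = dichotomize_by_median(clinical[expression_col].to_numpy())
    ct = pd.crosstab(clinical[covariate], pd.Series(labels, index=clinical.index))
    cols = [c for c in ("high", "low") if c in ct.columns]
    ct = ct[cols]
    return ContingencyTable(ct.to_numpy(), list(map(str, ct.index)), cols)


def clinical_report(clinical: pd.DataFrame,
                    covariates: list[str],
                    expression_col: str = "expression",
                    time_col: str = "survival_months",
                    event_col: str = "event") -> pd.DataFrame:
    """Contingency p-values per covariate plus the high/low log-rank test.

    2×2 tables use the Yates correction; larger tables the uncorrected
    Pearson statistic.
    """
    rows = []
    for cov in covariates:
        table = crosstab_expression(clinical, cov, expression_col)
        correction = "yates" if table.counts.shape == (2, 2) else "none"
        statistic, df, p = chi_square(table, correction)
        rows.append({"test": f"chi_square:{cov}", "statistic": statistic,
                     "df": df, "p_value": p})
    labels, _ = dichotomize_by_median(clinical[expression_col].to_numpy())
    statistic, p = logrank_test(clinical[time_col].to_numpy(),
                                clinical[event_col].to_numpy(), labels)
    rows.append({"test": "logrank:high_vs_low", "statistic": statistic,
                 "df": 1, "p_value": p})
    return pd.DataFrame(rows)
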