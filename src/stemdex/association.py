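"""Clinical association of the stemness index: group tests and survival.

Survival handling follows the usual cohort conventions: records missing time
or status are dropped, as are times under 30 days (early deaths/withdrawals
that mostly reflect perioperative events rather than disease course);
Kaplan-Meier curves use the product-limit estimator and group comparisons a
two-sided log-rank test with chi-square asymptotics. Index-versus-covariate
comparisons are rank-based: Wilcoxon rank-sum for two levels, Kruskal-Wallis
for three or more.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .exceptions import AnalysisError, DataError
from .stemness import split_by_median

log = logging.getLogger(__name__)

MIN_SURVIVAL_DAYS = 30.0


@dataclass
class GroupTestResult:
    covariate: str
    test: str                 # "wilcoxon" or "kruskal"
    statistic: float
    p_value: float
    group_sizes: dict[str, int]


def filter_survival(records: pd.DataFrame, time_col: str, event_col: str,
                    min_days: float = MIN_SURVIVAL_DAYS) -> pd.DataFrame:
    """Drop records with missing time/status or time below ``min_days``.

    Times exactly at the boundary are retained (the exclusion is strictly
    "< min_days"). Counts dropped per rule are logged; an empty result is an
    analysis error.
    """
    n0 = len(records)
    has_both = records[time_col].notna() & records[event_col].notna()
    n_missing = int((~has_both).sum())
    kept = records[has_both]
    early = kept[time_col] < min_days
    n_early = int(early.sum())
    kept = kept[~early]
    log.info("survival filter: dropped %d missing time/status, %d with time < %g days",
             n_missing, n_early, min_days)
    if kept.empty:
        raise AnalysisError("no records remain after survival filtering")
    return kept


def km_estimate(time: pd.Series | np.ndarray, event: pd.Series | np.ndarray) -> pd.DataFrame:
    """Product-limit survival curve as a (time, survival) step function.

    Right-censored observations enter the risk set but contribute no drop.
    The returned frame starts at time 0 with survival 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise AnalysisError("Kaplan-Meier estimate needs >= 1 record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-sided log-rank chi-square test across >= 2 groups.

    Returns (statistic, p) with k-1 degrees of freedom. A group with zero
    events triggers a warning; identical groups give statistic 0 and p 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) < 2:
        raise AnalysisError(f"log-rank test needs >= 2 groups, got {len(labels)}")
    for lab in labels:
        if event[group == lab].sum() == 0:
            warnings.warn(f"log-rank group {lab!r} has zero events")
    res = multivariate_logrank_test(time, group, event)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if np.isclose(stat, 0.0, atol=1e-12):
        stat, p = 0.0, 1.0
    return stat, p


def compare_index_by_covariate(index: pd.Series, clinical: pd.DataFrame,
                               covariate: str) -> GroupTestResult:
    """Rank-test the stemness index across levels of a clinical covariate.

    The index and clinical table are joined on sample id (inner); samples
    with a missing covariate are excluded with a logged count. Two levels use
    the Wilcoxon rank-sum test, three or more Kruskal-Wallis.
    """
    if covariate not in clinical.columns:
        raise AnalysisError(f"covariate {covariate!r} not in clinical table")
    joined = pd.DataFrame({"index": index}).join(clinical[[covariate]], how="inner")
    n_missing = int(joined[covariate].isna().sum())
    if n_missing:
        log.info("compare_index_by_covariate(%s): excluding %d samples with missing value",
                 covariate, n_missing)
    joined = joined.dropna()
    levels = sorted(joined[covariate].unique())
    if len(levels) < 2:
        raise AnalysisError(f"covariate {covariate!r} has {len(levels)} non-empty level(s); need >= 2")
    samples = [joined.loc[joined[covariate] == lev, "index"].to_numpy() for lev in levels]
    if len(levels) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test = "wilcoxon"
    else:
        stat, p = stats.kruskal(*samples)
        test = "kruskal"
    return GroupTestResult(covariate=covariate, test=test, statistic=float(stat),
                           p_value=float(p),
                           group_sizes={str(lev): len(s) for lev, s in zip(levels, samples)})


def gene_survival_split(expr: pd.DataFrame, gene: str, records: pd.DataFrame,
                        time_col: str, event_col: str) -> tuple[pd.Series, tuple[float, float]]:
    """Median-split a gene's expression and log-rank the two halves.

    The tie rule matches the index split (values at the median go high). A
    degenerate split — every sample on one side — is an analysis error, not a
    silent p-value.
    """
    if gene not in expr.index:
        raise DataError(f"gene {gene!r} not present in expression matrix")
    shared = records.index.intersection(expr.columns)
    if len(shared) < len(records):
        log.warning("gene_survival_split: %d survival records lack expression",
                    len(records) - len(shared))
    values = expr.loc[gene, shared]
    labels = split_by_median(values)
    if labels.nunique() < 2:
        raise AnalysisError(f"gene {gene!r}: degenerate median split (all samples on one side)")
    rec = records.loc[shared]
    result = logrank_test(rec[time_col], rec[event_col], labels.loc[shared])
    return labels, result
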