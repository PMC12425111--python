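"""Over-representation analysis of a gene list against GMT gene sets.

The test is the one-sided hypergeometric upper tail: with a universe of N
genes, a set of K, and a query of n, the p-value for an observed overlap k is
P(X >= k) for X ~ Hypergeometric(N, K, n). BH adjustment runs across all
tested sets. Only enrichment (not depletion) is tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .exceptions import AnalysisError
from .io import read_gmt  # re-exported: parsing lives with the other formats

__all__ = ["EnrichmentResult", "ora_test", "read_gmt"]

log = logging.getLogger(__name__)

MIN_SET_SIZE = 3


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    fdr: float
    overlap_genes: list[str]


def ora_test(query: set[str], sets: dict[str, set[str]], universe: set[str]) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test of ``query`` against each set.

    Query genes outside the universe are dropped with a warning; each set is
    intersected with the universe first and skipped if fewer than
    ``MIN_SET_SIZE`` members remain. Results are sorted by p-value; FDR is BH
    across the tested sets.
    """
    outside = set(query) - set(universe)
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
    query = set(query) & set(universe)
    if not query:
        raise AnalysisError("query is empty after restricting to the universe")
    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for name, members in sets.items():
        members = set(members) & set(universe)
        if len(members) < MIN_SET_SIZE:
            log.info("skipping set %r: %d members in universe (< %d)", name, len(members), MIN_SET_SIZE)
            continue
        overlap_genes = sorted(query & members)
        k = len(overlap_genes)
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_query))
        rows.append(EnrichmentResult(
            set_name=name, overlap=k, set_size=len(members), query_size=n_query,
            universe_size=n_univ, p_value=min(p, 1.0), fdr=float("nan"),
            overlap_genes=overlap_genes))
    if not rows:
        raise AnalysisError("no gene set has enough members in the universe to test")
    fdrs = bh_adjust([r.p_value for r in rows])
    for r, f in zip(rows, fdrs):
        r.fdr = float(f)
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_name": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
        "query_size": r.query_size, "universe_size": r.universe_size,
        "p_value": r.p_value, "fdr": r.fdr,
        "overlap_genes": ",".join(r.overlap_genes),
    } for r in results])
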