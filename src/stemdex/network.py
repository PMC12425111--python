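"""Interaction network construction and Maximal Clique Centrality hub ranking.

Edges come from a STRING-style table with a combined confidence score; only
edges with score strictly above the cutoff (default 0.4) are retained. Hub
genes are ranked by Maximal Clique Centrality,

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!,

with the convention that an isolated node (whose only maximal clique is the
singleton {v}) scores (1-1)! = 1. Ties are broken by degree, then gene id.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, DataError

log = logging.getLogger(__name__)

SCORE_CUTOFF = 0.4
DEFAULT_NODE_LIMIT = 20000


def read_string_edges(edges: pd.DataFrame | str, cutoff: float = SCORE_CUTOFF,
                      nodes: set[str] | None = None) -> nx.Graph:
    """Build the interaction graph from a STRING-style edge table or TSV path.

    Scores on the 0-1000 integer convention are auto-detected (any score > 1)
    and divided by 1000. The filter is strict: an edge scoring exactly the
    cutoff is dropped. Duplicate pairs (either orientation) keep the maximum
    score; self-loops are dropped. With ``nodes`` given, the graph is
    restricted to those genes (e.g. the DEG list) and genes absent from the
    edge table are reported as unmapped.
    """
    if not isinstance(edges, pd.DataFrame):
        from .io import read_edges
        edges = read_edges(edges)
    missing = {"node1", "node2", "combined_score"} - set(edges.columns)
    if missing:
        raise DataError(f"edge table lacks columns: {sorted(missing)}")
    score = edges["combined_score"].to_numpy(dtype=float)
    if (score > 1).any():
        score = score / 1000.0
    g = nx.Graph()
    for a, b, s in zip(edges["node1"], edges["node2"], score):
        if a == b:
            continue
        if nodes is not None and (a not in nodes or b not in nodes):
            continue
        if s > cutoff:
            prev = g.edges.get((a, b), {}).get("combined_score", -np.inf)
            if s > prev:
                g.add_edge(a, b, combined_score=float(s))
    if nodes is not None:
        unmapped = set(nodes) - set(g.nodes)
        if unmapped:
            log.info("%d of %d requested genes have no retained interaction", len(unmapped), len(nodes))
        g.graph["unmapped"] = sorted(unmapped)
    return g


def maximal_cliques(graph: nx.Graph, node_limit: int = DEFAULT_NODE_LIMIT) -> list[frozenset]:
    """All maximal cliques (Bron-Kerbosch with pivoting), each reported once.

    Enumeration is worst-case exponential, so graphs above ``node_limit``
    nodes are refused with guidance rather than silently hanging.
    """
    if graph.number_of_nodes() > node_limit:
        raise AnalysisError(
            f"graph has {graph.number_of_nodes()} nodes (> limit {node_limit}); "
            "raise node_limit explicitly or pre-filter the edge list")
    return [frozenset(c) for c in nx.find_cliques(graph)]


def mcc_scores(graph: nx.Graph, node_limit: int = DEFAULT_NODE_LIMIT) -> dict[str, float]:
    """Maximal Clique Centrality per node; isolated nodes score 1."""
    scores = {v: 0.0 for v in graph.nodes}
    for clique in maximal_cliques(graph, node_limit=node_limit):
        contrib = float(math.factorial(len(clique) - 1))
        for v in clique:
            scores[v] += contrib
    return scores


def mcc_rank(graph: nx.Graph, top: int = 10, method: str = "mcc",
             node_limit: int = DEFAULT_NODE_LIMIT) -> pd.DataFrame:
    """Hub ranking table: gene, score, degree, rank, hub flag.

    ``method="mcc"`` ranks by Maximal Clique Centrality, ``method="degree"``
    by degree. Sorting is score descending with ties broken by degree
    (descending) then gene id; the top ``top`` genes are flagged as hubs.
    """
    if graph.number_of_nodes() == 0:
        raise AnalysisError("cannot rank hubs on an empty graph")
    if method == "mcc":
        scores = mcc_scores(graph, node_limit=node_limit)
    elif method == "degree":
        scores = {v: float(d) for v, d in graph.degree()}
    else:
        raise AnalysisError(f"unknown ranking method {method!r}; use 'mcc' or 'degree'")
    rows = sorted(
        ((g, s, graph.degree(g)) for g, s in scores.items()),
        key=lambda t: (-t[1], -t[2], t[0]))
    df = pd.DataFrame(rows, columns=["gene_id", "mcc_score", "degree"])
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_hub"] = df["rank"] <= top
    return df.set_index("gene_id")


def correlate_with_index(expr: pd.DataFrame, genes: list[str], mrnasi: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with the stemness index.

    Two-sided t-based p-values; a zero-variance gene gets r = NaN with a
    logged warning. Requires >= 3 shared samples.
    """
    absent = [g for g in genes if g not in expr.index]
    if absent:
        raise DataError(f"genes not in expression matrix: {absent[:5]}")
    shared = mrnasi.index.intersection(expr.columns)
    if len(shared) < 3:
        raise DataError(f"need >= 3 shared samples, got {len(shared)}")
    y = mrnasi.loc[shared].to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = expr.loc[g, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            log.warning("gene %s (or the index) has zero variance; r = NaN", g)
            rows.append((g, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((g, float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene_id", "pearson_r", "p_value"]).set_index("gene_id")
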