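"""Independent reference implementations used only as test oracles.

Everything here is deliberately brute-force and independent of the package's
own code paths: subset enumeration for cliques, exact rational arithmetic for
the hypergeometric tail, the textbook step-up definition for BH, and a
derivative-free multi-start optimizer for the one-class objective.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy import optimize


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the definition: min over j >= rank of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        out[idx] = min(1.0, min(candidates))
    return out


def hypergeom_upper_tail_exact(k: int, universe: int, set_size: int, query: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(universe, set_size, query), exact rationals."""
    total = comb(universe, query)
    acc = Fraction(0)
    for j in range(k, min(set_size, query) + 1):
        acc += Fraction(comb(set_size, j) * comb(universe - set_size, query - j), total)
    return acc


def cliques_bruteforce(nodes: list, edges: set[frozenset]) -> set[frozenset]:
    """All maximal cliques by exhaustive subset enumeration (graphs <= ~10 nodes)."""

    def is_clique(sub):
        return all(frozenset(pair) in edges for pair in itertools.combinations(sub, 2))

    cliques = [frozenset(sub) for r in range(1, len(nodes) + 1)
               for sub in itertools.combinations(nodes, r) if is_clique(sub)]
    return {c for c in cliques if not any(c < other for other in cliques)}


def mcc_from_cliques(node, cliques: set[frozenset]) -> float:
    import math
    return float(sum(math.factorial(len(c) - 1) for c in cliques if node in c))


def oclr_objective_ref(w: np.ndarray, x_centered: np.ndarray, lam: float) -> float:
    """Independent restatement: (1/n) sum[s - log(1+e^s)] - lam/2 ||w||^2."""
    s = x_centered.T @ w
    return float(np.mean(s - np.log1p(np.exp(s))) - 0.5 * lam * np.dot(w, w))


def oclr_optimize_ref(x_centered: np.ndarray, lam: float, n_starts: int = 8,
                      seed: int = 0) -> float:
    """Best objective found by multi-start Nelder-Mead (derivative-free)."""
    rng = np.random.default_rng(seed)
    g = x_centered.shape[0]
    best = -np.inf
    starts = [np.zeros(g)] + [rng.normal(0, 1, g) for _ in range(n_starts - 1)]
    for w0 in starts:
        res = optimize.minimize(lambda w: -oclr_objective_ref(w, x_centered, lam), w0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = max(best, -res.fun)
    return best


def km_no_censoring(times: np.ndarray, t: float) -> float:
    """Survivor function with no censoring: 1 - empirical CDF at t."""
    times = np.asarray(times, dtype=float)
    return float(np.mean(times > t))
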