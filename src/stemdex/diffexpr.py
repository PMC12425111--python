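"""Differential expression between stemness-index strata.

Two routes are provided, matching the two data layers a cohort typically has:

* ``nb_wald_test`` — sequencing counts: a per-gene negative binomial GLM with
  log link, log-size-factor offsets (median-of-ratios normalization), a
  method-of-moments dispersion estimate, and a Wald test on the group
  coefficient. This is a deliberately simple, fully specified NB pipeline —
  no dispersion shrinkage and no fold-change shrinkage.
* ``moderated_t_test`` — log-intensity data: empirical-Bayes moderated t with
  the prior degrees of freedom and prior variance estimated by moment
  matching on the log sample variances.

The sign convention throughout: positive log2 fold change means higher
expression in the low-stemness ("L") group relative to the high ("H") group.
Significance uses strict thresholds: FDR < 0.05 and |log2FC| > 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import AnalysisError, DataError

log = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Each sample's factor is the median, over genes with all-positive counts,
    of that sample's count divided by the gene's geometric mean across
    samples.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise DataError("counts must be nonnegative")
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise DataError("no gene has all-positive counts; consider adding a pseudocount")
    logs = np.log(x[all_pos])
    log_geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _normalize_groups(groups: pd.Series | np.ndarray, columns: pd.Index) -> np.ndarray:
    if isinstance(groups, pd.Series):
        groups = groups.reindex(columns).to_numpy()
    groups = np.asarray(groups)
    labels = set(pd.unique(groups))
    if labels != {"H", "L"}:
        raise AnalysisError(f"groups must contain exactly the labels 'H' and 'L', got {sorted(map(str, labels))}")
    for lab in ("H", "L"):
        if (groups == lab).sum() < 2:
            raise AnalysisError(f"group {lab!r} has fewer than 2 samples")
    return groups


def estimate_dispersion(counts: pd.DataFrame, groups, sf: pd.Series | None = None,
                        floor: float = DISPERSION_FLOOR) -> pd.Series:
    """Per-gene NB dispersion alpha (var = mu + alpha * mu^2) by method of moments.

    Within each group, on size-factor-normalized counts z = y / s:
    alpha = (var(z) - mean(z) * mean(1/s)) / mean(z)^2; group estimates are
    pooled by their degrees of freedom and floored at ``floor``.
    """
    groups = _normalize_groups(groups, counts.columns)
    if sf is None:
        sf = size_factors(counts)
    y = counts.to_numpy(dtype=float)
    s = sf.to_numpy()
    z = y / s
    num = np.zeros(y.shape[0])
    den = 0.0
    for lab in ("H", "L"):
        sel = groups == lab
        n_g = int(sel.sum())
        m = z[:, sel].mean(axis=1)
        v = z[:, sel].var(axis=1, ddof=1)
        xi = np.mean(1.0 / s[sel])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m * xi) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += (n_g - 1) * a
        den += n_g - 1
    alpha = np.maximum(num / den, floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             max_iter: int = 50, tol: float = 1e-8):
    """Vectorized IRLS for per-gene NB GLMs with design [1, group].

    ``y`` is genes x samples, ``x`` the 0/1 group indicator (1 = L),
    ``offset`` the per-sample log size factor, ``alpha`` the per-gene
    dispersion. Returns (beta0, beta1, se1).
    """
    eps = 0.5
    s = np.exp(offset)
    z0 = (y / s)[:, x == 0].mean(axis=1)
    z1 = (y / s)[:, x == 1].mean(axis=1)
    b0 = np.log(np.maximum(z0, eps / len(offset)))
    b1 = np.log(np.maximum(z1, eps / len(offset))) - b0
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = np.clip(offset[None, :] + b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        zwork = (eta - offset[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)          # x is 0/1 so x^2 = x
        swz = (w * zwork).sum(axis=1)
        swxz = (w * x * zwork).sum(axis=1)
        det = sw * swx - swx**2
        det = np.where(det <= 0, np.nan, det)
        new_b0 = (swx * swz - swx * swxz) / det
        new_b1 = (sw * swxz - swx * swz) / det
        step = np.nanmax(np.abs(new_b0 - b0)) if len(b0) else 0.0
        step = max(step, np.nanmax(np.abs(new_b1 - b1)) if len(b1) else 0.0)
        b0 = np.where(np.isnan(new_b0), b0, new_b0)
        b1 = np.where(np.isnan(new_b1), b1, new_b1)
        if step < tol:
            break
    eta = np.clip(offset[None, :] + b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(sw / det)
    return b0, b1, se1


def nb_wald_test(counts: pd.DataFrame, groups, min_total_count: int | None = 10,
                 dispersion: pd.Series | None = None) -> pd.DataFrame:
    """NB GLM Wald test per gene between the H and L strata.

    Genes with total count below ``min_total_count`` are pre-filtered (pass
    ``None`` to disable); all-zero genes get NA p-values and are excluded
    from the FDR computation. Positive log2fc = higher in L.
    """
    groups = _normalize_groups(groups, counts.columns)
    counts = counts.copy()
    if min_total_count is not None:
        keep = counts.sum(axis=1) >= min_total_count
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("pre-filtering %d genes with total count < %d", n_drop, min_total_count)
        counts = counts[keep]
    if counts.empty:
        raise AnalysisError("no genes remain after count pre-filtering")
    sf = size_factors(counts)
    y = counts.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    if dispersion is None:
        dispersion = estimate_dispersion(counts, groups, sf)
    alpha = dispersion.reindex(counts.index).to_numpy()

    x = (groups == "L").astype(float)
    offset = np.log(sf.to_numpy())
    b0 = np.full(len(counts), np.nan)
    b1 = np.full(len(counts), np.nan)
    se1 = np.full(len(counts), np.nan)
    b0[nonzero], b1[nonzero], se1[nonzero] = _nb_irls(
        y[nonzero], x, offset, alpha[nonzero])

    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = b1 / se1
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    p[~nonzero] = np.nan
    n_allzero = int((~nonzero).sum())
    if n_allzero:
        log.info("%d all-zero genes excluded from testing (p = NA)", n_allzero)
    table = pd.DataFrame({
        "log2fc": b1 / np.log(2.0),
        "p_value": p,
        "mean_expression": (y / sf.to_numpy()).mean(axis=1),
    }, index=counts.index.rename("gene_id"))
    table["fdr"] = bh_adjust(table["p_value"])
    return classify_degs(table)


def _inverse_trigamma(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x -= delta
        if abs(delta) < 1e-10 * x:
            break
    return float(x)


def _fit_log_var_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled inverse chi-square variance prior.

    Uses the log sample variances: under the hierarchical model
    E[log s^2] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2) and
    Var[log s^2] = psi'(d/2) + psi'(d0/2).
    """
    e = np.log(np.maximum(s2, 1e-300))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, d / 2.0))
    if excess <= 1e-8:
        return np.inf, float(np.exp(np.mean(e) - special.digamma(d / 2.0) + np.log(d / 2.0)))
    d0 = 2.0 * _inverse_trigamma(excess)
    log_s0 = (np.mean(e) - special.digamma(d / 2.0) + np.log(d / 2.0)
              + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return d0, float(np.exp(log_s0))


def moderated_t_test(logexpr: pd.DataFrame, groups, moderate: bool = True) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t test per gene on log expression.

    Pooled per-gene variances s^2 (d = n_H + n_L - 2 df) are shrunk toward a
    moment-matched prior: posterior variance (d0*s0^2 + d*s^2) / (d0 + d),
    t with d0 + d df. With ``moderate=False`` this is the ordinary pooled
    two-sample t test. Positive log2fc = higher in L.
    """
    groups = _normalize_groups(groups, logexpr.columns)
    x = logexpr.to_numpy(dtype=float)
    h = x[:, groups == "H"]
    lo = x[:, groups == "L"]
    n_h, n_l = h.shape[1], lo.shape[1]
    d = n_h + n_l - 2
    diff = lo.mean(axis=1) - h.mean(axis=1)
    s2 = (h.var(axis=1, ddof=1) * (n_h - 1) + lo.var(axis=1, ddof=1) * (n_l - 1)) / d
    if moderate:
        d0, s0_2 = _fit_log_var_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df = np.inf
        else:
            s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
            df = d0 + d
    else:
        s2_post = s2
        df = d
    se = np.sqrt(s2_post * (1.0 / n_h + 1.0 / n_l))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    table = pd.DataFrame({
        "log2fc": diff,
        "p_value": p,
        "mean_expression": x.mean(axis=1),
    }, index=logexpr.index.rename("gene_id"))
    table["fdr"] = bh_adjust(table["p_value"])
    return classify_degs(table)


def bh_adjust(p) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment; NaNs pass through untouched.

    Adjusted value for the i-th smallest of m p-values is
    min over j >= i of p_(j) * m / j (cumulative minimum from the largest
    rank), capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    pv = arr[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        fdr = np.empty(m)
        fdr[order] = np.minimum(adj, 1.0)
        out[mask] = fdr
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="fdr")
    return out


def classify_degs(table: pd.DataFrame, fdr_threshold: float = FDR_THRESHOLD,
                  lfc_threshold: float = LFC_THRESHOLD) -> pd.DataFrame:
    """Flag direction per gene using the strict FDR and fold-change cutoffs.

    'up' means higher in the low-stemness group (log2fc > threshold), 'down'
    lower; both require fdr strictly below the FDR cutoff. Boundary values
    (fdr equal to the cutoff, |log2fc| equal to the threshold) are not called.
    """
    table = table.copy()
    sig = table["fdr"] < fdr_threshold
    table["direction"] = np.select(
        [sig & (table["log2fc"] > lfc_threshold), sig & (table["log2fc"] < -lfc_threshold)],
        ["up", "down"], default="ns")
    table.attrs["n_up"] = int((table["direction"] == "up").sum())
    table.attrs["n_down"] = int((table["direction"] == "down").sum())
    return table


def significant_genes(table: pd.DataFrame) -> list[str]:
    """Gene ids called in either direction."""
    return list(table.index[table["direction"] != "ns"])
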