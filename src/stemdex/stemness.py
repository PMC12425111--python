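"""One-class logistic regression stemness signature and mRNAsi scoring.

The signature is a per-gene weight vector w fitted on mean-centered
stem-cell expression profiles x_i by maximizing the ridge-penalized
one-class logistic likelihood

    (1/n) * sum_i [ s_i - log(1 + exp(s_i)) ] - (lambda2 / 2) * ||w||^2,
    s_i = w . x_i  (no intercept).

A cohort sample's raw score rho_j is the Spearman rank correlation between w
and the sample's expression over the shared genes; min-max rescaling of rho
across the cohort gives the stemness index mRNAsi in [0, 1], and dividing by
tumor purity gives the purity-corrected index.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import DataError

log = logging.getLogger(__name__)


@dataclass
class StemnessModel:
    """OCLR weight vector plus the training centering it was fitted under."""

    weights: pd.Series          # indexed by gene id
    centering: pd.Series        # per-gene training means
    penalty_l2: float
    converged: bool
    n_iter: int

    @property
    def gene_ids(self) -> pd.Index:
        return self.weights.index

    def save(self, path: str | Path) -> None:
        """Two-column TSV (gene_id, weight) + JSON sidecar with fit metadata."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.weights.rename("weight").to_csv(path, sep="\t", index_label="gene_id")
        sidecar = {
            "penalty_l2": self.penalty_l2,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "centering": {g: float(c) for g, c in self.centering.items()},
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, path: str | Path) -> "StemnessModel":
        path = Path(path)
        weights = pd.read_csv(path, sep="\t", index_col="gene_id")["weight"]
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            meta = json.load(fh)
        centering = pd.Series(meta["centering"]).reindex(weights.index)
        return cls(weights=weights, centering=centering,
                   penalty_l2=meta["penalty_l2"], converged=meta["converged"],
                   n_iter=meta["n_iter"])


@dataclass
class ScoredCohort:
    """Per-sample stemness scores and the high/low stratification."""

    rho: pd.Series               # raw Spearman correlation with the signature
    mrnasi: pd.Series            # index rescaled to [0, 1]
    corrected_mrnasi: pd.Series  # mrnasi / purity (NaN where purity missing)
    purity: pd.Series
    group: pd.Series             # "H" / "L"

    @property
    def sample_ids(self) -> pd.Index:
        return self.rho.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rho": self.rho, "mrnasi": self.mrnasi,
            "corrected_mrnasi": self.corrected_mrnasi,
            "purity": self.purity, "group": self.group,
        })


def oclr_objective(w: np.ndarray, x_centered: np.ndarray, penalty_l2: float) -> float:
    """Penalized one-class log-likelihood (to be maximized).

    ``x_centered`` is genes x samples, already mean-centered per gene.
    Uses log(sigmoid(s)) = -log1p(exp(-s)) via scipy for overflow safety.
    """
    s = w @ x_centered
    return float(np.mean(special.log_expit(s)) - 0.5 * penalty_l2 * np.dot(w, w))


def _oclr_grad(w: np.ndarray, x_centered: np.ndarray, penalty_l2: float) -> np.ndarray:
    s = w @ x_centered
    # d/ds log(sigmoid(s)) = sigmoid(-s)
    return x_centered @ special.expit(-s) / x_centered.shape[1] - penalty_l2 * w


def fit_oclr(train: pd.DataFrame, penalty_l2: float = 1.0, tol: float = 1e-6,
             max_iter: int = 1000, centering: pd.Series | np.ndarray | None = None) -> StemnessModel:
    """Fit the one-class logistic signature on a genes x samples training matrix.

    Profiles are centered per gene before fitting; the ridge-penalized
    one-class objective is then maximized by L-BFGS with analytic gradient.
    Convergence is declared when the gradient sup-norm is <= ``tol``;
    non-convergence sets ``converged=False`` (with a warning) rather than
    raising.

    ``centering`` supplies the per-gene reference means. The default (None)
    centers by the training means themselves — but note that self-centering
    makes every per-gene profile sum to zero, which pins the one-class
    optimum at exactly w = 0 (by Jensen's inequality the mean log-sigmoid of
    zero-sum scores peaks at w = 0). A useful signature therefore needs
    reference means from a broader matrix — e.g. stem plus differentiated
    samples together — so that the stem profiles retain a nonzero mean
    contrast; a warning is raised when self-centering is used.
    """
    if train.shape[1] < 2 or train.shape[0] < 2:
        raise DataError(f"need >= 2 genes and >= 2 training samples, got {train.shape}")
    x = np.asarray(train, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("training matrix contains non-finite values")
    if penalty_l2 <= 0:
        raise DataError("penalty_l2 must be positive")
    if centering is None:
        warnings.warn("centering by the training means themselves: the one-class "
                      "optimum is w = 0 by construction; pass reference `centering` "
                      "means (e.g. over stem + differentiated samples) for a useful signature")
        centering = x.mean(axis=1)
    elif isinstance(centering, pd.Series):
        centering = centering.reindex(train.index).to_numpy(dtype=float)
    else:
        centering = np.asarray(centering, dtype=float)
    if centering.shape != (train.shape[0],) or not np.isfinite(centering).all():
        raise DataError("centering must be a finite per-gene vector aligned with the training genes")
    xc = x - centering[:, None]

    def neg(w):
        return -oclr_objective(w, xc, penalty_l2), -_oclr_grad(w, xc, penalty_l2)

    w0 = np.zeros(train.shape[0])
    res = optimize.minimize(neg, w0, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter, "gtol": tol * 1e-2,
                                     "ftol": 1e-15})
    w = res.x
    # polish with a few Newton-flavored gradient steps if L-BFGS stopped short
    grad_norm = np.abs(_oclr_grad(w, xc, penalty_l2)).max()
    converged = grad_norm <= tol
    if not converged:
        warnings.warn(f"OCLR did not reach gradient tolerance {tol:g} "
                      f"(sup-norm {grad_norm:.2e} after {res.nit} iterations)")
    return StemnessModel(
        weights=pd.Series(w, index=train.index, name="weight"),
        centering=pd.Series(centering, index=train.index, name="centering"),
        penalty_l2=penalty_l2, converged=bool(converged), n_iter=int(res.nit),
    )


def score_samples(model: StemnessModel, cohort: pd.DataFrame) -> pd.Series:
    """Spearman correlation of each cohort sample with the signature weights.

    Scoring is restricted to the gene intersection; ties get average ranks.
    Cohort expression is used as-is (Spearman is location and scale
    invariant, so no cohort centering is applied).
    """
    shared = model.gene_ids.intersection(cohort.index)
    if len(shared) < 2:
        raise DataError(f"only {len(shared)} genes shared between model and cohort; need >= 2")
    if len(shared) < len(model.gene_ids):
        log.info("scoring on %d of %d model genes present in cohort",
                 len(shared), len(model.gene_ids))
    w = model.weights.loc[shared].to_numpy()
    x = cohort.loc[shared].to_numpy(dtype=float)
    w_rank = stats.rankdata(w)
    x_rank = stats.rankdata(x, axis=0)
    wz = w_rank - w_rank.mean()
    xz = x_rank - x_rank.mean(axis=0)
    denom = np.sqrt(np.sum(wz**2) * np.sum(xz**2, axis=0))
    with np.errstate(invalid="ignore"):
        rho = (wz @ xz) / denom
    return pd.Series(rho, index=cohort.columns, name="rho")


def rescale_to_index(rho: pd.Series, method: str = "minmax") -> pd.Series:
    """Map raw Spearman scores to the [0, 1] stemness index.

    ``method="minmax"`` (default) subtracts the cohort minimum and divides by
    the range, guaranteeing min 0 / max 1. ``method="max"`` keeps the literal
    subtract-min-divide-by-max reading, which does not guarantee a [0, 1]
    range. A constant cohort yields all zeros with a degenerate-cohort warning.
    """
    if len(rho) == 0:
        raise DataError("cannot rescale an empty score vector")
    lo, hi = float(np.min(rho)), float(np.max(rho))
    if hi == lo:
        warnings.warn("degenerate cohort: all Spearman scores equal; index set to 0")
        return pd.Series(np.zeros(len(rho)), index=rho.index, name="mrnasi")
    denom = (hi - lo) if method == "minmax" else hi
    if denom == 0:
        raise DataError("rescaling denominator is zero under method='max'")
    return ((rho - lo) / denom).rename("mrnasi")


def correct_for_purity(mrnasi: pd.Series, purity: pd.Series) -> pd.Series:
    """Purity-corrected index: mRNAsi / tumor purity, elementwise.

    Samples with missing purity are excluded with a warning; purity outside
    (0, 1] is a data error.
    """
    purity = purity.reindex(mrnasi.index)
    missing = purity.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} samples lack purity and are excluded "
                      "from the corrected index")
    valid = purity[~missing]
    if ((valid <= 0) | (valid > 1)).any():
        bad = valid[(valid <= 0) | (valid > 1)]
        raise DataError(f"purity must lie in (0, 1]; offending samples: {list(bad.index[:5])}")
    return (mrnasi[~missing] / valid).rename("corrected_mrnasi")


def split_by_median(index: pd.Series) -> pd.Series:
    """High/low stratification: 'H' where the index is >= the cohort median.

    Values equal to the median go to the high group; with all values equal,
    every sample is 'H' (degenerate but well-defined).
    """
    if len(index) < 2:
        raise DataError("median split needs >= 2 samples")
    med = float(np.median(index))
    return pd.Series(np.where(index >= med, "H", "L"), index=index.index, name="group")


def score_cohort(model: StemnessModel, cohort: pd.DataFrame,
                 purity: pd.Series | None = None,
                 rescale_method: str = "minmax") -> ScoredCohort:
    """Full scoring pass: rho -> mRNAsi -> corrected mRNAsi -> H/L groups."""
    rho = score_samples(model, cohort)
    mrnasi = rescale_to_index(rho, method=rescale_method)
    if purity is None:
        purity = pd.Series(1.0, index=mrnasi.index, name="purity")
    corrected = correct_for_purity(mrnasi, purity).reindex(mrnasi.index)
    group = split_by_median(mrnasi)
    return ScoredCohort(rho=rho, mrnasi=mrnasi, corrected_mrnasi=corrected,
                        purity=purity.reindex(mrnasi.index), group=group)
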