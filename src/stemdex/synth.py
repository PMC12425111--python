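"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of a stemness study: a stem-cell
training set carrying a planted up/down expression signature, a tumor cohort
whose samples carry a latent stemness level theta in [0, 1] that drives the
signature, purity contamination by a fixed non-tumor profile, negative
binomial sequencing counts, stemness-linked survival (higher stemness gives
longer survival), stage/subtype labels correlated with stemness, a
clique-structured protein-interaction network over the planted genes, and a
gene-set collection containing one set concentrated in the planted genes.

All randomness flows from ``SynthConfig.seed``; every generator is
deterministic given the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError

#: log2 baseline expression is drawn N(BASELINE_MEAN, BASELINE_SD) per gene
BASELINE_MEAN = 6.0
BASELINE_SD = 2.0

#: baseline hazard per day: median survival ~2 years at theta = 0
BASELINE_HAZARD = np.log(2.0) / 730.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Parameters
    ----------
    n_genes, n_stem_samples, n_tumor_samples
        Universe and sample sizes.
    n_signature_up, n_signature_dn
        How many genes the stemness signature raises / lowers.
    signature_effect
        Full-strength shift of a signature gene, in log2 units.
    noise_sd
        Gaussian noise on log2 expression.
    purity_range
        Tumor purity is drawn uniform on this interval within (0, 1].
    hazard_beta
        Log hazard ratio per unit stemness; hazard = h0 * exp(-beta * theta),
        so positive beta means higher stemness -> longer survival.
    censor_rate
        Fraction of samples whose survival time is right-censored.
    nb_dispersion
        Negative binomial size parameter for the count layer (variance =
        mu + mu^2 / size).
    clique_sizes, background_edge_prob
        Planted-clique sizes and Erdos-Renyi background density of the
        interaction network.
    gene_set_size, planted_set_purity
        Gene-set generator: set size, and the fraction of the planted set's
        members drawn from the planted DE genes.
    """

    n_genes: int = 2000
    n_stem_samples: int = 78
    n_diff_samples: int = 100
    n_tumor_samples: int = 200
    n_signature_up: int = 100
    n_signature_dn: int = 100
    signature_effect: float = 2.0
    noise_sd: float = 1.0
    purity_range: tuple[float, float] = (0.6, 0.95)
    hazard_beta: float = float(np.log(2.5))
    censor_rate: float = 0.3
    nb_dispersion: float = 10.0
    clique_sizes: tuple[int, ...] = (6,)
    background_edge_prob: float = 0.05
    gene_set_size: int = 50
    planted_set_purity: float = 0.9
    seed: int = 0

    def validate(self) -> "SynthConfig":
        for name in ("n_genes", "n_stem_samples", "n_diff_samples", "n_tumor_samples",
                     "n_signature_up", "n_signature_dn"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_signature_up + self.n_signature_dn >= self.n_genes:
            raise ConfigError("signature genes must be fewer than n_genes")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(f"purity_range must lie within (0, 1], got {self.purity_range}")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigError(f"censor_rate must be in [0, 1], got {self.censor_rate}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        return self

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream verification."""

    latent_stemness: pd.Series  # theta_i in [0, 1], indexed by tumor sample id
    signature_up: set[str]
    signature_dn: set[str]
    de_genes: set[str] = field(default_factory=set)
    planted_cliques: list[set[str]] = field(default_factory=list)
    enriched_set_name: str = "planted_enriched"


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _signature(cfg: SynthConfig, rng: np.random.Generator):
    """Baseline per-gene expression and the signed signature pattern.

    Derived from a child seed so training set and cohort share the same
    planted biology without sharing their noise streams.
    """
    genes = _gene_ids(cfg.n_genes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=cfg.n_genes)
    idx = rng.permutation(cfg.n_genes)
    up = idx[: cfg.n_signature_up]
    dn = idx[cfg.n_signature_up: cfg.n_signature_up + cfg.n_signature_dn]
    pattern = np.zeros(cfg.n_genes)
    pattern[up] = cfg.signature_effect
    pattern[dn] = -cfg.signature_effect
    up_ids = {genes[i] for i in up}
    dn_ids = {genes[i] for i in dn}
    return genes, baseline, pattern, up_ids, dn_ids


def _rngs(cfg: SynthConfig) -> dict[str, np.random.Generator]:
    """Independent child streams so each generator is reproducible in isolation."""
    root = np.random.SeedSequence(cfg.seed)
    names = ["signature", "training", "progenitors", "cohort", "cliques", "network", "genesets"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def generate_training_set(cfg: SynthConfig) -> pd.DataFrame:
    """Stem-cell expression (genes x samples, log2 scale) with the planted signature.

    Up-signature genes sit ``signature_effect`` above their baseline and
    down-signature genes the same amount below, plus N(0, noise_sd) noise.
    """
    cfg.validate()
    rngs = _rngs(cfg)
    genes, baseline, pattern, _, _ = _signature(cfg, rngs["signature"])
    rng = rngs["training"]
    mean = baseline + pattern  # stem samples express the signature at full strength
    x = mean[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_stem_samples))
    cols = [f"SC{j:03d}" for j in range(cfg.n_stem_samples)]
    return pd.DataFrame(x, index=genes, columns=cols)


def generate_progenitor_set(cfg: SynthConfig) -> pd.DataFrame:
    """Differentiated-progeny expression: the signature-free baseline plus noise.

    These samples play the role the differentiated progeny play in the real
    training design: they anchor the per-gene centering means so the one-class
    fit captures the stem-versus-differentiated contrast rather than absolute
    expression (centering stem profiles by their own means alone collapses the
    one-class optimum to w = 0).
    """
    cfg.validate()
    rngs = _rngs(cfg)
    genes, baseline, _, _, _ = _signature(cfg, rngs["signature"])
    rng = rngs["progenitors"]
    x = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_diff_samples))
    cols = [f"DP{j:03d}" for j in range(cfg.n_diff_samples)]
    return pd.DataFrame(x, index=genes, columns=cols)


def generate_tumor_cohort(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Tumor cohort: log2 expression, NB counts, clinical table, and truth.

    Per sample: theta_i ~ U[0,1]; pure-tumor log2 expression is baseline +
    theta_i * pattern + noise; purity contamination mixes the linear-scale
    signal with a fixed normal profile in proportion (1 - p_i); counts are
    NB with mean 2^expression and size ``nb_dispersion``; survival is
    exponential with hazard h0 * exp(-hazard_beta * theta_i) and independent
    censoring at rate ``censor_rate``; stage is drawn so expected theta
    decreases with stage.
    """
    cfg.validate()
    rngs = _rngs(cfg)
    genes, baseline, pattern, up_ids, dn_ids = _signature(cfg, rngs["signature"])
    rng = rngs["cohort"]
    n = cfg.n_tumor_samples
    samples = [f"T{j:04d}" for j in range(n)]

    theta = rng.uniform(0.0, 1.0, size=n)
    purity = rng.uniform(cfg.purity_range[0], cfg.purity_range[1], size=n)

    tumor = (baseline[:, None] + np.outer(pattern, theta)
             + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n)))
    # fixed contaminating profile: the signature-free baseline with its own
    # (deterministic within the cohort) noise draw
    normal_profile = baseline + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
    # mixing happens on the linear scale, as bulk mixtures compose physically
    mixed_linear = purity[None, :] * np.exp2(tumor) + (1.0 - purity)[None, :] * np.exp2(normal_profile)[:, None]
    expr = np.log2(mixed_linear)

    mu = np.exp2(expr)
    counts = rng.negative_binomial(cfg.nb_dispersion, cfg.nb_dispersion / (cfg.nb_dispersion + mu))

    clinical = _clinical_table(cfg, rng, samples, theta, purity)

    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = SyntheticTruth(
        latent_stemness=pd.Series(theta, index=samples, name="theta"),
        signature_up=up_ids,
        signature_dn=dn_ids,
        de_genes=up_ids | dn_ids,
    )
    truth.planted_cliques = _plant_cliques(cfg, truth, rngs["cliques"])
    return expr_df, counts_df, clinical, truth


def _survival(cfg, rng, theta, n):
    hazard = BASELINE_HAZARD * np.exp(-cfg.hazard_beta * theta)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=n) < cfg.censor_rate
    t_obs = np.where(censored, rng.uniform(size=n) * t_event, t_event)
    time = np.maximum(1.0, np.round(t_obs))
    event = (~censored).astype(int)
    return time, event


def _clinical_table(cfg, rng, samples, theta, purity) -> pd.DataFrame:
    n = len(samples)
    # stage score rises as stemness falls; quartile cut gives stages I-IV
    stage_score = (1.0 - theta) + rng.normal(0.0, 0.5, size=n)
    stage = pd.qcut(stage_score, 4, labels=["I", "II", "III", "IV"]).astype(str)
    t_stage = pd.qcut(stage_score + rng.normal(0, 0.3, n), 4, labels=["T1", "T2", "T3", "T4"]).astype(str)
    n_stage = np.where(stage_score + rng.normal(0, 0.5, n) > np.median(stage_score), "N1", "N0")
    m_stage = np.where(stage == "IV", "M1", "M0")
    invasion_p = 1.0 / (1.0 + np.exp(-(stage_score - np.median(stage_score))))
    lymphatic = (rng.uniform(size=n) < invasion_p).astype(int)
    vascular = (rng.uniform(size=n) < invasion_p).astype(int)
    # mesenchymal-like subtype concentrates at low stemness
    cms4_p = 0.15 + 0.5 * (1.0 - theta)
    is_cms4 = rng.uniform(size=n) < cms4_p
    other = rng.choice(["CMS1", "CMS2", "CMS3"], size=n)
    subtype = np.where(is_cms4, "CMS4", other)

    pfs_time, pfs_event = _survival(cfg, rng, theta, n)
    dss_time, dss_event = _survival(cfg, rng, theta, n)
    return pd.DataFrame(
        {
            "stage": stage,
            "T": t_stage,
            "N": n_stage,
            "M": m_stage,
            "lymphatic_invasion": lymphatic,
            "vascular_invasion": vascular,
            "subtype": subtype,
            "purity": purity,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "dss_time": dss_time,
            "dss_event": dss_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )


def _plant_cliques(cfg: SynthConfig, truth: SyntheticTruth, rng: np.random.Generator) -> list[set[str]]:
    pool = sorted(truth.de_genes)
    cliques: list[set[str]] = []
    for k in cfg.clique_sizes:
        if k > len(pool):
            raise ConfigError(f"clique size {k} exceeds remaining planted-gene pool {len(pool)}")
        members = list(rng.choice(pool, size=k, replace=False))
        cliques.append(set(members))
        pool = [g for g in pool if g not in cliques[-1]]
    return cliques


def generate_network(truth: SyntheticTruth, cfg: SynthConfig) -> pd.DataFrame:
    """STRING-style edge list over the planted DE genes.

    Planted cliques are fully connected with combined scores uniform on
    (0.45, 1.0) — all above the 0.4 retention cutoff; background edges are
    Erdos-Renyi with scores uniform on (0, 1).
    """
    cfg.validate()
    if not truth.planted_cliques:
        raise ConfigError("truth has no planted cliques")
    rng = _rngs(cfg)["network"]
    nodes = sorted(truth.de_genes)
    edges: dict[tuple[str, str], float] = {}
    n = len(nodes)
    if cfg.background_edge_prob > 0:
        mask = rng.uniform(size=(n, n)) < cfg.background_edge_prob
        scores = rng.uniform(size=(n, n))
        iu = np.triu_indices(n, k=1)
        for i, j in zip(*iu):
            if mask[i, j]:
                edges[(nodes[i], nodes[j])] = float(scores[i, j])
    for clique in truth.planted_cliques:
        members = sorted(clique)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                edges[(members[a], members[b])] = float(rng.uniform(0.45, 1.0))
    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["node1", "node2", "combined_score"],
    )
    return df


def generate_gene_sets(truth: SyntheticTruth, n_sets: int, cfg: SynthConfig) -> dict[str, set[str]]:
    """GMT-style collection with one set concentrated in the planted DE genes.

    The planted set draws ``planted_set_purity`` of its members from
    ``truth.de_genes`` and the rest from the background; remaining sets are
    uniform draws from the gene universe.
    """
    cfg.validate()
    if n_sets < 1:
        raise ConfigError("n_sets must be >= 1")
    rng = _rngs(cfg)["genesets"]
    universe = _gene_ids(cfg.n_genes)
    background = sorted(set(universe) - truth.de_genes)
    de = sorted(truth.de_genes)

    k = min(cfg.gene_set_size, len(universe))
    n_from_de = min(int(round(cfg.planted_set_purity * k)), len(de))
    planted = set(rng.choice(de, size=n_from_de, replace=False))
    planted |= set(rng.choice(background, size=k - n_from_de, replace=False))

    sets: dict[str, set[str]] = {truth.enriched_set_name: planted}
    for i in range(1, n_sets):
        sets[f"random_set_{i:03d}"] = set(rng.choice(universe, size=k, replace=False))
    return sets
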