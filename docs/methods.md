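# Methods

## The stemness index

The core of the package is a transcriptomic stemness index. A weight vector
`w` over genes is learned from stem-cell expression profiles by one-class
logistic regression (OCLR): with per-gene-centered training profiles
`x_i` (genes × samples, log2 scale) and scores `s_i = w·x_i`, the fit
maximizes the ridge-penalized one-class log-likelihood

    L(w) = (1/n) Σ_i [ s_i − log(1 + exp(s_i)) ] − (λ₂/2) ‖w‖²,

with no intercept. `s − log(1+e^s) = log σ(s)` is concave and monotone in
`s`, so `L` is strictly concave and the optimum is unique. We maximize it
with L-BFGS using the analytic gradient `(1/n) Σ_i σ(−s_i) x_i − λ₂ w`;
convergence is declared when the gradient sup-norm falls below `tol`
(default 1e-6, `max_iter` 1000), and a failed fit sets a flag rather than
raising. Defaults: ridge only, `λ₂ = 1`, no L1 term — the configuration the
published pan-cancer stemness workflow uses.

A cohort sample `j` is scored by the Spearman rank correlation `ρ_j`
between `w` and the sample's expression over the genes shared with the
model (average ranks on ties; duplicate gene symbols are collapsed by mean
at read time). Cohort samples are not centered — Spearman is invariant to
per-sample location and scale, and more generally to any strictly
increasing per-sample transform, which is the key robustness property of
the index. `ρ` is mapped to the index by min–max rescaling across the
cohort, `mRNAsi_j = (ρ_j − min ρ)/(max ρ − min ρ)`, so the cohort minimum
is exactly 0 and the maximum exactly 1. The purity-corrected index is the
elementwise quotient `mRNAsi / purity`, with purity an input column in
(0, 1]. Samples are stratified at the cohort median: index ≥ median → "H",
otherwise "L" (ties at the median go high).

### Why the centering reference matters

Centering the stem profiles by their **own** per-gene means makes every
gene's values sum to zero across training samples, and then `w = 0` is the
exact global maximizer of `L` for any ridge strength: by Jensen's
inequality `mean_i log σ(s_i) ≤ log σ(mean_i s_i) = log σ(0)`, with
equality at `w = 0`, and the penalty only sharpens this. A useful signature
therefore requires centering means computed on a broader matrix in which
the stem samples deviate from the average — in the original workflow, the
stem **and** differentiated-progeny samples together. `fit_oclr` exposes
this as the `centering` argument (per-gene reference means); the default,
self-centering, is retained for completeness but warns, since it provably
returns the zero vector. The pipeline centers on the combined
stem + progenitor gene means.

### Rescaling variants

The min–max map is the default because it is the only reading that
guarantees a [0, 1] index. A literal subtract-min-then-divide-by-max
variant is available as `rescale_to_index(..., method="max")` for
comparison; it does not reach 1 unless the maximum correlation dominates.
A cohort with constant `ρ` yields an all-zero index plus a warning.

## Survival and clinical association

Survival records missing time or status, or with time < 30 days, are
excluded before analysis (the conventional guard against perioperative
events; the boundary is strict, 30 days is retained). Curves use the
Kaplan–Meier product-limit estimator and group contrasts the two-sided
log-rank test with chi-square asymptotics on k−1 df (both via lifelines);
no exact small-sample option is provided. Index-versus-covariate contrasts
are rank-based: Wilcoxon rank-sum for two levels, Kruskal–Wallis for three
or more, asymptotic p-values with tie correction (scipy). Per-gene survival
splits reuse the median rule, and a degenerate split (constant gene) is an
error, never a silent p-value.

## Differential expression

Counts are normalized by median-of-ratios size factors: per sample, the
median over all-positive genes of the count divided by the gene's
geometric mean. Each gene is fit with a negative binomial GLM (log link,
`variance = μ + αμ²`) with design `[intercept, group]` and log-size-factor
offsets, implemented as a vectorized IRLS across genes (working weight
`μ/(1+αμ)`, 2×2 normal equations per gene, linear predictor clipped to
±30). Dispersion `α` is a per-gene method-of-moments estimate on
normalized counts, pooled across the two groups by degrees of freedom and
floored at 1e-8 — deliberately simpler than shrinkage-based estimators,
with no fold-change shrinkage either. The Wald z on the group coefficient
gives a two-sided normal p; `log2FC = β₁/ln 2`, with the sign convention
that positive means higher in the low-stemness group. Genes with total
count < 10 are pre-filtered (configurable off); all-zero genes get NA
p-values and are excluded from FDR.

For log-intensity data the alternative route is an empirical-Bayes
moderated t: pooled per-gene variances `s²` (d df) are shrunk toward a
scaled-inverse-chi-square prior whose parameters `(d₀, s₀²)` are
moment-matched on the log sample variances using digamma/trigamma
identities (`E[log s²]` and `Var[log s²]` of log-F), with the posterior
variance `(d₀s₀² + ds²)/(d₀+d)` and t on `d₀+d` df; an infinite `d₀`
(under-dispersed log-variances) degenerates to a common variance and a
normal reference. `moderate=False` gives the ordinary pooled t exactly.

Multiple testing uses Benjamini–Hochberg step-up with monotonicity
enforced by a cumulative minimum from the largest rank; NaNs pass through
and do not count toward m. Significance is strict on both thresholds:
FDR < 0.05 **and** |log2FC| > 1 — boundary values are not called.

## Enrichment

Over-representation of a query list against GMT gene sets is the one-sided
hypergeometric upper tail `P(X ≥ k)` with the universe defaulting to the
genes actually tested for differential expression (the statistically
defensible background, configurable). Sets with fewer than 3 members in
the universe are skipped; BH runs across tested sets. Depletion is not
tested.

## Network hubs

STRING-style edges are kept when the combined score is strictly above 0.4
(scores on the 0–1000 integer convention are auto-detected and divided by
1000; duplicate pairs keep the maximum; self-loops are dropped). The graph
may be restricted to the significant DEG list, reporting unmapped genes.
Hubs are ranked by Maximal Clique Centrality,
`MCC(v) = Σ_{maximal cliques C ∋ v} (|C|−1)!`, computed from a full
Bron–Kerbosch-with-pivoting enumeration (networkx); an isolated node's
only maximal clique is the singleton, so it scores `0! = 1`. Enumeration is
worst-case exponential, so graphs above a node limit (default 20000) are
refused with guidance instead of hanging. Ranking sorts by score, then
degree, then gene id — fully deterministic — and flags the top 10 (degree
ranking is available as an alternative method). Hub expression is related
to the index by Pearson correlation with t-based two-sided p-values.

## The synthetic cohort

The generator produces every pipeline input with known ground truth, under
one root seed split into independent child streams (so each generator is
reproducible in isolation).

* **Expression.** Per-gene baseline log2 expression ~ N(6, 2). A signature
  of `n_signature_up` = 100 up- and `n_signature_dn` = 100 down-genes (of
  2000) shifts by ±`signature_effect` = 2.0 log2 units at full strength.
  Stem samples (n = 78, matching a typical pluripotent training set)
  express the signature fully; differentiated progenitors (n = 100)
  express baseline only; tumor sample `i` expresses it at its latent
  stemness `θ_i ~ U[0,1]`. Gaussian noise sd 1.0 throughout.
* **Purity.** Tumor purity `p_i ~ U(0.6, 0.95)`. The observed bulk signal
  mixes tumor and a fixed normal profile **on the linear scale** —
  `log2(p·2^tumor + (1−p)·2^normal)` — as physical mixtures compose.
* **Counts.** Negative binomial with mean `2^expression` and size
  (`nb_dispersion`) 10, i.e. α = 0.1, a typical bulk RNA-seq dispersion.
* **Survival.** Exponential event times with hazard
  `h₀·exp(−β·θ_i)`, `h₀ = ln 2 / 730` per day (median two years at θ = 0)
  and `β = ln 2.5`, so higher stemness means longer survival — the
  direction the index shows in colorectal cohorts. Censoring: a
  Bernoulli(`censor_rate` = 0.3) flag with the censored time drawn uniform
  on (0, T) — the exact-rate simulation convention. Times are rounded to
  whole days with a 1-day floor, so the 30-day filter engages naturally.
* **Clinical covariates.** Stage I–IV is a noisy quartile cut of `1−θ`
  (expected stemness falls with stage); T/N/M and invasion flags derive
  from the same score; the mesenchymal-like subtype label concentrates at
  low stemness.
* **Network.** Nodes are the planted signature genes; planted cliques
  (default one 6-clique) are fully connected with scores U(0.45, 1) — all
  above the 0.4 cutoff — over an Erdős–Rényi background (p = 0.05) with
  U(0, 1) scores.
* **Gene sets.** One planted set draws 90% of its 50 members from the
  signature genes; the remaining sets are uniform draws.

What the generator does **not** emulate: platform/batch effects, realistic
gene–gene correlation beyond the planted signature, library-size variation
in the count layer, informative censoring, and any real-cohort structure.
Passing tests therefore demonstrate algorithmic correctness and calibration
under a clean generative model, not performance on real tumor data.

## Numerical choices and degenerate inputs

* OCLR: `log σ` via `scipy.special.log_expit` (overflow-safe); L-BFGS with
  `ftol` 1e-15 so the gradient criterion governs.
* Spearman scoring is computed from average ranks and a vectorized Pearson
  step; a constant sample yields NaN rather than an arbitrary value.
* NB IRLS: 50 iterations max, step tolerance 1e-8, singular normal
  equations freeze the affected gene's coefficients at their last value.
* Median split: NumPy midpoint median; ties at the median are "H".
* Log-rank returns statistic exactly 0 and p = 1 for numerically null
  contrasts; a group with zero events warns.
* Hub ranking tie-break (score, degree, id) makes reruns byte-identical.

## Problem sizes used in the bundled checks

The acceptance script and heavy tests use the default cohort
(2000 genes × 200 samples), 100 random small instances for the optimizer
oracle, 1000 null replicates for log-rank calibration, 200 replicates for
power, 2000 null genes and 100 planted genes for the NB Wald checks, a
full margin sweep of universes ≤ 12 for the exact enrichment comparison,
and 100 random graphs / 100 generator seeds for the network checks —
sizes at which every simulated quantity is stable to well within the
asserted bands.

## Known limitations

* The NB dispersion estimator is method-of-moments, not Cox–Reid adjusted;
  at very small group sizes its p-values are slightly anti-conservative.
* The moderated-t prior fit assumes a common prior across the intensity
  range (no intensity trend).
* The enrichment universe choice differs from tools that default to a
  genome-wide background; p-values are not comparable across that choice.
* MCC requires full maximal-clique enumeration; extremely dense graphs can
  be exponential even below the node limit.
* Which of the eleven CytoHubba-style rankings a given study used is often
  unstated; MCC is this package's default as that tool's flagship score,
  with degree ranking as the alternative.
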