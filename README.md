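# stemdex

A tested, reusable implementation of the transcriptomic stemness-index
workflow used in cancer stemness studies: learn a stem-cell signature by
one-class logistic regression, score tumor samples with a rank-based
stemness index (mRNAsi), and run the downstream stages — high/low
stratification, clinical association and survival, differential
expression, gene-set enrichment, and interaction-network hub-gene
ranking — as one pipeline over plain-text inputs.

## The problem and who this is for

Cancer stem cells drive initiation, metastasis and therapy resistance, but
quantifying "how stem-like" a bulk tumor sample is from its transcriptome
requires a calibrated index rather than marker eyeballing. The mRNAsi
approach trains a one-class model on pluripotent stem-cell expression and
scores each tumor by how its expression ranks against the learned
signature. This package is for computational biologists who want that
workflow as an importable, unit-tested Python library — with every stage
verifiable against a bundled synthetic-data generator that plants known
ground truth (latent stemness, differential genes, network cliques,
enriched sets), so the statistics can be checked end to end without any
external cohort download.

## The model

With mean-centered stem-cell profiles `x_i` and scores `s_i = w·x_i`, the
signature `w` maximizes the ridge-penalized one-class logistic likelihood

    (1/n) Σ_i [ s_i − log(1 + exp(s_i)) ] − (λ₂/2) ‖w‖² ,

a strictly concave problem solved by L-BFGS. A cohort sample's raw score is
the Spearman correlation ρ between `w` and its expression over shared
genes; min–max rescaling across the cohort gives `mRNAsi ∈ [0, 1]`, and
division by tumor purity gives the corrected index. Samples split at the
median (ties go high) into mRNAsi-H/L; downstream stages test survival
(Kaplan–Meier / log-rank, 30-day exclusion), covariate association
(Wilcoxon / Kruskal–Wallis), differential expression (NB Wald with
median-of-ratios normalization, or moderated t; strict FDR < 0.05 and
|log2FC| > 1), hypergeometric over-representation, and Maximal Clique
Centrality hub ranking (`MCC(v) = Σ_{cliques C ∋ v} (|C|−1)!`, edges with
combined score > 0.4). Details, conventions and caveats: `docs/methods.md`.

## Worked example

`examples/` contains one short script per capability. The first fits the
signature and scores a synthetic cohort:

```bash
python examples/01_score_stemness.py
```

```
fitted 2000 gene weights, converged=True in 13 iterations

lowest- and highest-stemness samples (mRNAsi spans [0, 1] by construction):
         rho  mrnasi  corrected_mrnasi  purity group
T0053 -0.018   0.000             0.000   0.913     L
T0097 -0.014   0.029             0.035   0.828     L
T0074 -0.013   0.031             0.035   0.881     L
T0141  0.111   0.929             1.063   0.874     H
T0190  0.115   0.956             1.013   0.944     H
T0139  0.121   1.000             1.167   0.857     H

Spearman(mRNAsi, planted latent stemness) = 0.951
```

Each sample's `rho` is its rank correlation with the signature; `mrnasi`
rescales those to [0, 1]; `corrected_mrnasi` divides by purity. The final
line compares the index against the latent stemness the generator planted —
0.951 means the index recovers the simulated stemness gradient almost
perfectly. The survival example then shows the planted direction of effect
(log-rank H vs L on progression-free survival, p = 0.046, with the
high-stemness group's two-year survival 0.75 vs 0.63), and the remaining
scripts walk through differential expression + enrichment, hub ranking,
and the full pipeline.

The same stages are available from the shell:

```bash
stemdex synth --outdir data --seed 0
stemdex fit   --train data/training_expression.tsv \
              --reference data/progenitor_expression.tsv --out model.tsv
stemdex score --model model.tsv --expr data/cohort_expression.tsv \
              --clinical data/clinical.tsv --out scores.tsv
stemdex de    --counts data/cohort_counts.tsv --scores scores.tsv --out degs.tsv
stemdex run   --seed 0 --outdir full_run     # everything, with a manifest
```

All formats are plain TSV/GMT/JSON; real cohort matrices, clinical tables,
GMT collections and STRING-style edge lists drop into the same commands via
the `inputs:` section of the run config.

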