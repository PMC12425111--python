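"""Fit the one-class stemness signature and score a tumor cohort.

Generates a synthetic stem-cell training set plus a tumor cohort with known
latent stemness, fits the OCLR weight vector (centered on the combined
stem + differentiated-progeny means), and scores every tumor sample:
Spearman rho against the signature, mRNAsi in [0, 1], and the
purity-corrected index.
"""

import pandas as pd
from scipy.stats import spearmanr

import stemdex as sd

cfg = sd.SynthConfig(seed=0)
train = sd.generate_training_set(cfg)          # 2000 genes x 78 stem samples
reference = sd.generate_progenitor_set(cfg)    # differentiated baseline samples
expr, counts, clinical, truth = sd.generate_tumor_cohort(cfg)

centering = pd.concat([train, reference], axis=1).mean(axis=1)
model = sd.fit_oclr(train, centering=centering)
print(f"fitted {len(model.gene_ids)} gene weights, converged={model.converged} "
      f"in {model.n_iter} iterations")

scored = sd.score_cohort(model, expr, purity=clinical["purity"])
frame = scored.to_frame().sort_values("mrnasi")
print("\nlowest- and highest-stemness samples (mRNAsi spans [0, 1] by construction):")
print(pd.concat([frame.head(3), frame.tail(3)]).round(3))

rho = spearmanr(scored.mrnasi, truth.latent_stemness).statistic
print(f"\nSpearman(mRNAsi, planted latent stemness) = {rho:.3f}")
print("-> the rank-based index recovers the simulated stemness gradient; the")
print("   corrected column divides mRNAsi by tumor purity to undo stromal dilution.")
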