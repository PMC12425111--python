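import warnings

import pandas as pd
import pytest

import stemdex as sd


@pytest.fixture(scope="session")
def small_cfg() -> sd.SynthConfig:
    """Scaled-down study conditions for fast unit tests."""
    return sd.SynthConfig(n_genes=300, n_stem_samples=20, n_diff_samples=20,
                          n_tumor_samples=60, n_signature_up=30, n_signature_dn=30,
                          seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic cohort (2000 genes x 200 samples), shared across tests."""
    cfg = sd.SynthConfig(seed=0)
    expr, counts, clinical, truth = sd.generate_tumor_cohort(cfg)
    return cfg, expr, counts, clinical, truth


@pytest.fixture(scope="session")
def default_model(default_cohort):
    """OCLR signature fitted on the default training set with progenitor centering."""
    cfg = default_cohort[0]
    train = sd.generate_training_set(cfg)
    reference = sd.generate_progenitor_set(cfg)
    centering = pd.concat([train, reference], axis=1).mean(axis=1)
    return sd.fit_oclr(train, centering=centering)


@pytest.fixture(scope="session")
def default_scored(default_cohort, default_model):
    _, expr, _, clinical, _ = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sd.score_cohort(default_model, expr, purity=clinical["purity"])
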