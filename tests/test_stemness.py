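"""OCLR fitting, Spearman scoring, index rescaling, purity correction, splits."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stemdex as sd
from stemdex.exceptions import DataError
from stemdex.stemness import oclr_objective

from oracles import oclr_objective_ref, oclr_optimize_ref


def _fit_quiet(train, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sd.fit_oclr(train, **kw)


class TestFitOCLR:
    def test_single_active_gene_matches_grid_oracle(self):
        # gene 1 carries centered values (+1, -1); gene 2 is inert (all zero).
        train = pd.DataFrame([[1.0, -1.0], [0.0, 0.0]], index=["g1", "g2"],
                             columns=["s1", "s2"])
        model = _fit_quiet(train, penalty_l2=1.0, centering=np.zeros(2))
        xc = train.to_numpy()
        grid = np.linspace(-3, 3, 200001)
        vals = [oclr_objective_ref(np.array([w, 0.0]), xc, 1.0) for w in grid]
        w_star = grid[int(np.argmax(vals))]
        assert abs(model.weights["g1"] - w_star) < 1e-4
        # 1-D stationarity of the fitted weight
        obj = oclr_objective(model.weights.to_numpy(), xc, 1.0)
        assert obj >= max(vals) - 1e-9

    def test_identical_samples_self_centered_gives_zero(self):
        train = pd.DataFrame(np.tile([[5.0], [2.0], [7.0]], (1, 4)),
                             index=list("abc"), columns=list("wxyz"))
        with pytest.warns(UserWarning):
            model = sd.fit_oclr(train)
        assert np.allclose(model.weights, 0.0)
        assert model.converged

    def test_random_instance_beats_random_search(self):
        rng = np.random.default_rng(42)
        train = pd.DataFrame(rng.normal(0, 1, (5, 6)))
        model = _fit_quiet(train, penalty_l2=1.0, centering=np.zeros(5))
        xc = train.to_numpy()
        fitted = oclr_objective(model.weights.to_numpy(), xc, 1.0)
        draws = rng.normal(0, 1, (1000, 5))
        best_random = max(oclr_objective(w, xc, 1.0) for w in draws)
        assert fitted >= best_random - 1e-12

    def test_small_instances_match_independent_optimizer(self):
        rng = np.random.default_rng(1)
        for i in range(20):
            g = rng.integers(2, 4)
            n = rng.integers(2, 7)
            train = pd.DataFrame(rng.normal(0, 1.5, (g, n)))
            model = _fit_quiet(train, penalty_l2=1.0, centering=np.zeros(g))
            ours = oclr_objective(model.weights.to_numpy(), train.to_numpy(), 1.0)
            ref = oclr_optimize_ref(train.to_numpy(), 1.0, seed=i)
            assert ours >= ref - 1e-6

    def test_nonfinite_input_rejected(self):
        train = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(DataError):
            sd.fit_oclr(train)

    def test_model_roundtrip(self, tmp_path, default_model):
        path = tmp_path / "model.tsv"
        default_model.save(path)
        loaded = sd.StemnessModel.load(path)
        assert list(loaded.gene_ids) == list(default_model.gene_ids)
        assert np.allclose(loaded.weights, default_model.weights)
        assert np.allclose(loaded.centering, default_model.centering)
        assert loaded.penalty_l2 == default_model.penalty_l2
        assert loaded.converged == default_model.converged


class TestScoring:
    def _model(self, w, genes):
        return sd.StemnessModel(weights=pd.Series(w, index=genes),
                                centering=pd.Series(0.0, index=genes),
                                penalty_l2=1.0, converged=True, n_iter=1)

    def test_monotone_transform_of_weights_scores_one(self):
        genes = [f"g{i}" for i in range(10)]
        w = np.arange(10, dtype=float)
        model = self._model(w, genes)
        cohort = pd.DataFrame({"s1": np.exp(w / 3) + 5, "s2": -w}, index=genes)
        rho = sd.score_samples(model, cohort)
        assert rho["s1"] == pytest.approx(1.0)
        assert rho["s2"] == pytest.approx(-1.0)

    def test_hand_computed_three_gene_case(self):
        # weight ranks (1,2,3) vs sample ranks (2,1,3): rho = 1 - 6*2/24 = 0.5
        model = self._model([10.0, 20.0, 30.0], ["a", "b", "c"])
        cohort = pd.DataFrame({"s": [5.0, 1.0, 9.0]}, index=["a", "b", "c"])
        assert sd.score_samples(model, cohort)["s"] == pytest.approx(0.5)

    def test_insufficient_overlap_names_size(self):
        model = self._model([1.0, 2.0], ["a", "b"])
        cohort = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "zz"])
        with pytest.raises(DataError, match="1"):
            sd.score_samples(model, cohort)

    def test_scoring_uses_shared_subset(self):
        model = self._model([1.0, 2.0, 3.0], ["a", "b", "c"])
        cohort = pd.DataFrame({"s": [1.0, 2.0, 99.0]}, index=["a", "b", "x"])
        assert sd.score_samples(model, cohort)["s"] == pytest.approx(1.0)


class TestRescaleAndSplit:
    def test_linear_map_endpoints(self):
        rho = pd.Series([0.2, 0.5, 0.8], index=list("abc"))
        out = sd.rescale_to_index(rho)
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_constant_scores_warn_and_zero(self):
        rho = pd.Series([0.3, 0.3, 0.3])
        with pytest.warns(UserWarning, match="degenerate"):
            out = sd.rescale_to_index(rho)
        assert (out == 0.0).all()

    def test_literal_divide_by_max_variant(self):
        rho = pd.Series([0.2, 0.5, 0.8])
        out = sd.rescale_to_index(rho, method="max")
        assert np.allclose(out, (rho - 0.2) / 0.8)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            sd.rescale_to_index(pd.Series(dtype=float))

    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_minmax_output_hits_both_endpoints(self, values):
        rho = pd.Series(values)
        if rho.nunique() == 1:
            with pytest.warns(UserWarning):
                out = sd.rescale_to_index(rho)
            assert (out == 0.0).all()
        else:
            out = sd.rescale_to_index(rho)
            assert out.min() == 0.0 and out.max() == 1.0
            assert out.between(0, 1).all()

    def test_purity_correction_cases(self):
        m = pd.Series([0.5, 0.0, 0.8], index=list("abc"))
        p = pd.Series([0.5, 0.9, 1.0], index=list("abc"))
        out = sd.correct_for_purity(m, p)
        assert np.allclose(out, [1.0, 0.0, 0.8])
        with pytest.raises(DataError):
            sd.correct_for_purity(m, pd.Series([0.5, -0.1, 1.0], index=list("abc")))
        with pytest.raises(DataError):
            sd.correct_for_purity(m, pd.Series([0.5, 1.1, 1.0], index=list("abc")))
        with pytest.warns(UserWarning, match="lack purity"):
            out = sd.correct_for_purity(m, pd.Series([0.5, np.nan, 1.0], index=list("abc")))
        assert list(out.index) == ["a", "c"]

    def test_median_split_basic_and_ties(self):
        assert list(sd.split_by_median(pd.Series([0.1, 0.2, 0.3, 0.4]))) == ["L", "L", "H", "H"]
        # ties at the median go to the high group
        assert list(sd.split_by_median(pd.Series([0.1, 0.2, 0.2, 0.9]))) == ["L", "H", "H", "H"]
        assert list(sd.split_by_median(pd.Series([0.5, 0.5, 0.5]))) == ["H", "H", "H"]
        with pytest.raises(DataError):
            sd.split_by_median(pd.Series([0.5]))


class TestCohortInvariants:
    def test_monotone_per_sample_transform_leaves_scores_identical(self, default_model, default_cohort):
        _, expr, _, clinical, _ = default_cohort
        expr = expr.iloc[:, :40]
        transformed = expr.copy()
        # different strictly increasing transform per sample
        for j, col in enumerate(transformed.columns):
            x = transformed[col]
            transformed[col] = [x * 2 + 1, np.exp(x / 10), x**3][j % 3]
        a = sd.score_samples(default_model, expr)
        b = sd.score_samples(default_model, transformed)
        assert (a == b).all()
        assert (sd.rescale_to_index(a) == sd.rescale_to_index(b)).all()
        assert (sd.split_by_median(a) == sd.split_by_median(b)).all()

    def test_sample_permutation_permutes_outputs(self, default_model, default_cohort):
        _, expr, _, _, _ = default_cohort
        expr = expr.iloc[:, :30]
        perm = expr.columns[::-1]
        a = sd.score_samples(default_model, expr)
        b = sd.score_samples(default_model, expr[perm])
        assert (b == a.loc[perm]).all()

    def test_recovery_of_planted_stemness(self, default_scored, default_cohort):
        from scipy.stats import spearmanr
        truth = default_cohort[4]
        rho = spearmanr(default_scored.mrnasi, truth.latent_stemness).statistic
        assert rho >= 0.9
        assert default_scored.mrnasi.min() == 0.0
        assert default_scored.mrnasi.max() == 1.0
        # corrected index is the elementwise quotient
        assert np.allclose(default_scored.corrected_mrnasi,
                           default_scored.mrnasi / default_scored.purity)
        assert set(default_scored.group) == {"H", "L"}
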