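"""Size factors, NB Wald test, moderated t, BH adjustment, DEG classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stemdex as sd
from stemdex.diffexpr import bh_adjust, classify_degs
from stemdex.exceptions import AnalysisError, DataError

from oracles import bh_oracle


def _nb_counts(rng, mu, size, shape):
    return rng.negative_binomial(size, size / (size + mu), size=shape)


def _two_group_counts(rng, n_genes, n_per_group, mu=100.0, dispersion_size=10.0,
                      fold=None, n_planted=0):
    """Null NB matrix with optionally the first n_planted genes at `fold` in L."""
    n = 2 * n_per_group
    mu_mat = np.full((n_genes, n), mu)
    if n_planted:
        mu_mat[:n_planted, n_per_group:] *= fold
    y = _nb_counts(rng, mu_mat, dispersion_size, (n_genes, n))
    counts = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(n)])
    groups = pd.Series(["H"] * n_per_group + ["L"] * n_per_group, index=counts.columns)
    return counts, groups


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(sd.size_factors(counts), 1.0)

    def test_doubled_sample_ratio_sqrt_two(self):
        counts = pd.DataFrame({"a": [10, 30, 50], "b": [20, 60, 100]})
        sf = sd.size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_single_gene_direct_formula(self):
        counts = pd.DataFrame({"a": [4], "b": [9]})
        sf = sd.size_factors(counts)
        # geometric mean 6: ratios 4/6 and 9/6
        assert sf["a"] == pytest.approx(4 / 6)
        assert sf["b"] == pytest.approx(9 / 6)

    def test_no_all_positive_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(DataError, match="pseudocount"):
            sd.size_factors(counts)


class TestBH:
    def test_equal_ladder_collapses_to_largest(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_nan_passthrough(self):
        p = pd.Series([0.01, np.nan, 0.04])
        out = bh_adjust(p)
        assert np.isnan(out.iloc[1])
        # NaNs do not count toward m
        assert np.allclose(out.dropna(), bh_oracle(np.array([0.01, 0.04])))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust(np.array([0.5, 1.5]))


class TestNBWald:
    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(11)
        counts, groups = _two_group_counts(rng, 1000, 30)
        table = sd.nb_wald_test(counts, groups)
        rate = (table["p_value"] < 0.05).mean()
        assert 0.02 < rate < 0.08

    def test_planted_fourfold_genes_recovered(self):
        rng = np.random.default_rng(12)
        counts, groups = _two_group_counts(rng, 600, 50, fold=4.0, n_planted=60)
        table = sd.nb_wald_test(counts, groups)
        hits = table.iloc[:60]
        recovered = ((hits["fdr"] < 0.05) & (hits["log2fc"].abs() > 1)).mean()
        assert recovered >= 0.9
        # planted genes are higher in L, so the convention calls them "up"
        assert (hits["direction"] == "up").mean() >= 0.9

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(13)
        counts, groups = _two_group_counts(rng, 100, 20, fold=3.0, n_planted=20)
        t1 = sd.nb_wald_test(counts, groups)
        swapped = groups.map({"H": "L", "L": "H"})
        t2 = sd.nb_wald_test(counts, swapped)
        assert np.allclose(t1["log2fc"], -t2["log2fc"], atol=1e-6)

    def test_doubling_all_counts_preserves_log2fc(self):
        rng = np.random.default_rng(14)
        counts, groups = _two_group_counts(rng, 200, 25, fold=3.0, n_planted=30)
        t1 = sd.nb_wald_test(counts, groups)
        t2 = sd.nb_wald_test(counts * 2, groups)
        assert np.abs(t1["log2fc"] - t2["log2fc"]).max() < 0.05

    def test_permuted_labels_lose_enrichment(self):
        rng = np.random.default_rng(15)
        counts, groups = _two_group_counts(rng, 400, 30, fold=4.0, n_planted=40)
        aligned = sd.nb_wald_test(counts, groups)
        perm = pd.Series(rng.permutation(groups.to_numpy()), index=groups.index)
        table = sd.nb_wald_test(counts, perm)
        called_before = (aligned.iloc[:40]["direction"] != "ns").mean()
        called_after = (table.iloc[:40]["direction"] != "ns").mean()
        assert called_before >= 0.9
        assert called_after <= 0.2  # planted genes no longer enriched among calls

    def test_all_zero_gene_gets_na(self):
        rng = np.random.default_rng(16)
        counts, groups = _two_group_counts(rng, 50, 10)
        counts.iloc[0] = 0
        table = sd.nb_wald_test(counts, groups, min_total_count=None)
        assert np.isnan(table.loc["g0", "p_value"])
        assert np.isnan(table.loc["g0", "fdr"])

    def test_prefilter_drops_low_count_genes(self):
        rng = np.random.default_rng(17)
        counts, groups = _two_group_counts(rng, 50, 10)
        counts.iloc[0] = 0
        counts.iloc[0, 0] = 3
        table = sd.nb_wald_test(counts, groups, min_total_count=10)
        assert "g0" not in table.index

    def test_bad_groups_rejected(self):
        rng = np.random.default_rng(18)
        counts, groups = _two_group_counts(rng, 20, 5)
        with pytest.raises(AnalysisError):
            sd.nb_wald_test(counts, groups.str.lower())

    def test_dispersion_moment_estimate_reasonable(self):
        rng = np.random.default_rng(19)
        counts, groups = _two_group_counts(rng, 2000, 50, dispersion_size=10.0)
        alpha = sd.estimate_dispersion(counts, groups)
        # true alpha = 1/size = 0.1
        assert 0.05 < alpha.median() < 0.2


class TestModeratedT:
    def _log_matrix(self, rng, n_genes=300, n=20, shift=0.0, n_planted=0, sdev=0.5):
        x = rng.normal(7.0, 1.0, (n_genes, 1)) + rng.normal(0, sdev, (n_genes, 2 * n))
        if n_planted:
            x[:n_planted, n:] += shift
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(2 * n)])
        groups = pd.Series(["H"] * n + ["L"] * n, index=df.columns)
        return df, groups

    def test_unmoderated_matches_plain_t(self):
        rng = np.random.default_rng(21)
        logexpr, groups = self._log_matrix(rng)
        table = sd.moderated_t_test(logexpr, groups, moderate=False)
        h = logexpr.loc[:, (groups == "H").to_numpy()]
        lo = logexpr.loc[:, (groups == "L").to_numpy()]
        ref = stats.ttest_ind(lo, h, axis=1, equal_var=True)
        assert np.abs(table["p_value"].to_numpy() - ref.pvalue).max() < 1e-10

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(22)
        logexpr, groups = self._log_matrix(rng, n_genes=2000)
        table = sd.moderated_t_test(logexpr, groups)
        ks = stats.kstest(table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_shift_power(self):
        rng = np.random.default_rng(23)
        logexpr, groups = self._log_matrix(rng, n_genes=500, n=20, shift=2.0,
                                           n_planted=50, sdev=0.5)
        table = sd.moderated_t_test(logexpr, groups)
        hits = table.iloc[:50]
        assert ((hits["fdr"] < 0.05) & (hits["log2fc"] > 1)).mean() >= 0.95

    def test_zero_variance_gene_survives_moderation(self):
        rng = np.random.default_rng(24)
        logexpr, groups = self._log_matrix(rng, n_genes=50)
        logexpr.iloc[0] = 5.0  # no variance at all
        table = sd.moderated_t_test(logexpr, groups)
        assert np.isfinite(table["p_value"].drop("g0")).all()
        assert not np.isnan(table.loc["g0", "p_value"])


class TestClassify:
    def _table(self, log2fc, fdr):
        return pd.DataFrame({"log2fc": log2fc, "p_value": fdr, "fdr": fdr})

    def test_boundaries_are_strict(self):
        table = classify_degs(self._table([1.0, 2.0, 2.0, -2.0],
                                          [0.01, 0.05, 0.01, 0.01]))
        assert list(table["direction"]) == ["ns", "ns", "up", "down"]

    def test_empty_table_zero_counts(self):
        table = classify_degs(self._table([], []))
        assert table.attrs["n_up"] == 0 and table.attrs["n_down"] == 0
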