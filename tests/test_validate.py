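import numpy as np
import pandas as pd
import pytest

from epidomain.domains import DomainCall, segment
from epidomain.validate import (
    expression_z,
    fleiss_kappa,
    go_accordance_test,
    random_neighbor_sets,
    within_domain_variance_test,
)


def _sig_domains(windows):
    calls = []
    for i, (a, b) in enumerate(windows):
        c = DomainCall(i, "chr1", a, b - 1, 0, "active")
        c.significant = True
        calls.append(c)
    return calls


class TestRandomNeighborSets:
    def test_deterministic_given_seed(self):
        breaks = np.array([0, 50])
        a = random_neighbor_sets(breaks, 100, [3, 7], B=20, seed=4)
        b = random_neighbor_sets(breaks, 100, [3, 7], B=20, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_windows_are_contiguous_and_within_chains(self):
        breaks = np.array([0, 40])
        wins = random_neighbor_sets(breaks, 100, [5], B=200, seed=0)
        for (a, b) in wins[:, 0, :]:
            assert b - a == 5
            assert (a >= 0 and b <= 40) or (a >= 40 and b <= 100)

    def test_start_distribution_uniform(self):
        wins = random_neighbor_sets(np.array([0]), 20, [1], B=6000, seed=1)
        counts = np.bincount(wins[:, 0, 0], minlength=20)
        # each of 20 starts expected 300 times; 5 sigma band
        assert counts.min() > 300 - 5 * np.sqrt(300)
        assert counts.max() < 300 + 5 * np.sqrt(300)

    def test_oversized_window_raises(self):
        with pytest.raises(ValueError, match="no chromosome"):
            random_neighbor_sets(np.array([0, 10]), 20, [15], B=5, seed=0)


class TestVarianceTest:
    def test_hand_computed_observed_statistic(self):
        values = np.array([1.0, 3.0, 2.0, 2.0, 5.0])
        calls = _sig_domains([(0, 2), (2, 4)])
        res = within_domain_variance_test(calls, values, np.array([0]), B=50, seed=0)[0]
        # var([1,3]) = 2, var([2,2]) = 0 -> mean 1 (unbiased estimator)
        assert res.observed == pytest.approx(1.0)
        assert res.direction == "less"

    def test_constant_values_hit_p_floor(self):
        values = np.zeros(60)
        # constant data: every window variance is 0 == observed, count = B
        calls = _sig_domains([(0, 4), (10, 13)])
        res = within_domain_variance_test(calls, values, np.array([0]), B=100, seed=1)[0]
        assert res.observed == 0.0
        assert res.p_value == 1.0  # all null values tie the observed

    def test_minimum_p_is_one_over_B(self):
        rng = np.random.default_rng(2)
        n = 300
        values = rng.normal(size=n)
        # make two domains nearly constant -> observed variance far below null
        values[10:20] = 0.001 * rng.normal(size=10)
        values[100:110] = 0.001 * rng.normal(size=10)
        calls = _sig_domains([(10, 20), (100, 110)])
        B = 200
        res = within_domain_variance_test(calls, values, np.array([0]), B=B, seed=3)[0]
        assert res.p_value == pytest.approx(1.0 / B)

    def test_calibration_on_unstructured_data(self):
        """Domains placed arbitrarily on exchangeable data give unremarkable
        p-values (median across seeds well inside (0, 1))."""
        pvals = []
        for seed in range(9):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=200)
            calls = _sig_domains([(5, 10), (50, 58), (120, 124)])
            res = within_domain_variance_test(calls, values, np.array([0]),
                                              B=200, seed=seed)[0]
            pvals.append(res.p_value)
        assert 0.1 <= np.median(pvals) <= 0.9

    def test_multicolumn_values_give_one_result_per_mark(self):
        rng = np.random.default_rng(4)
        V = rng.normal(size=(100, 3))
        calls = _sig_domains([(0, 5), (40, 44)])
        results = within_domain_variance_test(calls, V, np.array([0]), B=20,
                                              seed=0, names=["a", "b", "c"])
        assert [r.name for r in results] == ["a", "b", "c"]

    def test_no_evaluable_domain_raises(self):
        calls = _sig_domains([(0, 1)])  # singleton only
        with pytest.raises(ValueError):
            within_domain_variance_test(calls, np.zeros(10), np.array([0]), B=10)


class TestExpressionZ:
    def test_focal_at_row_mean_gives_zero(self):
        df = pd.DataFrame({"ES": [2.0], "a": [1.0], "b": [3.0]}, index=["g1"])
        assert expression_z(df, "ES")["g1"] == pytest.approx(0.0)

    def test_two_line_closed_form(self):
        df = pd.DataFrame({"ES": [0.0], "other": [2.0]}, index=["g1"])
        # mean 1, unbiased sd sqrt(2): z = -1/sqrt(2)
        assert expression_z(df, "ES")["g1"] == pytest.approx(-1 / np.sqrt(2))

    def test_matrix_matches_per_row_loop(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 6)),
                          columns=["ES"] + [f"l{i}" for i in range(5)],
                          index=[f"g{i}" for i in range(30)])
        z = expression_z(df, "ES")
        for g in df.index:
            row = df.loc[g]
            expected = (row["ES"] - row.mean()) / row.std(ddof=1)
            assert z[g] == pytest.approx(expected)

    def test_zero_sd_gene_dropped(self):
        df = pd.DataFrame({"ES": [1.0, 1.0], "a": [1.0, 2.0], "b": [1.0, 3.0]},
                          index=["flat", "ok"])
        z = expression_z(df, "ES")
        assert "flat" not in z.index and "ok" in z.index


class TestFleissKappa:
    def test_perfect_agreement_gives_one(self):
        table = np.array([[5, 0], [0, 5], [5, 0], [0, 5]])
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_single_category_raises(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[4, 0], [4, 0]]))

    def test_unequal_rater_counts_raise(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[3, 1], [2, 1]]))

    def test_random_marginal_ratings_give_near_zero_kappa(self):
        rng = np.random.default_rng(6)
        kappas = []
        for _ in range(300):
            ratings = rng.choice(3, size=(30, 6), p=[0.5, 0.3, 0.2])
            table = np.stack([(ratings == c).sum(axis=1) for c in range(3)], axis=1)
            kappas.append(fleiss_kappa(table))
        assert abs(np.mean(kappas)) < 0.02

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        rng = np.random.default_rng(seed)
        for _ in range(5):
            n_subjects = int(rng.integers(4, 12))
            n_cat = int(rng.integers(2, 5))
            n_raters = int(rng.integers(2, 8))
            table = rng.multinomial(n_raters, rng.dirichlet(np.ones(n_cat)),
                                    size=n_subjects)
            if np.isclose(np.sum((table.sum(0) / table.sum()) ** 2), 1.0):
                continue
            assert fleiss_kappa(table) == pytest.approx(
                sm_kappa(table, method="fleiss"), abs=1e-12
            )


class TestGOAccordance:
    def _setup(self, rng, n=200, shared=True):
        gene_ids = [f"g{i}" for i in range(n)]
        vocab = [f"GO:{i:07d}" for i in range(12)]
        path = np.repeat(rng.integers(0, 3, size=n // 8), 8)[:n]
        calls = [c for c in segment(path) if c.n_genes >= 3]
        for c in calls:
            c.significant = True
        go = {}
        for c in calls:
            terms = frozenset(rng.choice(vocab, size=3, replace=False))
            for i in range(c.start_gene_index, c.end_gene_index + 1):
                if shared:
                    go[gene_ids[i]] = terms
                else:
                    go[gene_ids[i]] = frozenset(rng.choice(vocab, size=3, replace=False))
        return gene_ids, vocab, calls, go

    def test_domain_shared_go_hits_p_floor(self):
        rng = np.random.default_rng(7)
        gene_ids, vocab, calls, go = self._setup(rng, shared=True)
        B = 100
        res = go_accordance_test(calls, go, gene_ids, np.array([0]), vocab, B=B, seed=0)
        assert res.direction == "greater"
        assert res.p_value == pytest.approx(1.0 / B)

    def test_positionally_random_go_is_uncalibrated_small(self):
        pvals = []
        for seed in range(6):
            rng = np.random.default_rng(seed + 100)
            gene_ids, vocab, calls, go = self._setup(rng, shared=False)
            res = go_accordance_test(calls, go, gene_ids, np.array([0]), vocab,
                                     B=100, seed=seed)
            pvals.append(res.p_value)
        assert max(pvals) > 0.05  # not systematically at the floor

    def test_observed_mean_matches_stored_per_domain_recomputation(self):
        from epidomain.validate import _window_kappa

        rng = np.random.default_rng(8)
        gene_ids, vocab, calls, go = self._setup(rng, shared=True)
        res = go_accordance_test(calls, go, gene_ids, np.array([0]), vocab, B=10, seed=0)
        ys = [
            _window_kappa(gene_ids, (c.start_gene_index, c.end_gene_index + 1), go, vocab)
            for c in calls
        ]
        assert res.observed == pytest.approx(np.nanmean(ys))
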