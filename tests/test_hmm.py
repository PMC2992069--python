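import numpy as np
import pytest
from scipy.stats import multivariate_normal

from epidomain.cluster import kmeans_fit
from epidomain.hmm import (
    HMMParams,
    PriorHyperparams,
    decode,
    decode_agreement,
    em_fit,
    emission_logdensity,
    forward_backward,
    init_from_clusters,
    init_from_prior,
    viterbi,
    assign_state_labels,
)
from epidomain.simulate import reference_params, simulate_scores

from conftest import enumerate_paths, random_hmm_params


class TestEmissionDensity:
    def test_standard_normal_at_mean(self):
        params = HMMParams([[0.0]], [[1.0]], [[1.0]], [1.0])
        assert emission_logdensity([0.0], 0, params) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_independent_dims_sum(self):
        params = HMMParams([[1.0, -2.0]], [[0.5, 2.0]], [[1.0]], [1.0])
        lp = emission_logdensity([0.3, 0.7], 0, params)
        one_d = sum(
            emission_logdensity([x], 0, HMMParams([[m]], [[v]], [[1.0]], [1.0]))
            for x, m, v in [(0.3, 1.0, 0.5), (0.7, -2.0, 2.0)]
        )
        assert lp == pytest.approx(one_d)

    def test_matches_scipy_diagonal_mvn(self):
        rng = np.random.default_rng(0)
        params = random_hmm_params(rng, S=3, m=4)
        for s in range(3):
            x = rng.normal(size=4)
            ref = multivariate_normal.logpdf(
                x, mean=params.means[s], cov=np.diag(params.variances[s])
            )
            assert emission_logdensity(x, s, params) == pytest.approx(ref)

    def test_non_finite_input_raises(self):
        params = HMMParams([[0.0]], [[1.0]], [[1.0]], [1.0])
        with pytest.raises(ValueError):
            emission_logdensity([np.nan], 0, params)


class TestInitialization:
    def test_cluster_init_copies_means_and_occupancy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(8, 1, (75, 2))])
        km = kmeans_fit(X, K=2, seed=0)
        init = init_from_clusters(km)
        np.testing.assert_allclose(init.means, km.centers)
        np.testing.assert_allclose(sorted(init.initial), [0.25, 0.75], atol=0.02)
        np.testing.assert_allclose(init.transition.sum(axis=1), 1.0)
        assert init.transition[0, 0] == pytest.approx(0.9)

    def test_prior_init_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(2.0, 1.5, size=(200, 3))
        a = init_from_prior(X, S=3, seed=5)
        b = init_from_prior(X, S=3, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.variances, b.variances)

    def test_prior_draws_match_hyperparameters_in_expectation(self):
        """Monte-Carlo oracle: prior variance draws average to s2, means to
        theta."""
        hyper = PriorHyperparams(theta=[3.0], s2=[2.5], nu=[10.0])
        X = np.zeros((5, 1))  # unused when hyper is supplied
        draws_v, draws_m = [], []
        for seed in range(2500):
            p = init_from_prior(X, S=4, hyper=hyper, seed=seed)
            draws_v.append(p.variances.ravel())
            draws_m.append(p.means.ravel())
        mean_v = np.concatenate(draws_v).mean()
        mean_m = np.concatenate(draws_m).mean()
        assert mean_v == pytest.approx(2.5, rel=0.05)
        assert mean_m == pytest.approx(3.0, abs=3 * np.sqrt(2.5 / 10_000))

    def test_prior_rejects_low_nu(self):
        with pytest.raises(ValueError):
            PriorHyperparams(theta=[0.0], s2=[1.0], nu=[2.0])


class TestEMFit:
    def test_single_state_recovers_sample_moments(self):
        rng = np.random.default_rng(3)
        X = rng.normal(1.5, 2.0, size=(300, 2))
        init = HMMParams([[0.0, 0.0]], [[1.0, 1.0]], [[1.0]], [1.0])
        fitted, trace = em_fit(X, init, tol=1e-10, max_iter=5)
        np.testing.assert_allclose(fitted.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(fitted.variances[0], X.var(axis=0), atol=1e-8)

    def test_loglik_trace_monotone_across_random_datasets(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gen = random_hmm_params(rng, S=2, m=2)
            truth = simulate_scores(gen, 150, mean_domain_len=6.0, seed=seed)
            init = random_hmm_params(np.random.default_rng(seed + 1000), S=2, m=2)
            _, trace = em_fit(truth.scores, init, tol=1e-6, max_iter=40)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_short_chain_skipped_with_warning(self):
        from epidomain.scores import GeneScoreMatrix

        rng = np.random.default_rng(4)
        matrix = GeneScoreMatrix(
            gene_ids=[f"g{i}" for i in range(11)],
            marks=["a"],
            scores=rng.normal(size=(11, 1)),
            chrom_breaks=np.array([0, 10]),  # second chain has 1 gene
        )
        init = HMMParams([[0.0]], [[1.0]], [[1.0]], [1.0])
        with pytest.warns(UserWarning, match="skipping chain"):
            em_fit(matrix, init, tol=1e-6, max_iter=3)

    def test_cluster_init_beats_random_prior_inits(self):
        """On reference-parameter data, cluster-based initialisation reaches a
        final log-likelihood at least as high as the best of random
        semi-conjugate prior initialisations (run at reduced scale)."""
        gen = reference_params(3)
        truth = simulate_scores(gen, 800, mean_domain_len=10.0, seed=0)
        km = kmeans_fit(truth.scores, K=3, seed=0)
        _, trace_c = em_fit(truth.scores, init_from_clusters(km), tol=1e-4, max_iter=200)
        best_prior = -np.inf
        for seed in range(10):
            init = init_from_prior(truth.scores, S=3, seed=seed)
            _, trace_p = em_fit(truth.scores, init, tol=1e-4, max_iter=200)
            best_prior = max(best_prior, trace_p[-1])
        assert trace_c[-1] >= best_prior - 1e-6


class TestDecoders:
    @pytest.mark.parametrize("seed", range(12))
    def test_viterbi_and_posteriors_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(2, 4))
        n = int(rng.integers(3, 9))
        params = random_hmm_params(rng, S=S, m=2)
        X = rng.normal(size=(n, 2))
        paths, logps = enumerate_paths(X, params)

        best = paths[int(np.argmax(logps))]
        assert tuple(viterbi(X, params)) == best

        total = np.logaddexp.reduce(logps)
        post_ref = np.zeros((n, S))
        for path, lp in zip(paths, logps):
            for t, s in enumerate(path):
                post_ref[t, s] += np.exp(lp - total)
        post, loglik = forward_backward(X, params)
        np.testing.assert_allclose(post, post_ref, atol=1e-9)
        assert loglik == pytest.approx(total)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        params = random_hmm_params(rng, S=3, m=3)
        X = rng.normal(size=(500, 3))
        post, _ = forward_backward(X, params)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_path_is_constant(self):
        params = HMMParams([[0.0]], [[1.0]], [[1.0]], [1.0])
        assert set(viterbi(np.random.default_rng(0).normal(size=(20, 1)), params)) == {0}

    def test_noiseless_two_state_data_decoded_exactly(self):
        gen = reference_params(2)
        truth = simulate_scores(gen, 400, mean_domain_len=10.0,
                                variance_multiplier=1e-8, seed=2)
        path = viterbi(truth.scores, gen)
        np.testing.assert_array_equal(path, truth.true_states)

    def test_loglik_invariant_to_state_relabeling(self):
        rng = np.random.default_rng(5)
        params = random_hmm_params(rng, S=3, m=2)
        X = rng.normal(size=(60, 2))
        _, ll = forward_backward(X, params)
        perm = [2, 0, 1]
        relabeled = HMMParams(
            means=params.means[perm],
            variances=params.variances[perm],
            transition=params.transition[np.ix_(perm, perm)],
            initial=params.initial[perm],
        )
        _, ll2 = forward_backward(X, relabeled)
        assert ll2 == pytest.approx(ll)

    def test_chains_decoded_independently(self):
        """Splitting the data at a chain break must equal decoding the two
        chains separately."""
        from epidomain.scores import GeneScoreMatrix

        rng = np.random.default_rng(6)
        params = random_hmm_params(rng, S=2, m=2)
        X = rng.normal(size=(40, 2))
        joint = GeneScoreMatrix([f"g{i}" for i in range(40)], ["a", "b"], X,
                                np.array([0, 25]))
        path = viterbi(joint, params)
        np.testing.assert_array_equal(path[:25], viterbi(X[:25], params))
        np.testing.assert_array_equal(path[25:], viterbi(X[25:], params))

    def test_decode_agreement_arithmetic(self):
        a = np.zeros(500, dtype=int)
        b = a.copy()
        assert decode_agreement(a, b) == 1.0
        b[123] = 1
        assert decode_agreement(a, b) == pytest.approx(0.998)
        with pytest.raises(ValueError):
            decode_agreement(a, a[:10])

    def test_viterbi_map_agreement_high_on_reference_data(self):
        gen = reference_params(3)
        truth = simulate_scores(gen, 2000, mean_domain_len=10.0, seed=3)
        dec = decode(truth.scores, gen)
        assert decode_agreement(dec.viterbi_path, dec.map_path) >= 0.95


def test_matches_hmmlearn_reference_implementation():
    """Independent cross-check: loglik and Viterbi path agree with hmmlearn's
    diagonal-covariance GaussianHMM under identical fixed parameters."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(8)
    params = random_hmm_params(rng, S=3, m=2)
    X = rng.normal(size=(300, 2))
    ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
    ref.startprob_ = params.initial
    ref.transmat_ = params.transition
    ref.means_ = params.means
    ref.covars_ = params.variances
    ll_ref, path_ref = ref.decode(X, algorithm="viterbi")
    assert tuple(viterbi(X, params)) == tuple(path_ref)
    _, ll = forward_backward(X, params)
    assert ll == pytest.approx(ref.score(X))


def test_state_label_assignment_on_reference_params():
    params = reference_params(3)
    relabeled = assign_state_labels(
        HMMParams(params.means, params.variances, params.transition,
                  params.initial, marks=params.marks)
    )
    assert relabeled.state_labels == ["non-active", "null", "active"]
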