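"""Exact-inference checks: forward-backward and Viterbi against exhaustive
path enumeration, plus structural special cases."""

import itertools

import numpy as np
import pytest

import nighthmm as nh
from nighthmm.exceptions import ParameterError
from nighthmm.hmm import _gauss_logpdf


def enumerate_paths(pi, A, logB):
    """Brute-force posterior quantities by summing over all K^T paths."""
    T, K = logB.shape
    log_joint = {}
    total = -np.inf
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        log_joint[path] = lp
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    for path, lp in log_joint.items():
        w = np.exp(lp - total)
        for t, s in enumerate(path):
            gamma[t, s] += w
        for t in range(1, T):
            xi[path[t - 1], path[t]] += w
    return gamma, xi, total, best_path


def random_point_model(rng, K, D=2):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    means = rng.normal(0, 2, (K, D))
    covs = np.stack([np.diag(rng.uniform(0.5, 2, D)) for _ in range(K)])
    return nh.HmmModel.from_point_estimates(pi, A, means, covs)


class TestEnumerationOracle:
    @pytest.mark.parametrize("trial", range(20))
    def test_gamma_xi_evidence_viterbi_match_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        T = int(rng.integers(2, 7))
        K = int(rng.integers(1, 4))
        model = random_point_model(rng, K)
        X = rng.normal(0, 1.5, (T, model.D))
        post = nh.forward_backward(X, model)
        vit = nh.viterbi_decode(X, model)
        logB = np.column_stack(
            [_gauss_logpdf(X, model.means[k], model.covs[k]) for k in range(K)]
        )
        g, xi, total, best = enumerate_paths(model.pi, model.A, logB)
        assert np.allclose(post.gamma, g, atol=1e-10)
        assert np.allclose(post.xi[0], xi, atol=1e-10)
        assert np.isclose(post.loglik[0], total, atol=1e-10)
        assert tuple(vit) == best

    def test_segments_break_transitions(self):
        """Two segments behave as two independent chains from pi."""
        rng = np.random.default_rng(5)
        model = random_point_model(rng, 2)
        X = rng.normal(size=(6, 2))
        both = nh.forward_backward(X, model, segments=[(0, 3), (3, 6)])
        first = nh.forward_backward(X[:3], model)
        second = nh.forward_backward(X[3:], model)
        assert np.allclose(both.gamma[:3], first.gamma, atol=1e-12)
        assert np.allclose(both.gamma[3:], second.gamma, atol=1e-12)
        assert np.isclose(both.loglik.sum(),
                          first.loglik[0] + second.loglik[0], atol=1e-10)


class TestIndependentReference:
    def test_loglik_and_posteriors_match_hmmlearn(self):
        """Fixed-parameter inference agrees with an independent HMM library."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        K, D, T = 3, 2, 40
        model = random_point_model(rng, K, D)
        X = rng.normal(0, 1.5, (T, D))
        ref = hmmlearn.GaussianHMM(n_components=K, covariance_type="full",
                                   init_params="", params="")
        ref.startprob_ = model.pi
        ref.transmat_ = model.A
        ref.means_ = model.means
        ref.covars_ = model.covs
        post = nh.forward_backward(X, model)
        assert np.isclose(post.loglik[0], ref.score(X), atol=1e-8)
        assert np.allclose(post.gamma, ref.predict_proba(X), atol=1e-8)
        assert np.array_equal(nh.viterbi_decode(X, model), ref.predict(X))


class TestSpecialCases:
    def test_single_state_gamma_is_one(self):
        model = nh.HmmModel.from_point_estimates(
            [1.0], [[1.0]], [[0.0, 0.0]], [np.eye(2)])
        X = np.random.default_rng(0).normal(size=(10, 2))
        post = nh.forward_backward(X, model)
        assert np.allclose(post.gamma, 1.0)
        expected = _gauss_logpdf(X, model.means[0], model.covs[0]).sum()
        assert np.isclose(post.loglik[0], expected, atol=1e-10)

    def test_identical_emissions_uniform_gamma(self):
        K = 3
        means = np.zeros((K, 2))
        covs = np.stack([np.eye(2)] * K)
        model = nh.HmmModel.from_point_estimates(
            np.full(K, 1 / K), np.full((K, K), 1 / K), means, covs)
        X = np.random.default_rng(1).normal(size=(8, 2))
        post = nh.forward_backward(X, model)
        assert np.allclose(post.gamma, 1 / K, atol=1e-12)

    def test_near_deterministic_emissions_recover_path(self):
        rng = np.random.default_rng(2)
        means = np.array([[-5.0, -5.0], [5.0, 5.0]])
        covs = np.stack([np.eye(2) * 1e-3] * 2)
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = nh.HmmModel.from_point_estimates([0.5, 0.5], A, means, covs)
        true = rng.integers(0, 2, 30)
        X = means[true] + rng.normal(0, 0.01, (30, 2))
        assert np.array_equal(nh.viterbi_decode(X, model), true)

    def test_nonfinite_observation_rejected(self):
        model = random_point_model(np.random.default_rng(3), 2)
        X = np.zeros((4, 2))
        X[1, 0] = np.nan
        with pytest.raises(ParameterError):
            nh.forward_backward(X, model)

    def test_gamma_rows_normalized(self, trained):
        gamma = trained["fit"].posteriors.gamma
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_decode_modes(self, trained):
        scores = trained["scores"][:200]
        post = nh.decode(scores, trained["fit"].model, mode="posterior")
        vit = nh.decode(scores, trained["fit"].model, mode="viterbi")
        assert post.gamma.shape == (200, 6)
        assert vit.shape == (200,)
        with pytest.raises(ParameterError):
            nh.decode(scores, trained["fit"].model, mode="nope")
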