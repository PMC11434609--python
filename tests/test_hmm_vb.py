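"""Variational updates and free energy: conjugate-evidence oracle,
monotonicity, permutation invariance, degenerate cases."""

import numpy as np
import pytest
from scipy.special import multigammaln

import nighthmm as nh
from nighthmm.exceptions import ParameterError
from nighthmm.hmm import (
    HmmModel,
    StatePosteriors,
    default_priors,
    forward_backward,
    free_energy,
    vb_update,
)


def analytic_log_marginal(X, nw):
    """Closed-form Normal-Wishart-Gaussian log marginal likelihood."""
    N, D = X.shape
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    T0 = np.linalg.inv(nw.W0)
    dm = (xbar - nw.m0)[:, None]
    TN = T0 + S + nw.beta0 * N / (nw.beta0 + N) * (dm @ dm.T)
    nuN, betaN = nw.nu0 + N, nw.beta0 + N
    return (
        -N * D / 2 * np.log(np.pi)
        + multigammaln(nuN / 2, D) - multigammaln(nw.nu0 / 2, D)
        + nw.nu0 / 2 * np.linalg.slogdet(T0)[1]
        - nuN / 2 * np.linalg.slogdet(TN)[1]
        + D / 2 * np.log(nw.beta0 / betaN)
    )


class TestFreeEnergy:
    def test_single_state_matches_conjugate_evidence(self):
        """For K=1 the converged bound is tight: F = -log p(X)."""
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 1.5, size=(200, 3))
        res = nh.fit(X, 1, n_restarts=1, seed=0, max_iter=300, tol=1e-12)
        _, _, nw = default_priors(X, 1)
        assert np.isclose(res.free_energy, -analytic_log_marginal(X, nw),
                          atol=1e-6)

    def test_prior_posterior_zero_data_gives_zero(self):
        D, K = 2, 2
        pi0, A0, nw = default_priors(np.random.default_rng(1).normal(size=(10, D)), K)
        model = HmmModel(
            K=K, D=D, prior_pi_conc=pi0, prior_A_conc=A0, nw_prior=nw,
            post_pi_conc=pi0.copy(), post_A_conc=A0.copy(),
            post_m=np.tile(nw.m0, (K, 1)), post_beta=np.full(K, nw.beta0),
            post_W=np.tile(nw.W0, (K, 1, 1)), post_nu=np.full(K, nw.nu0),
        )
        empty = StatePosteriors(gamma=np.zeros((0, K)), xi=np.zeros((0, K, K)),
                                loglik=np.zeros(0))
        assert abs(free_energy(empty, model)) < 1e-10

    @pytest.mark.parametrize("trial", range(20))
    def test_nonincreasing_over_iterations(self, trial):
        rng = np.random.default_rng(200 + trial)
        K = int(rng.integers(1, 4))
        X = rng.normal(0, 1, size=(60, 2)) + rng.integers(0, 2, size=(60, 1)) * 2
        res = nh.fit(X, K, n_restarts=1, seed=trial, max_iter=40, tol=1e-12)
        assert np.all(np.diff(res.free_energy_trace) <= 1e-8)

    def test_permutation_invariance(self, trained):
        """Relabeling the states leaves the bound unchanged."""
        model = trained["fit"].model
        X = trained["scores"]
        segs = trained["concat"].segments
        perm = np.array([3, 0, 5, 1, 4, 2])
        permuted = HmmModel(
            K=model.K, D=model.D,
            prior_pi_conc=model.prior_pi_conc[perm],
            prior_A_conc=model.prior_A_conc[np.ix_(perm, perm)],
            nw_prior=model.nw_prior,
            post_pi_conc=model.post_pi_conc[perm],
            post_A_conc=model.post_A_conc[np.ix_(perm, perm)],
            post_m=model.post_m[perm], post_beta=model.post_beta[perm],
            post_W=model.post_W[perm], post_nu=model.post_nu[perm],
        )
        f0 = free_energy(forward_backward(X, model, segs), model)
        f1 = free_energy(forward_backward(X, permuted, segs), permuted)
        assert np.isclose(f0, f1, atol=1e-10 * max(1, abs(f0)))


class TestVbUpdate:
    def test_onehot_gamma_small_beta0_recovers_weighted_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(3.0, 1.0, size=(50, 2))
        pi0, A0, nw = default_priors(X, 1)
        nw.beta0 = 1e-10
        model = HmmModel(
            K=1, D=2, prior_pi_conc=pi0, prior_A_conc=A0, nw_prior=nw,
            post_pi_conc=pi0.copy(), post_A_conc=A0.copy(),
            post_m=np.tile(nw.m0, (1, 1)), post_beta=np.full(1, nw.beta0),
            post_W=np.tile(nw.W0, (1, 1, 1)), post_nu=np.full(1, nw.nu0),
        )
        gamma = np.ones((50, 1))
        post = StatePosteriors(gamma=gamma, xi=np.zeros((1, 1, 1)),
                               loglik=np.zeros(1))
        updated = vb_update(X, post, model)
        assert np.allclose(updated.post_m[0], X.mean(axis=0), atol=1e-8)

    def test_mirrored_assignments_give_mirrored_posteriors(self):
        rng = np.random.default_rng(3)
        half = rng.normal(2.0, 1.0, size=(40, 2))
        X = np.vstack([half, -half])
        pi0, A0, nw = default_priors(X, 2)
        nw.m0 = np.zeros(2)  # symmetric prior location
        model = HmmModel(
            K=2, D=2, prior_pi_conc=pi0, prior_A_conc=A0, nw_prior=nw,
            post_pi_conc=pi0.copy(), post_A_conc=A0.copy(),
            post_m=np.zeros((2, 2)), post_beta=np.full(2, nw.beta0),
            post_W=np.tile(nw.W0, (2, 1, 1)), post_nu=np.full(2, nw.nu0),
        )
        gamma = np.zeros((80, 2))
        gamma[:40, 0] = 1.0
        gamma[40:, 1] = 1.0
        post = StatePosteriors(gamma=gamma, xi=np.zeros((1, 2, 2)),
                               loglik=np.zeros(1))
        updated = vb_update(X, post, model)
        assert np.allclose(updated.post_m[0], -updated.post_m[1], atol=1e-10)
        assert np.allclose(updated.post_W[0], updated.post_W[1], atol=1e-10)

    def test_empty_state_keeps_prior(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        model = nh.init_model(X, 2, seed=0)
        gamma = np.zeros((30, 2))
        gamma[:, 0] = 1.0  # state 1 never used
        post = StatePosteriors(gamma=gamma, xi=np.zeros((1, 2, 2)),
                               loglik=np.zeros(1))
        updated = vb_update(X, post, model)
        nw = model.nw_prior
        assert np.allclose(updated.post_m[1], nw.m0)
        assert updated.post_nu[1] == nw.nu0

    def test_transition_rows_stay_stochastic(self, trained):
        A = trained["fit"].model.A
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-10)
        assert (A >= 0).all()


class TestInitModel:
    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 3))
        a = nh.init_model(X, 3, seed=7)
        b = nh.init_model(X, 3, seed=7)
        assert np.array_equal(a.post_m, b.post_m)
        assert np.array_equal(a.post_A_conc, b.post_A_conc)

    def test_single_state_mean_is_data_mean(self):
        rng = np.random.default_rng(6)
        X = rng.normal(5.0, 1.0, size=(100, 2))
        model = nh.init_model(X, 1, seed=0)
        # beta0=1 shrinks slightly toward the prior mean (the data mean), so
        # the posterior location equals the data mean here
        assert np.allclose(model.post_m[0], X.mean(axis=0), atol=1e-8)

    def test_separated_clusters_found(self):
        rng = np.random.default_rng(7)
        centers = np.array([[-6, 0], [0, 6], [6, 0]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.5, size=(60, 2)) for c in centers])
        model = nh.init_model(X, 3, seed=0)
        from scipy.optimize import linear_sum_assignment
        d = np.linalg.norm(model.post_m[:, None] - centers[None], axis=2)
        r, c = linear_sum_assignment(d)
        assert (d[r, c] < 0.5).all()

    def test_k_exceeding_frames_raises(self):
        with pytest.raises(ParameterError):
            nh.init_model(np.zeros((3, 2)), 5, seed=0)


class TestSerialization:
    def test_model_json_roundtrip(self, trained):
        from nighthmm.hmm import model_from_json, model_to_json
        model = trained["fit"].model
        back, h = model_from_json(model_to_json(model, pca_hash="abc"))
        assert h == "abc"
        assert np.allclose(back.A, model.A, atol=1e-15)
        assert np.allclose(back.post_W, model.post_W, atol=1e-15)
        X = trained["scores"][:50]
        assert np.allclose(
            forward_backward(X, back).gamma,
            forward_backward(X, model).gamma, atol=1e-12)
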