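"""Back-projection, relative activation, FC and network aggregation."""

import numpy as np
import pytest

import nighthmm as nh
from nighthmm.exceptions import ParameterError
from nighthmm.io_preprocess import PcaModel


def identity_pca(R):
    return PcaModel(mixing=np.eye(R), component_variances=np.ones(R),
                    total_variance=float(R), n_components=R,
                    channel_means=np.zeros(R))


class TestProjectToRoi:
    def test_identity_mixing_returns_parameters(self, trained):
        model = trained["fit"].model
        pca = identity_pca(model.D)
        means, covs = nh.project_to_roi(model, pca)
        assert np.allclose(means, model.means)
        assert np.allclose(covs, model.covs)

    def test_zero_mean_returns_channel_means(self):
        rng = np.random.default_rng(0)
        R, D = 6, 3
        M, _ = np.linalg.qr(rng.standard_normal((R, D)))
        pca = PcaModel(mixing=M[:, :D], component_variances=np.ones(D),
                       total_variance=6.0, n_components=D,
                       channel_means=rng.normal(size=R))
        model = nh.HmmModel.from_point_estimates(
            [1.0], [[1.0]], np.zeros((1, D)), np.eye(D)[None])
        means, _ = nh.project_to_roi(model, pca)
        assert np.allclose(means[0], pca.channel_means)

    def test_roundtrip_is_subspace_projection(self, trained):
        """Project truth into PC space and back: equals the truth's
        orthogonal projection onto the PC subspace."""
        pca = trained["pca"]
        v = (trained["model_true"].means[0] - trained["raw_mean"]) / trained["raw_sd"]
        coords = pca.transform(v[None])[0]
        back = pca.mixing @ coords + pca.channel_means
        proj = pca.mixing @ (pca.mixing.T @ (v - pca.channel_means)) + pca.channel_means
        assert np.allclose(back, proj, atol=1e-10)

    def test_projected_covariance_psd(self, trained):
        _, covs = nh.project_to_roi(trained["fit"].model, trained["pca"])
        for C in covs:
            assert np.linalg.eigvalsh(C).min() >= -1e-8

    def test_dimension_mismatch_raises(self, trained):
        with pytest.raises(ParameterError):
            nh.project_to_roi(trained["fit"].model, identity_pca(7))


class TestRelativeActivation:
    def test_identical_states_zero_maps(self):
        X = np.tile(np.arange(4.0), (3, 1))
        assert np.allclose(nh.relative_activation(X), 0.0)

    def test_column_sums_zero(self):
        rng = np.random.default_rng(1)
        rel = nh.relative_activation(rng.normal(size=(5, 8)))
        assert np.allclose(rel.sum(axis=0), 0.0, atol=1e-10)

    def test_antisymmetric_pair(self):
        v = np.arange(1.0, 5.0)
        rel = nh.relative_activation(np.vstack([v, -v]))
        assert np.allclose(rel, np.vstack([v, -v]))

    def test_idempotent_on_centered_input(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 6))
        once = nh.relative_activation(X)
        assert np.allclose(nh.relative_activation(once), once, atol=1e-12)


class TestStateFc:
    def test_diagonal_covariance_identity_correlation(self):
        assert np.allclose(nh.state_fc(np.diag([1.0, 4.0, 9.0])), np.eye(3))

    def test_rank_one_all_ones(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(nh.state_fc(np.outer(v, v)), 1.0)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(6, 6))
        C = B @ B.T
        R = nh.state_fc(C)
        d = np.sqrt(np.diag(C))
        direct = C / np.outer(d, d)
        assert np.allclose(R, direct, atol=1e-12)

    def test_negative_diagonal_raises(self):
        with pytest.raises(ParameterError):
            nh.state_fc(np.diag([1.0, -1.0]))


class TestNetworkAggregate:
    def test_zero_correlations_zero_blocks(self):
        fc = np.eye(4)
        out = nh.network_aggregate(fc, ["A", "A", "B", "B"])
        assert out.loc["A", "B"] == pytest.approx(0.0)
        assert out.loc["A", "A"] == pytest.approx(0.0)

    def test_constant_half_correlation(self):
        fc = np.full((4, 4), 0.5)
        np.fill_diagonal(fc, 1.0)
        out = nh.network_aggregate(fc, ["A", "A", "B", "B"])
        z = np.arctanh(0.5)
        for a in "AB":
            for b in "AB":
                assert out.loc[a, b] == pytest.approx(z, abs=1e-12)

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(4)
        B = rng.normal(size=(7, 3))
        fc = nh.state_fc(B @ B.T + 3 * np.eye(7))
        nets = ["A", "A", "B", "B", "B", "C", "C"]
        out = nh.network_aggregate(fc, nets)
        z = np.arctanh(np.clip(fc, -1 + 1e-7, 1 - 1e-7))
        # direct within-A: pair (0,1)
        assert out.loc["A", "A"] == pytest.approx(z[0, 1], abs=1e-12)
        vals = [z[i, j] for i in (0, 1) for j in (2, 3, 4)]
        assert out.loc["A", "B"] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_singleton_network_within_undefined(self):
        fc = np.eye(3)
        with pytest.warns(UserWarning):
            out = nh.network_aggregate(fc, ["A", "A", "B"])
        assert np.isnan(out.loc["B", "B"])


class TestFcSimilarity:
    def test_self_similarity_one(self, trained):
        _, covs = nh.project_to_roi(trained["fit"].model, trained["pca"])
        fcs = np.stack([nh.state_fc(c) for c in covs])
        sim = nh.fc_similarity(fcs)
        assert np.allclose(np.diag(sim), 1.0, atol=1e-10)
        assert np.allclose(sim, sim.T, atol=1e-10)

    def test_duplicate_state_similarity_one(self):
        rng = np.random.default_rng(5)
        B = rng.normal(size=(5, 5))
        fc = nh.state_fc(B @ B.T + 5 * np.eye(5))
        sim = nh.fc_similarity(np.stack([fc, fc]))
        assert sim[0, 1] == pytest.approx(1.0)

    def test_distinct_covariances_less_similar_than_identical(self, study):
        covs = study[0].model.covs
        fcs = np.stack([nh.state_fc(c) for c in covs[:3]])
        fcs = np.concatenate([fcs, fcs[:1]])  # state 3 duplicates state 0
        sim = nh.fc_similarity(fcs)
        assert sim[0, 3] > sim[0, 1]
        assert sim[0, 3] > sim[0, 2]
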