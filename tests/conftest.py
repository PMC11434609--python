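"""Shared fixtures: the default synthetic study, one trained model, and the
two-night generalization experiment. Session-scoped so the expensive VB fits
run once."""

from __future__ import annotations

import numpy as np
import pytest

import nighthmm as nh


@pytest.fixture(scope="session")
def study():
    """Default study conditions: 3 participants x 2000 frames x 20 channels,
    K_true = 6 states nested in six sleep stages."""
    return nh.make_study(seed=0)


@pytest.fixture(scope="session")
def trained(study):
    """Preprocess the study and fit a K=6 VB-HMM (best of 5 restarts)."""
    sessions = [nh.standardize(ds.observations) for ds in study]
    concat = nh.concatenate(sessions)
    pca, scores = nh.fit_pca(concat, 13)
    res = nh.fit(scores, 6, segments=concat.segments, n_restarts=5, seed=100)
    hyp_cat = np.concatenate([ds.hypnogram for ds in study])
    true_path = np.concatenate([ds.true_path for ds in study])
    raw = np.vstack([ds.observations.data for ds in study])
    return {
        "study": study,
        "model_true": study[0].model,
        "concat": concat,
        "pca": pca,
        "scores": scores,
        "fit": res,
        "hypnogram": hyp_cat,
        "true_path": true_path,
        "raw_mean": raw.mean(axis=0),
        "raw_sd": raw.std(axis=0, ddof=1),
    }


@pytest.fixture(scope="session")
def second_night(trained):
    """A fresh night from the same generative truth, decoded with the frozen
    night-2 model through the frozen PCA."""
    study1 = nh.make_study(model=trained["model_true"], seed=500)
    sessions1 = [nh.standardize(ds.observations) for ds in study1]
    concat1 = nh.concatenate(sessions1)
    scores1 = trained["pca"].transform(concat1.data)
    post1 = nh.apply_model(scores1, trained["fit"].model, segments=concat1.segments)
    hyp1 = np.concatenate([ds.hypnogram for ds in study1])
    return {
        "concat": concat1,
        "scores": scores1,
        "posteriors": post1,
        "hypnogram": hyp1,
    }


@pytest.fixture(scope="session")
def planted_modular_matrix():
    """21-state transition matrix with 5 planted modules at a 9:1
    within:between row-mass ratio."""
    rng = np.random.default_rng(7)
    sizes = [7, 3, 5, 2, 4]
    truth = np.repeat(np.arange(5), sizes)
    K = truth.size
    W = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if i != j:
                W[i, j] = rng.uniform(0.5, 1.5)
    for i in range(K):
        within = (truth == truth[i]).copy()
        within[i] = False
        between = truth != truth[i]
        W[i, within] *= 0.9 / W[i, within].sum()
        W[i, between] *= 0.1 / W[i, between].sum()
    return W, truth


def make_markov_dataset(K=4, D=5, T=1200, seed=0, mean_scale=1.6, p_self=0.75):
    """Single-segment Markov-Gaussian data with separated state means."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0, mean_scale, (K, D))
    covs = np.stack([np.eye(D) * rng.uniform(0.6, 1.2) for _ in range(K)])
    A = np.full((K, K), (1 - p_self) / (K - 1))
    np.fill_diagonal(A, p_self)
    gm = nh.GenerativeModel(K=K, R=D, stage_pools={"N2": list(range(K))}, A=A,
                            pi=np.full(K, 1 / K), means=means, covs=covs)
    hyp = np.array(["N2"] * T, dtype=object)
    path = nh.simulate_state_sequence(hyp, gm, seed + 1)
    obs = nh.simulate_observations(path, gm, seed + 2)
    return obs.data, path, gm
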