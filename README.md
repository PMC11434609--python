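# nighthmm

Data-driven characterization of whole-night sleep from multichannel brain
time series. `nighthmm` fits a variational-Bayes Gaussian hidden Markov
model (HMM) to ROI time courses, selects the number of brain states from
the variational free energy, quantifies each state's temporal signature
(fractional occupancy, lifetime) and its correspondence to
polysomnography-based sleep stages (Wake, N1, N2, N3, REM, Undefined),
clusters the state transition matrix into directed-modularity "transition
modules", back-projects state parameters to activation and
functional-connectivity (FC) maps, and generalizes a frozen model to a
held-out recording night. It is aimed at sleep/fMRI researchers who want a
tested, reproducible implementation of this analysis, and ships a
synthetic-data generator so the entire pipeline is exercisable without any
imaging data.

## The model

Each hidden state `k` is a multivariate Gaussian `N(mu_k, Sigma_k)` over
the reduced (PCA) channels — `mu_k` is the state's mean activation pattern
and `Sigma_k` its FC matrix — and state switching is a first-order Markov
chain `(pi, A)`. Conjugate priors (Dirichlet on `pi` and the rows of `A`,
Normal–Wishart on each `(mu_k, Lambda_k)`) give closed-form variational
updates, and the variational free energy

    F = -( sum_seg log Z_seg - KL[q(pi)] - KL[q(A)] - KL[q(mu, Lambda)] )

is the exact negative evidence bound: it decreases monotonically over
iterations, and its first local minimum over the number of states K is the
model-order selection rule. Transition structure is summarized with the
Leicht–Newman directed modularity Q of the off-diagonal-renormalized
transition matrix. See `docs/methods.md` for the full account.

## Worked example

Fit the default synthetic study (3 participants × 2000 frames × 20
channels, 6 ground-truth states nested in the six sleep stages, TR = 3 s),
then decode a second synthetic night with the frozen model:

```python
import numpy as np
import nighthmm as nh

study = nh.make_study(seed=0)                       # night 2 (training)
sessions = [nh.standardize(ds.observations) for ds in study]
concat = nh.concatenate(sessions)
pca, scores = nh.fit_pca(concat, 13)
print(f"variance retained: {100 * pca.explained_variance_fraction:.1f}%")

res = nh.fit(scores, K=6, segments=concat.segments, n_restarts=5, seed=100)
hyp = np.concatenate([ds.hypnogram for ds in study])
summary = nh.summarize(res.posteriors.gamma, res.posteriors.viterbi,
                       hyp, concat.segments, tr_seconds=3.0)
print(summary.wta_stage)
print(np.round(summary.mean_lifetime_s, 1))

W = nh.off_diagonal_normalize(res.model.A)
part = nh.directed_modularity(W)
print(f"{part.n_modules} transition modules, Q = {part.q:.3f}")

night1 = nh.make_study(model=study[0].model, seed=500)   # held-out night
s1 = [nh.standardize(ds.observations) for ds in night1]
c1 = nh.concatenate(s1)
post1 = nh.apply_model(pca.transform(c1.data), res.model, segments=c1.segments)
summary1 = nh.summarize(post1.gamma, post1.viterbi,
                        np.concatenate([ds.hypnogram for ds in night1]),
                        c1.segments, 3.0)
r, p = nh.cross_night_correlation(summary.stage_dist, summary1.stage_dist)
print(f"cross-night r = {r:.3f}")
```

Output:

```
variance retained: 81.8%
['REM', 'N2', 'N3', 'N1', 'Wake', 'Undefined']
[20.9 16.2 23.4 10.3 24.8 11.5]
2 transition modules, Q = 0.239
cross-night r = 1.000
```

Each recovered state maps winner-takes-all onto exactly one of the six
planted stages; mean lifetimes fall in the 8.7–36 s range the generator is
designed to produce; and the stage distributions of the frozen states are
essentially identical across the two nights (r ≈ 1.0), the synthetic analog
of cross-night model generalization.

The same run is available from the shell:

```bash
nighthmm run --config config.yaml --seed 0
```

with a YAML config selecting the synthetic conditions, `n_components`, `k`
(or `k_range` for a free-energy scan), and an optional `apply_night`
section; every output table is stamped with the config hash and seed, and
reruns are numerically identical.

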