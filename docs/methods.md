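# Methods

## The model

`nighthmm` characterizes whole-night brain dynamics as a sequence of
recurring, quasi-stationary states. Observations are frames of a reduced
ROI time series (one frame per repetition time, TR); each hidden state `k`
emits a multivariate Gaussian with state-specific mean activation `mu_k`
and covariance `Sigma_k` (the state's functional-connectivity pattern), and
switching between states follows a first-order Markov chain with initial
distribution `pi` and row-stochastic transition matrix `A`.

Inference is variational Bayes with fully conjugate priors:

- Dirichlet priors on `pi` and on each row of `A` (concentration 1 by
  default — flat, no sticky bias);
- a Normal–Wishart prior on each state's `(mu_k, Lambda_k)` with location
  `m0` = global data mean, scale `beta0 = 1`, degrees of freedom
  `nu0 = D + 1`, and Wishart scale `W0` chosen so the expected precision
  `nu0 * W0` equals the inverse global data covariance.

The E-step runs scaled forward–backward under the *expected* natural
parameters (digamma-based geometric means); the M-step applies the standard
conjugate updates from the soft counts. The variational free energy is

```
F = -( sum_seg log Z_seg - KL[q(pi)] - sum_rows KL[q(A_row)]
       - sum_states KL[q(mu, Lambda)] )
```

where `log Z_seg` is the sum of the forward-pass scaling constants. Under
this parametrization F is the exact negative evidence lower bound, so it is
monotone non-increasing across iterations, vanishes for zero data with
posterior = prior, and for K = 1 converges to the negative closed-form
Normal–Wishart log marginal likelihood — all three properties are asserted
in the test suite.

Recordings are processed as contiguous *segments* (runs split at censored
frames): each segment restarts from `pi` and no transition is counted
across a gap, so run breaks and censored frames never contaminate `A`.

### Numerical choices

- Forward–backward uses per-frame scaling with the per-frame max of the
  log-emissions shifted out before exponentiation; probabilities are
  clipped at 1e-300 before logs.
- Point estimates are posterior expectations; the covariance point estimate
  is the inverse expected precision `(nu_k W_k)^{-1}`, which is defined for
  every posterior including prior-dominated empty states (the
  inverse-Wishart mean `W^{-1}/(nu-D-1)` is not, at `nu0 = D+1`).
- A state whose total responsibility falls below 1e-8 keeps its prior
  hyperparameters and is logged.
- Convergence: relative free-energy change < 1e-5 (default), max 500
  iterations; initialization is k-means on frames (10 k-means restarts,
  seeded) followed by one M-step; the fit uses 5 VB restarts with seeds
  `seed+0..4`, keeping the lowest final free energy (ties to lower seed).
- Data covariance used in the prior receives a ridge of
  `1e-8 * trace/D` before inversion.

## Preprocessing

Each participant's channels are standardized to mean 0 and sample SD 1
(denominator n−1) over that participant's uncensored frames; the transform
is applied to all frames. Standardized sessions are concatenated and
reduced by PCA (SVD of the column-centered matrix, unwhitened scores) to
`n_components` dimensions (default 13). The PCA is fitted once on the
training night and frozen; a held-out night is standardized per participant
and projected through the *same* mixing matrix, which is what makes
frozen-model decoding across nights well defined. Scores are unwhitened so
back-projected state covariances remain interpretable.

## Model-order selection

`scan_orders` fits every K in a range and records four statistics: the
final free energy, maximum and median fractional occupancy (column means of
gamma), mean state lifetime, and — when per-frame stage labels are
available — Wilks' Λ from a one-way MANOVA of the soft state time courses
against the stage grouping (last gamma column dropped because rows sum
to 1; a ridge of 1e-10 is added if the total scatter is singular). The
chosen order is the *first local minimum of the free energy*; the other
statistics are diagnostics, not voters. If no interior local minimum
exists, the global argmin is used, with ties toward smaller K. Soft gamma
(not Viterbi indicators) feeds Λ, matching the use of state time courses
rather than hard paths.

## State statistics

Lifetimes are computed on the Viterbi path: a visit is a maximal
single-state run within one segment; visits truncated by segment edges are
counted at their observed length (excluding them would bias short
recordings), and the mean visit duration is multiplied by TR. Each state's
stage distribution is its row-normalized co-occurrence with the six
hypnogram labels (Wake, N1, N2, N3, REM, Undefined); winner-takes-all
assigns the state to its modal stage with exact ties broken by the fixed
order Wake > N1 > N2 > N3 > REM > Undefined. Cross-night similarity is the
Pearson correlation between two flattened K×6 stage-distribution matrices
(states aligned by the frozen model); the reported p-value is never used
for any decision inside the pipeline.

## Transition modules

Because states persist for several frames, self-transitions dominate `A`;
the matrix is therefore off-diagonal renormalized (diagonal zeroed, rows
rescaled to 1) before community detection. Modules maximize the
Leicht–Newman *directed* modularity

```
Q = (1/m) sum_ij [ W_ij - k_i^out k_j^in / m ] delta(c_i, c_j)
```

by recursive spectral bisection of the symmetrized modularity matrix
`(B + B^T)` restricted to each group (generalized subdivision matrix), with
Kernighan–Lin-style fine-tuning (full deterministic passes, each node
flipped once in greedy order, best prefix kept). Splitting stops when no
bisection adds more than 1e-12 to Q. The number of modules is emergent. An
exhaustive-search implementation over all set partitions serves as the test
oracle for K ≤ 8. A symmetric (undirected-null) variant is available behind
a flag.

## State maps

State means and covariances are back-projected with the PCA mixing matrix:
`roi_mean = M mu + channel_means`, `roi_cov = M Sigma M^T`. Activation maps
are reported relative to the *unweighted* across-state mean. Per-state FC
is the correlation matrix of the back-projected covariance, computed as-is
on the rank-deficient matrix (rank ≤ n_components; documented, not
repaired). Network-level FC is the mean Fisher-z (atanh, correlations
clipped to ±(1−1e-7)) over ROI pairs within (i<j) or between networks;
single-ROI networks have undefined within-network values. Between-state FC
similarity is the Pearson correlation of vectorized upper triangles.

An empirical-FC alternative (recomputing correlations over state-assigned
frames) is deliberately not the default: the model covariance is the
quantity the HMM estimates, and it is what gets back-projected.

## Synthetic data

The generator emulates the structure of a whole-night sleep fMRI study at
desk scale; defaults are 3 participants × 2000 frames × 20 channels at
TR = 3 s, with K_true = 6 states nested one-per-stage in the six PSG
stages.

- The hypnogram cycles through a fixed template of (stage, mean bout)
  pairs; bout durations are gamma-distributed (shape set by a
  coefficient-of-variation parameter, default 0.4), rounded and floored at
  one frame. Gamma bouts give the super-Markov persistence of real sleep
  stages while within-stage state dwells stay geometric, matching the
  fitted model's Markov assumption.
- Default bout means (Wake 8, N1 3.5, N2 6, N3 8, N2 5, REM 7,
  Undefined 4 frames) put realized state lifetimes in the 8.7–36 s range
  reported for fMRI-derived sleep states; the N1 mean is 3.5 rather than 3
  frames because discretization biases short bouts low.
- Within a bout, a Markov chain runs on the stage's state pool (transition
  matrix restricted and renormalized; chain re-initialized from restricted
  `pi` at bout boundaries — pools are disjoint by default, so continuing
  the chain is not meaningful).
- Emissions are exact multivariate Gaussians per state; ground-truth means
  are unit-scale random patterns (well separated over 20 channels) and
  covariances are random SPD matrices with eigenvalues in ~[0.4, 1.6], so
  every state also carries a distinct connectivity fingerprint.
- One master seed; participant p uses `seed + 10p`, and a night's
  hypnogram/path/emission draws use consecutive sub-seeds. Identical seeds
  give bit-identical datasets.

What the generator deliberately omits: hemodynamic convolution,
physiological noise, scanner drift, motion, and any autocorrelation within
a state. Passing recovery tests on these data therefore demonstrates the
correctness of the estimator and pipeline plumbing — not robustness to the
noise structure of real fMRI.

## Experiment scales

The built-in experiments (tests and `scripts/acceptance.py`) use: the
default 3 × 2000-frame study reduced to 13 components for recovery and
cross-night checks; a 1 × 1200-frame, 5-channel, K_true = 4 dataset scanned
over K = 2..8 with 2 restarts per fit, repeated for 10 seeds, for the
order-selection experiment; a planted 5-module, 21-state matrix with a 9:1
within:between row-mass ratio for module recovery; and a 10⁴-frame
two-state chain with self-transition 0.75 for the dwell-law check (expected
lifetime TR/(1−p) = 12 s). These sizes keep every experiment comfortably
reproducible on a laptop while leaving the statistical targets (transition
error ≤ 0.05, mean correlation ≥ 0.99, ARI = 1.0, cross-night r ≥ 0.9)
well-powered.

## Known limitations

- Gaussian emissions with temporally independent frames given the state; no
  autoregressive or time-embedded observation models.
- The VB bound is optimized by coordinate ascent from k-means
  initializations; restarts mitigate but do not eliminate local optima.
- Back-projected covariances are rank-deficient (rank ≤ n_components);
  ROI-level FC values inherit that smoothing.
- Spectral bisection with fine-tuning is not guaranteed globally optimal for
  modularity (tests bound it at ≥ 95% of the exhaustive optimum for small
  K, exact on block-structured matrices).
- Real-data ingestion accepts pre-extracted ROI tables only; volumetric
  image I/O and atlas work are upstream of this package.
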