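"""Variational-Bayes Gaussian hidden Markov model.

Each hidden state carries a multivariate Gaussian emission (mean activation
vector + covariance / functional-connectivity matrix); switching follows a
first-order Markov chain. Conjugate priors — Dirichlet on the initial and
per-row transition distributions, Normal-Wishart on each state's (mean,
precision) — give closed-form coordinate updates:

  E-step  forward-backward under the *expected* natural parameters
          (digamma-based geometric means of pi, A and the Gaussian density),
          per contiguous segment; no transition is counted across a segment
          boundary and every segment restarts from the initial distribution.
  M-step  Dirichlet rows from the xi counts, Normal-Wishart from the
          gamma-weighted data moments.

The variational free energy (negative evidence lower bound)

  F = -( sum_segments log Z_seg  -  KL[q(pi)] - sum_rows KL[q(A_row)]
         - sum_states KL[q(mu, Lambda)] )

is exact under this parametrization — log Z_seg is the sum of the scaling
normalizers of the forward pass run with the expected parameters — so F is
monotone non-increasing across iterations, and for K = 1 the converged F
equals the closed-form Normal-Wishart log marginal likelihood with the sign
flipped. Lower F = better model; the model-order scan picks the first local
minimum of F over K.

Point estimates exposed for decoding and maps are posterior expectations:
pi and A are Dirichlet means, state means are the Normal-Wishart location,
and each state covariance is the inverse of the expected precision
(nu_k W_k)^{-1} (well defined for every posterior, unlike the
inverse-Wishart mean, which diverges at the default prior for empty states).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, multigammaln
from sklearn.cluster import KMeans

from .exceptions import ParameterError

logger = logging.getLogger("nighthmm")

_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class NormalWishartPrior:
    """Shared Normal-Wishart hyperparameters (m0, beta0, W0, nu0)."""

    m0: np.ndarray
    beta0: float
    W0: np.ndarray
    nu0: float


@dataclass
class HmmModel:
    """K-state Gaussian HMM with conjugate prior and posterior families.

    Posterior arrays are stacked: ``post_m`` is (K, D), ``post_W`` is
    (K, D, D), etc. ``point_mode`` models bypass the variational expectations
    and use exact fixed parameters — used for decoding with known parameters
    and for oracle tests.
    """

    K: int
    D: int
    prior_pi_conc: np.ndarray
    prior_A_conc: np.ndarray
    nw_prior: NormalWishartPrior
    post_pi_conc: np.ndarray
    post_A_conc: np.ndarray
    post_m: np.ndarray
    post_beta: np.ndarray
    post_W: np.ndarray
    post_nu: np.ndarray
    point_mode: bool = False
    _pi: np.ndarray | None = None
    _A: np.ndarray | None = None
    _covs: np.ndarray | None = None

    # -- point estimates ----------------------------------------------------

    @property
    def pi(self) -> np.ndarray:
        if self.point_mode:
            return self._pi
        return self.post_pi_conc / self.post_pi_conc.sum()

    @property
    def A(self) -> np.ndarray:
        if self.point_mode:
            return self._A
        return self.post_A_conc / self.post_A_conc.sum(axis=1, keepdims=True)

    @property
    def means(self) -> np.ndarray:
        return self.post_m

    @property
    def covs(self) -> np.ndarray:
        if self.point_mode:
            return self._covs
        return np.linalg.inv(self.post_nu[:, None, None] * self.post_W)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_point_estimates(cls, pi, A, means, covs) -> "HmmModel":
        """Model with exact fixed parameters (no variational uncertainty)."""
        pi = np.asarray(pi, float)
        A = np.asarray(A, float)
        means = np.atleast_2d(np.asarray(means, float))
        covs = np.asarray(covs, float)
        K, D = means.shape
        if covs.shape != (K, D, D):
            raise ParameterError("covs must be (K, D, D)")
        nw = NormalWishartPrior(np.zeros(D), 1.0, np.eye(D), float(D + 1))
        prec = np.linalg.inv(covs)
        return cls(
            K=K, D=D,
            prior_pi_conc=np.ones(K), prior_A_conc=np.ones((K, K)), nw_prior=nw,
            post_pi_conc=np.ones(K), post_A_conc=np.ones((K, K)),
            post_m=means, post_beta=np.ones(K),
            post_W=prec, post_nu=np.ones(K),
            point_mode=True, _pi=pi, _A=A, _covs=covs,
        )

    # -- expected (geometric-mean) parameters used by the E-step ------------

    def expected_log_pi(self) -> np.ndarray:
        if self.point_mode:
            return np.log(np.clip(self._pi, _LOG_FLOOR, None))
        return digamma(self.post_pi_conc) - digamma(self.post_pi_conc.sum())

    def expected_log_A(self) -> np.ndarray:
        if self.point_mode:
            return np.log(np.clip(self._A, _LOG_FLOOR, None))
        return digamma(self.post_A_conc) - digamma(
            self.post_A_conc.sum(axis=1, keepdims=True)
        )

    def expected_log_emissions(self, X: np.ndarray) -> np.ndarray:
        """(T, K) expected Gaussian log-densities E_q[log N(x | mu_k, Lambda_k)]."""
        X = np.atleast_2d(np.asarray(X, float))
        if not np.all(np.isfinite(X)):
            raise ParameterError("observations contain non-finite values")
        if X.shape[1] != self.D:
            raise ParameterError(f"data dimension {X.shape[1]} != model D={self.D}")
        T = X.shape[0]
        out = np.empty((T, self.K))
        if self.point_mode:
            for k in range(self.K):
                out[:, k] = _gauss_logpdf(X, self.post_m[k], self._covs[k])
            return out
        D = self.D
        for k in range(self.K):
            W, nu, beta, m = self.post_W[k], self.post_nu[k], self.post_beta[k], self.post_m[k]
            _, logdetW = np.linalg.slogdet(W)
            elogdet = (
                digamma(0.5 * (nu - np.arange(D))).sum() + D * np.log(2.0) + logdetW
            )
            diff = X - m
            maha = np.einsum("ti,ij,tj->t", diff, W, diff)
            out[:, k] = 0.5 * (elogdet - D * np.log(2 * np.pi) - D / beta - nu * maha)
        return out


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Exact multivariate normal log-density via Cholesky."""
    D = len(mean)
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (D * np.log(2 * np.pi) + logdet + maha)


@dataclass
class StatePosteriors:
    """Per-frame state beliefs from one E-step (or decode)."""

    gamma: np.ndarray  # (T, K)
    xi: np.ndarray  # (n_segments, K, K), summed pairwise expectations
    loglik: np.ndarray  # per-segment log normalizers
    viterbi: np.ndarray | None = None  # (T,) most-probable path


@dataclass
class FitResult:
    model: HmmModel
    posteriors: StatePosteriors
    free_energy_trace: np.ndarray
    converged: bool
    seed: int
    n_restarts_used: int

    @property
    def free_energy(self) -> float:
        return float(self.free_energy_trace[-1])


# ---------------------------------------------------------------------------
# forward-backward / Viterbi on one segment
# ---------------------------------------------------------------------------

def _fb_segment(logB: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray):
    """Scaled forward-backward. Returns (gamma, xi_sum, log_evidence).

    Works with sub-normalized (geometric-mean) parameters; the log evidence
    is the sum of the scaling constants, which under VB expected parameters
    is the data term of the evidence lower bound.
    """
    T, K = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    piv = np.exp(log_pi)
    Av = np.exp(log_A)
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = piv * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise ParameterError("zero forward mass; check observations")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ Av) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (Av @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.zeros((K, K))
    for t in range(1, T):
        x = Av * np.outer(alpha[t - 1], B[t] * beta[t]) / c[t]
        xi += x / x.sum()
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi, loglik


def _viterbi_segment(logB: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    delta = log_pi + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_A
        back[t] = scores.argmax(axis=0)
        delta = scores[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _iter_segments(segments) -> list[tuple[int, int]]:
    return [(int(s), int(e)) for s, e in segments]


def forward_backward(X: np.ndarray, model: HmmModel, segments=None) -> StatePosteriors:
    """E-step: per-segment scaled forward-backward under expected parameters."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 0:
        raise ParameterError("empty data")
    if segments is None:
        segments = [(0, X.shape[0])]
    segments = _iter_segments(segments)
    logB = model.expected_log_emissions(X)
    log_pi = model.expected_log_pi()
    log_A = model.expected_log_A()
    T = X.shape[0]
    gamma = np.zeros((T, model.K))
    xi = np.zeros((len(segments), model.K, model.K))
    loglik = np.zeros(len(segments))
    for i, (s, e) in enumerate(segments):
        g, x, ll = _fb_segment(logB[s:e], log_pi, log_A)
        gamma[s:e] = g
        xi[i] = x
        loglik[i] = ll
    return StatePosteriors(gamma=gamma, xi=xi, loglik=loglik)


def viterbi_decode(X: np.ndarray, model: HmmModel, segments=None) -> np.ndarray:
    """Exact most-probable path per segment under the point estimates."""
    X = np.atleast_2d(np.asarray(X, float))
    if segments is None:
        segments = [(0, X.shape[0])]
    log_pi = np.log(np.clip(model.pi, _LOG_FLOOR, None))
    log_A = np.log(np.clip(model.A, _LOG_FLOOR, None))
    means, covs = model.means, model.covs
    logB = np.column_stack(
        [_gauss_logpdf(X, means[k], covs[k]) for k in range(model.K)]
    )
    path = np.empty(X.shape[0], dtype=int)
    for s, e in _iter_segments(segments):
        path[s:e] = _viterbi_segment(logB[s:e], log_pi, log_A)
    return path


def decode(X: np.ndarray, model: HmmModel, mode: str = "posterior", segments=None):
    """State time courses for fitted parameters.

    mode="posterior" returns a :class:`StatePosteriors` with soft gamma;
    mode="viterbi" returns the hard most-probable path.
    """
    if mode == "posterior":
        return forward_backward(X, model, segments)
    if mode == "viterbi":
        return viterbi_decode(X, model, segments)
    raise ParameterError(f"unknown decode mode {mode!r}")


# ---------------------------------------------------------------------------
# VB updates
# ---------------------------------------------------------------------------

def default_priors(X: np.ndarray, K: int, alpha_pi: float = 1.0, alpha_A: float = 1.0):
    """Data-scaled uninformative priors: m0 = data mean, E[Lambda] matched to
    the inverse data covariance, beta0 = 1, nu0 = D + 1, Dirichlet 1."""
    D = X.shape[1]
    m0 = X.mean(axis=0)
    cov = np.cov(X.T, ddof=1).reshape(D, D)
    cov = cov + 1e-8 * np.trace(cov) / D * np.eye(D)
    nu0 = float(D + 1)
    W0 = np.linalg.inv(cov * nu0)
    return (
        np.full(K, alpha_pi),
        np.full((K, K), alpha_A),
        NormalWishartPrior(m0=m0, beta0=1.0, W0=W0, nu0=nu0),
    )


def vb_update(X: np.ndarray, posteriors: StatePosteriors, model: HmmModel,
              segments=None) -> HmmModel:
    """M-step: conjugate posterior updates from the E-step expectations."""
    X = np.atleast_2d(np.asarray(X, float))
    if segments is None:
        segments = [(0, X.shape[0])]
    segments = _iter_segments(segments)
    K, D = model.K, model.D
    gamma, xi = posteriors.gamma, posteriors.xi
    first = np.zeros(K)
    for s, _ in segments:
        first += gamma[s]
    pi_conc = model.prior_pi_conc + first
    A_conc = model.prior_A_conc + xi.sum(axis=0)

    nw = model.nw_prior
    W0inv = np.linalg.inv(nw.W0)
    Nk = gamma.sum(axis=0)
    post_m = np.empty((K, D))
    post_beta = np.empty(K)
    post_W = np.empty((K, D, D))
    post_nu = np.empty(K)
    for k in range(K):
        if Nk[k] < 1e-8:
            logger.debug("state %d empty (N=%.3g); posterior stays prior-dominated", k, Nk[k])
            post_m[k], post_beta[k] = nw.m0, nw.beta0
            post_W[k], post_nu[k] = nw.W0, nw.nu0
            continue
        xbar = gamma[:, k] @ X / Nk[k]
        diff = X - xbar
        Sk = (gamma[:, k] * diff.T) @ diff
        dm = (xbar - nw.m0)[:, None]
        Winv = W0inv + Sk + (nw.beta0 * Nk[k] / (nw.beta0 + Nk[k])) * (dm @ dm.T)
        post_beta[k] = nw.beta0 + Nk[k]
        post_m[k] = (nw.beta0 * nw.m0 + Nk[k] * xbar) / post_beta[k]
        post_nu[k] = nw.nu0 + Nk[k]
        post_W[k] = np.linalg.inv(0.5 * (Winv + Winv.T))
    return HmmModel(
        K=K, D=D,
        prior_pi_conc=model.prior_pi_conc, prior_A_conc=model.prior_A_conc,
        nw_prior=nw,
        post_pi_conc=pi_conc, post_A_conc=A_conc,
        post_m=post_m, post_beta=post_beta, post_W=post_W, post_nu=post_nu,
    )


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def _kl_dirichlet(q: np.ndarray, p: np.ndarray) -> float:
    q = np.asarray(q, float)
    p = np.asarray(p, float)
    qs, ps = q.sum(), p.sum()
    return float(
        gammaln(qs) - gammaln(ps)
        - (gammaln(q) - gammaln(p)).sum()
        + ((q - p) * (digamma(q) - digamma(qs))).sum()
    )


def _kl_normal_wishart(m, beta, W, nu, nw: NormalWishartPrior) -> float:
    D = len(m)
    m0, beta0, W0, nu0 = nw.m0, nw.beta0, nw.W0, nw.nu0
    _, logdetW = np.linalg.slogdet(W)
    _, logdetW0 = np.linalg.slogdet(W0)
    elogdet = digamma(0.5 * (nu - np.arange(D))).sum() + D * np.log(2.0) + logdetW
    # Gaussian part, expectation over Lambda ~ Wishart(W, nu)
    dm = m - m0
    kl_gauss = 0.5 * (
        D * (beta0 / beta - 1.0 - np.log(beta0 / beta))
        + beta0 * nu * dm @ W @ dm
    )
    # Wishart part:
    # KL = (nu-nu0)/2 E[log|L|] - nu D/2 + nu/2 tr(W0^-1 W) - log B(W0,nu0) + log B(W,nu)
    # with log B(W,nu)^-1 = (nu/2) log|W| + nu D/2 log 2 + logGamma_D(nu/2)
    W0inv = np.linalg.inv(W0)
    kl_wish = (
        0.5 * (nu - nu0) * elogdet
        - 0.5 * nu * D
        + 0.5 * nu * np.trace(W0inv @ W)
        + (0.5 * nu0 * logdetW0 + 0.5 * nu0 * D * np.log(2.0) + multigammaln(0.5 * nu0, D))
        - (0.5 * nu * logdetW + 0.5 * nu * D * np.log(2.0) + multigammaln(0.5 * nu, D))
    )
    return float(kl_gauss + kl_wish)


def free_energy(posteriors: StatePosteriors, model: HmmModel) -> float:
    """Negative evidence lower bound; lower is better.

    ``posteriors`` must come from :func:`forward_backward` run under the same
    ``model`` for the value to be the exact bound.
    """
    kl = _kl_dirichlet(model.post_pi_conc, model.prior_pi_conc)
    for j in range(model.K):
        kl += _kl_dirichlet(model.post_A_conc[j], model.prior_A_conc[j])
    for k in range(model.K):
        kl += _kl_normal_wishart(
            model.post_m[k], model.post_beta[k], model.post_W[k], model.post_nu[k],
            model.nw_prior,
        )
    return float(-(posteriors.loglik.sum() - kl))


# ---------------------------------------------------------------------------
# initialization and fitting
# ---------------------------------------------------------------------------

def init_model(X: np.ndarray, K: int, seed: int, segments=None,
               alpha_pi: float = 1.0, alpha_A: float = 1.0) -> HmmModel:
    """K-means responsibilities + one conjugate M-step. Deterministic per seed."""
    X = np.atleast_2d(np.asarray(X, float))
    T = X.shape[0]
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > T:
        raise ParameterError(f"K={K} exceeds the number of frames T={T}")
    if segments is None:
        segments = [(0, T)]
    segments = _iter_segments(segments)
    pi0, A0, nw = default_priors(X, K, alpha_pi, alpha_A)
    if K == 1:
        labels = np.zeros(T, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2**31))
        labels = km.fit_predict(X)
    gamma = np.zeros((T, K))
    gamma[np.arange(T), labels] = 1.0
    xi = np.zeros((len(segments), K, K))
    for i, (s, e) in enumerate(segments):
        for t in range(s + 1, e):
            xi[i, labels[t - 1], labels[t]] += 1.0
    stub = HmmModel(
        K=K, D=X.shape[1],
        prior_pi_conc=pi0, prior_A_conc=A0, nw_prior=nw,
        post_pi_conc=pi0.copy(), post_A_conc=A0.copy(),
        post_m=np.tile(nw.m0, (K, 1)), post_beta=np.full(K, nw.beta0),
        post_W=np.tile(nw.W0, (K, 1, 1)), post_nu=np.full(K, nw.nu0),
    )
    post = StatePosteriors(gamma=gamma, xi=xi, loglik=np.zeros(len(segments)))
    return vb_update(X, post, stub, segments)


def fit(
    X: np.ndarray,
    K: int,
    segments=None,
    max_iter: int = 500,
    tol: float = 1e-5,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """VB fit with restarts; returns the restart with lowest final free energy.

    Restart r uses seed ``seed + r``; ties break toward the lower seed. The
    free-energy trace is the exact bound after each E-step and is monotone
    non-increasing.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if segments is None:
        segments = [(0, X.shape[0])]
    best: FitResult | None = None
    for r in range(n_restarts):
        model = init_model(X, K, seed=seed + r, segments=segments)
        trace: list[float] = []
        converged = False
        posteriors = None
        for _ in range(max_iter):
            posteriors = forward_backward(X, model, segments)
            F = free_energy(posteriors, model)
            trace.append(F)
            if len(trace) > 1:
                rel = abs(trace[-2] - F) / max(abs(trace[-2]), 1e-12)
                if rel < tol:
                    converged = True
                    break
            model = vb_update(X, posteriors, model, segments)
        if not converged:
            logger.warning("restart %d: no convergence in %d iterations", r, max_iter)
        result = FitResult(
            model=model,
            posteriors=posteriors,
            free_energy_trace=np.array(trace),
            converged=converged,
            seed=seed + r,
            n_restarts_used=n_restarts,
        )
        if best is None or result.free_energy < best.free_energy:
            best = result
    best.posteriors.viterbi = viterbi_decode(X, best.model, segments)
    return best


def apply_model(
    new_X: np.ndarray, model: HmmModel, segments=None, re_estimate: str = "none"
) -> StatePosteriors:
    """Semi-supervised generalization: decode new data with every state
    parameter (emissions *and* transitions) frozen — one E-step plus Viterbi.
    """
    if re_estimate != "none":
        raise ParameterError("only re_estimate='none' is supported")
    new_X = np.atleast_2d(np.asarray(new_X, float))
    if new_X.shape[0] == 0:
        raise ParameterError("empty data")
    if new_X.shape[1] != model.D:
        raise ParameterError(
            f"new data has dimension {new_X.shape[1]}, model expects {model.D}; "
            "project through the training-night PCA first"
        )
    post = forward_backward(new_X, model, segments)
    post.viterbi = viterbi_decode(new_X, model, segments)
    return post


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_json(model: HmmModel, pca_hash: str = "") -> str:
    import json

    if model.point_mode:
        raise ParameterError("point-mode models are not serialized")
    nw = model.nw_prior
    return json.dumps({
        "K": model.K, "D": model.D, "pca_hash": pca_hash,
        "prior": {
            "pi_conc": model.prior_pi_conc.tolist(),
            "A_conc": model.prior_A_conc.tolist(),
            "m0": nw.m0.tolist(), "beta0": nw.beta0,
            "W0": nw.W0.tolist(), "nu0": nw.nu0,
        },
        "posterior": {
            "pi_conc": model.post_pi_conc.tolist(),
            "A_conc": model.post_A_conc.tolist(),
            "m": model.post_m.tolist(), "beta": model.post_beta.tolist(),
            "W": model.post_W.tolist(), "nu": model.post_nu.tolist(),
        },
    })


def model_from_json(text: str) -> tuple[HmmModel, str]:
    import json

    d = json.loads(text)
    pr, po = d["prior"], d["posterior"]
    model = HmmModel(
        K=d["K"], D=d["D"],
        prior_pi_conc=np.array(pr["pi_conc"]),
        prior_A_conc=np.array(pr["A_conc"]),
        nw_prior=NormalWishartPrior(
            m0=np.array(pr["m0"]), beta0=float(pr["beta0"]),
            W0=np.array(pr["W0"]), nu0=float(pr["nu0"]),
        ),
        post_pi_conc=np.array(po["pi_conc"]),
        post_A_conc=np.array(po["A_conc"]),
        post_m=np.array(po["m"]), post_beta=np.array(po["beta"]),
        post_W=np.array(po["W"]), post_nu=np.array(po["nu"]),
    )
    return model, d.get("pca_hash", "")
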