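"""Model-order selection: scan K, compute selection statistics, pick K.

Four statistics are recorded per model order: the variational free energy,
maximum and median fractional occupancy across states, the mean state
lifetime in seconds, and (when per-frame stage labels are supplied) Wilks'
lambda from a one-way MANOVA of the soft state time courses against the
stage grouping. The chosen order is the first local minimum of the free
energy over K; the other statistics are reported as diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .hmm import fit
from .state_stats import lifetimes

logger = logging.getLogger("nighthmm")


@dataclass
class OrderScan:
    k_values: list[int]
    free_energies: list[float]
    max_fo: list[float]
    median_fo: list[float]
    mean_lifetime_s: list[float]
    wilks_lambda: list[float] = field(default_factory=list)
    chosen_k: int = -1

    def to_frame(self) -> pd.DataFrame:
        d = {
            "K": self.k_values,
            "free_energy": self.free_energies,
            "max_fo": self.max_fo,
            "median_fo": self.median_fo,
            "mean_lifetime_s": self.mean_lifetime_s,
        }
        if self.wilks_lambda:
            d["wilks_lambda"] = self.wilks_lambda
        return pd.DataFrame(d)


def fractional_occupancy_stats(gamma: np.ndarray) -> tuple[float, float]:
    """Max and median across states of the per-state fractional occupancy
    (column means of gamma)."""
    gamma = np.atleast_2d(np.asarray(gamma, float))
    if gamma.size == 0:
        raise ParameterError("empty gamma")
    fo = gamma.mean(axis=0)
    return float(fo.max()), float(np.median(fo))


def wilks_lambda(gamma: np.ndarray, stage_labels) -> float:
    """One-way MANOVA Wilks' lambda of the state time courses vs stages.

    Lambda = det(W) / det(W + B) with W/B the within/between-group scatter
    of the gamma columns; the last column is dropped before computing the
    scatters because gamma rows sum to 1 (rank repair). Lower values mean
    the state time courses separate the sleep stages better.
    """
    gamma = np.atleast_2d(np.asarray(gamma, float))
    labels = np.asarray(stage_labels)
    if len(labels) != gamma.shape[0]:
        raise ParameterError("labels and gamma must have equal frame counts")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ParameterError("need at least 2 stage groups")
    Y = gamma[:, :-1]
    grand = Y.mean(axis=0)
    p = Y.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        Yg = Y[labels == g]
        mg = Yg.mean(axis=0)
        C = Yg - mg
        W += C.T @ C
        d = (mg - grand)[:, None]
        B += len(Yg) * (d @ d.T)
    total = W + B
    sign, logdet_t = np.linalg.slogdet(total)
    if sign <= 0 or not np.isfinite(logdet_t):
        warnings.warn("singular total scatter; adding ridge 1e-10", stacklevel=2)
        W = W + 1e-10 * np.eye(p)
        total = W + B
    sw, lw = np.linalg.slogdet(W)
    st, lt = np.linalg.slogdet(total)
    if sw <= 0:
        return 0.0
    return float(np.exp(lw - lt))


def first_local_minimum(k_values, values) -> int:
    """Smallest K that is a strict local minimum of the curve; if none, the
    global argmin (ties toward the smaller K)."""
    k_values = list(k_values)
    values = np.asarray(values, float)
    if len(values) < 3:
        raise ParameterError("need at least 3 values to find a local minimum")
    for i in range(1, len(values) - 1):
        if values[i] < values[i - 1] and values[i] < values[i + 1]:
            return int(k_values[i])
    return int(k_values[int(np.argmin(values))])


def scan_orders(
    X: np.ndarray,
    k_range,
    segments=None,
    tr_seconds: float = 3.0,
    labels=None,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> OrderScan:
    """Fit every K in ``k_range`` and record the four selection statistics.

    A failed fit is recorded as NaN with a warning; ``chosen_k`` applies the
    free-energy first-local-minimum rule when at least 3 orders succeeded.
    """
    k_range = list(k_range)
    if not k_range or any(b <= a for a, b in zip(k_range, k_range[1:])):
        raise ParameterError("k_range must be non-empty and ascending")
    scan = OrderScan([], [], [], [], [], [] if labels is not None else [])
    for K in k_range:
        try:
            res = fit(X, K, segments=segments, max_iter=max_iter, tol=tol,
                      n_restarts=n_restarts, seed=seed)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("fit failed for K=%d: %s", K, exc)
            scan.k_values.append(K)
            scan.free_energies.append(np.nan)
            scan.max_fo.append(np.nan)
            scan.median_fo.append(np.nan)
            scan.mean_lifetime_s.append(np.nan)
            if labels is not None:
                scan.wilks_lambda.append(np.nan)
            continue
        mx, md = fractional_occupancy_stats(res.posteriors.gamma)
        lt = lifetimes(res.posteriors.viterbi,
                       segments or [(0, X.shape[0])], tr_seconds)
        scan.k_values.append(K)
        scan.free_energies.append(res.free_energy)
        scan.max_fo.append(mx)
        scan.median_fo.append(md)
        scan.mean_lifetime_s.append(float(np.nanmean(lt)))
        if labels is not None:
            scan.wilks_lambda.append(wilks_lambda(res.posteriors.gamma, labels))
    finite = [v for v in scan.free_energies if np.isfinite(v)]
    if len(finite) >= 3:
        ks = [k for k, v in zip(scan.k_values, scan.free_energies) if np.isfinite(v)]
        scan.chosen_k = first_local_minimum(ks, finite)
    return scan
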