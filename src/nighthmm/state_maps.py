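"""Back-projection of state parameters to ROI space and FC summaries.

State means and covariances live in PCA space; the PCA mixing matrix
projects them back to the ROI channels. Activation maps are reported
relative to the unweighted across-state average; each state's functional
connectivity (FC) is the correlation matrix of its back-projected
covariance (rank at most the number of components, by construction);
network-level FC averages the Fisher-z transformed ROI-pair correlations
within and between networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .hmm import HmmModel
from .io_preprocess import PcaModel


@dataclass
class StateMap:
    roi_mean: np.ndarray  # relative activation per ROI
    roi_fc: np.ndarray  # ROI x ROI correlation
    network_fc: pd.DataFrame | None = None


def project_to_roi(model: HmmModel, pca: PcaModel) -> tuple[np.ndarray, np.ndarray]:
    """Back-project state means/covariances: (K, R) means and (K, R, R) covs.

    ROI mean = mixing @ state_mean + channel_means; ROI covariance =
    mixing @ state_cov @ mixing^T (rank <= n_components).
    """
    if model.D != pca.n_components:
        raise ParameterError(
            f"model dimension {model.D} != PCA components {pca.n_components}"
        )
    M = pca.mixing  # (R, D)
    roi_means = model.means @ M.T + pca.channel_means
    roi_covs = np.einsum("rd,kde,se->krs", M, model.covs, M)
    roi_covs = 0.5 * (roi_covs + roi_covs.transpose(0, 2, 1))
    return roi_means, roi_covs


def relative_activation(state_roi_means: np.ndarray) -> np.ndarray:
    """Subtract the unweighted across-state mean from each state's map."""
    X = np.atleast_2d(np.asarray(state_roi_means, float))
    if X.shape[0] < 2:
        raise ParameterError("need at least 2 states")
    return X - X.mean(axis=0)


def state_fc(roi_cov: np.ndarray) -> np.ndarray:
    """Covariance -> correlation; zero-variance ROIs yield NaN rows/columns."""
    C = np.asarray(roi_cov, float)
    d = np.diag(C)
    if (d < 0).any():
        raise ParameterError("negative variance on the covariance diagonal")
    sd = np.sqrt(d)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance ROI(s); correlations set to NaN",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = C / np.outer(sd, sd)
    R[zero, :] = np.nan
    R[:, zero] = np.nan
    np.fill_diagonal(R, np.where(zero, np.nan, 1.0))
    return R


def network_aggregate(fc: np.ndarray, roi_networks: list[str]) -> pd.DataFrame:
    """Average Fisher-z FC within and between networks.

    Correlations are clipped to +-(1 - 1e-7) before atanh; within-network
    blocks use unordered ROI pairs i < j (self-pairs excluded); a network
    with a single ROI has an undefined within-network value (NaN).
    """
    fc = np.asarray(fc, float)
    R = fc.shape[0]
    if len(roi_networks) != R:
        raise ParameterError("every ROI needs a network label")
    z = np.arctanh(np.clip(fc, -1 + 1e-7, 1 - 1e-7))
    networks = list(dict.fromkeys(roi_networks))  # stable order
    idx = {n: np.flatnonzero(np.asarray(roi_networks, dtype=object) == n)
           for n in networks}
    out = pd.DataFrame(np.nan, index=networks, columns=networks, dtype=float)
    for a in networks:
        ia = idx[a]
        for b in networks:
            ib = idx[b]
            if a == b:
                if len(ia) < 2:
                    warnings.warn(f"network {a!r} has a single ROI; "
                                  "within-network FC undefined", stacklevel=2)
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                vals = z[np.ix_(ia, ia)][iu, ju]
            else:
                vals = z[np.ix_(ia, ib)].ravel()
            out.loc[a, b] = float(np.nanmean(vals))
    return out


def fc_similarity(roi_fcs: np.ndarray) -> np.ndarray:
    """(K, K) Pearson correlation between the vectorized upper triangles of
    each state's FC matrix; constant vectors give NaN entries."""
    roi_fcs = np.asarray(roi_fcs, float)
    K, R, _ = roi_fcs.shape
    if K < 2:
        raise ParameterError("need at least 2 states")
    iu, ju = np.triu_indices(R, k=1)
    V = roi_fcs[:, iu, ju]
    out = np.empty((K, K))
    sd = V.std(axis=1)
    if (sd == 0).any():
        warnings.warn("constant FC vector(s); similarity entries set to NaN",
                      stacklevel=2)
    Vc = V - V.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = Vc @ Vc.T
        out = num / np.outer(np.sqrt((Vc**2).sum(axis=1)),
                             np.sqrt((Vc**2).sum(axis=1)))
    out[sd == 0, :] = np.nan
    out[:, sd == 0] = np.nan
    return out


def build_state_maps(model: HmmModel, pca: PcaModel,
                     roi_networks: list[str] | None = None) -> list[StateMap]:
    """Full per-state map bundle: relative activation, FC, network FC."""
    roi_means, roi_covs = project_to_roi(model, pca)
    rel = relative_activation(roi_means)
    maps = []
    for k in range(model.K):
        fc = state_fc(roi_covs[k])
        net = network_aggregate(fc, roi_networks) if roi_networks else None
        maps.append(StateMap(roi_mean=rel[k], roi_fc=fc, network_fc=net))
    return maps
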