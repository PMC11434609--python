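"""Per-state temporal statistics and sleep-stage correspondence.

A state "visit" is a maximal run of one state in the Viterbi path within one
contiguous segment; lifetime is the mean visit duration in seconds. Each
state's stage distribution is the row-normalized co-occurrence of the state
with the six hypnogram stages, and the winner-takes-all label assigns the
state to its most frequent stage. Cross-night similarity is the Pearson
correlation between two stage-distribution matrices with states aligned by
the frozen model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ParameterError
from .io_preprocess import STAGES


@dataclass
class StateSummary:
    fo: np.ndarray
    mean_lifetime_s: np.ndarray
    stage_dist: np.ndarray  # (K, 6) rows normalized
    wta_stage: list[str]
    stages: tuple[str, ...] = STAGES

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stage_dist, columns=list(self.stages))
        df.insert(0, "state", np.arange(len(self.fo)))
        df.insert(1, "fo", self.fo)
        df.insert(2, "lifetime_s", self.mean_lifetime_s)
        df["wta_stage"] = self.wta_stage
        return df


def _visits(path: np.ndarray, segments) -> list[tuple[int, int]]:
    """(state, run length) for every maximal within-segment run."""
    out = []
    for s, e in segments:
        t = s
        while t < e:
            u = t
            while u < e and path[u] == path[t]:
                u += 1
            out.append((int(path[t]), u - t))
            t = u
    return out


def lifetimes(path, segments, tr_seconds: float, K: int | None = None) -> np.ndarray:
    """Per-state mean visit duration in seconds.

    Visits truncated by a segment boundary count at their observed length;
    a state that is never visited gets NaN.
    """
    path = np.asarray(path, dtype=int)
    if K is None:
        K = int(path.max()) + 1 if path.size else 0
    sums = np.zeros(K)
    counts = np.zeros(K)
    for state, length in _visits(path, segments):
        sums[state] += length
        counts[state] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1) * tr_seconds, np.nan)


def stage_distribution(path, hypnogram, K: int | None = None,
                       stages: tuple[str, ...] = STAGES) -> np.ndarray:
    """(K, 6) matrix: row k = fraction of state k's frames in each stage.

    Rows of never-visited states are left all-zero (winner-takes-all raises
    on them)."""
    path = np.asarray(path, dtype=int)
    hypnogram = np.asarray(hypnogram)
    if len(path) != len(hypnogram):
        raise ParameterError("path and hypnogram lengths differ")
    if K is None:
        K = int(path.max()) + 1
    counts = np.zeros((K, len(stages)))
    stage_idx = {s: i for i, s in enumerate(stages)}
    for k, s in zip(path, hypnogram):
        counts[k, stage_idx[str(s)]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    out = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
    return out


def winner_takes_all(stage_dist: np.ndarray,
                     stages: tuple[str, ...] = STAGES) -> list[str]:
    """Assign each state to its most frequent stage; exact ties break by the
    fixed stage priority Wake > N1 > N2 > N3 > REM > Undefined."""
    stage_dist = np.atleast_2d(np.asarray(stage_dist, float))
    labels = []
    for row in stage_dist:
        if row.sum() == 0:
            raise ParameterError("all-zero stage-distribution row (state never visited)")
        labels.append(stages[int(np.argmax(row))])
    return labels


def cross_night_correlation(dist_a: np.ndarray, dist_b: np.ndarray) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two flattened K x 6 matrices."""
    a = np.asarray(dist_a, float).ravel()
    b = np.asarray(dist_b, float).ravel()
    if a.shape != b.shape:
        raise ParameterError("stage-distribution matrices must have identical shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("zero variance in a stage-distribution matrix")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def summarize(gamma, viterbi, hypnogram, segments, tr_seconds: float) -> StateSummary:
    """Full per-state summary from one decoded night."""
    gamma = np.atleast_2d(np.asarray(gamma, float))
    K = gamma.shape[1]
    fo = gamma.mean(axis=0)
    lt = lifetimes(viterbi, segments, tr_seconds, K=K)
    dist = stage_distribution(viterbi, hypnogram, K=K)
    wta = []
    for row in dist:
        wta.append(STAGES[int(np.argmax(row))] if row.sum() > 0 else "unvisited")
    return StateSummary(fo=fo, mean_lifetime_s=lt, stage_dist=dist, wta_stage=wta)
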