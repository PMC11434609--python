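"""Directed modularity analysis of the state transition matrix.

Self-transitions dominate a sleep-state transition matrix (states persist
for several frames), so the matrix is first off-diagonal renormalized: the
diagonal is zeroed and each row rescaled to sum to one, leaving only the
between-state transition structure. Communities ("transition modules") are
then found by maximizing the Leicht-Newman directed modularity

    Q = (1/m) sum_ij [ W_ij - k_i^out k_j^in / m ] delta(c_i, c_j)

via recursive spectral bisection of the symmetrized modularity matrix
(B + B^T)/2 with Kernighan-Lin-style fine-tuning; splitting stops when no
bisection increases Q. The number of modules is emergent, not fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError


@dataclass
class ModulePartition:
    assignment: np.ndarray  # per-state module index, contiguous from 0
    q: float
    n_modules: int


def off_diagonal_normalize(A: np.ndarray) -> np.ndarray:
    """Zero the diagonal and renormalize each row to sum to 1.

    Rows with no off-diagonal mass are left as zero rows with a warning."""
    A = np.asarray(A, float)
    K = A.shape[0]
    if A.ndim != 2 or A.shape[1] != K:
        raise ParameterError("A must be square")
    if K < 2:
        raise ParameterError("need at least 2 states")
    W = A.copy()
    np.fill_diagonal(W, 0.0)
    sums = W.sum(axis=1)
    dead = sums == 0
    if dead.any():
        warnings.warn(f"rows {np.flatnonzero(dead).tolist()} have no off-diagonal mass",
                      stacklevel=2)
    sums[dead] = 1.0
    return W / sums[:, None]


def modularity_score(W: np.ndarray, assignment: np.ndarray) -> float:
    """Directed modularity Q of a given partition."""
    W = np.asarray(W, float)
    m = W.sum()
    if m <= 0:
        raise ParameterError("W has no mass")
    kout = W.sum(axis=1)
    kin = W.sum(axis=0)
    B = W - np.outer(kout, kin) / m
    assignment = np.asarray(assignment)
    same = assignment[:, None] == assignment[None, :]
    return float((B * same).sum() / m)


def _kl_refine(Bsym: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin fine-tuning of a +-1 split vector.

    Repeated passes; in each pass every node is flipped exactly once in
    greedy order and the best intermediate configuration is kept if it
    improves the quadratic form s^T Bsym s. Deterministic (ascending index
    tie-break)."""
    n = len(s)
    s = s.copy()

    def qform(v):
        return float(v @ Bsym @ v)

    improved = True
    while improved:
        improved = False
        best_val = qform(s)
        trial = s.copy()
        moved = np.zeros(n, dtype=bool)
        seq_best_val = best_val
        seq_best = None
        for _ in range(n):
            # gain of flipping node i: -4 s_i (Bsym s)_i + 4 B_ii
            g = -4.0 * trial * (Bsym @ trial) + 4.0 * np.diag(Bsym)
            g[moved] = -np.inf
            i = int(np.argmax(g))
            trial[i] = -trial[i]
            moved[i] = True
            val = qform(trial)
            if val > seq_best_val + 1e-12:
                seq_best_val = val
                seq_best = trial.copy()
        if seq_best is not None:
            s = seq_best
            improved = True
    return s


def directed_modularity(W: np.ndarray, symmetric: bool = False,
                        tol: float = 1e-12) -> ModulePartition:
    """Partition states by recursive spectral bisection of the modularity
    matrix; ``symmetric=True`` replaces the directed null model with the
    undirected one on (W + W^T)/2."""
    W = np.asarray(W, float)
    K = W.shape[0]
    if W.ndim != 2 or W.shape[1] != K or K < 2:
        raise ParameterError("W must be square with K >= 2")
    if (W < 0).any():
        raise ParameterError("W must be nonnegative")
    m = W.sum()
    if m <= 0:
        raise ParameterError("all-zero transition matrix")
    if symmetric:
        W = 0.5 * (W + W.T)
        m = W.sum()
    kout = W.sum(axis=1)
    kin = W.sum(axis=0)
    B = W - np.outer(kout, kin) / m
    Bsym = B + B.T  # Q(partition) = sum_same Bsym_ij / (2 m)

    assignment = np.zeros(K, dtype=int)
    next_label = [1]

    def split_group(members: np.ndarray) -> None:
        """Recursive bisection using the generalized modularity matrix."""
        if len(members) < 2:
            return
        Bg = Bsym[np.ix_(members, members)].copy()
        np.fill_diagonal(Bg, np.diag(Bg) - Bg.sum(axis=1))
        _, evecs = np.linalg.eigh(Bg)
        v = evecs[:, -1]
        s = np.where(v >= 0, 1.0, -1.0)
        s = _kl_refine(Bg, s)
        dq = float(s @ Bg @ s) / (2.0 * m)
        if dq <= tol:
            return
        left = members[s > 0]
        right = members[s < 0]
        if len(left) == 0 or len(right) == 0:
            return
        lab = next_label[0]
        next_label[0] += 1
        assignment[right] = lab
        split_group(left)
        split_group(right)

    split_group(np.arange(K))
    # relabel contiguously in order of first appearance
    _, assignment = np.unique(assignment, return_inverse=True)
    order = {}
    relabeled = np.empty(K, dtype=int)
    for i, a in enumerate(assignment):
        if a not in order:
            order[a] = len(order)
        relabeled[i] = order[a]
    q = modularity_score(W, relabeled)
    return ModulePartition(assignment=relabeled, q=q, n_modules=int(relabeled.max()) + 1)


def brute_force_modularity(W: np.ndarray) -> ModulePartition:
    """Exhaustive search over all set partitions (small K only); the oracle
    counterpart of :func:`directed_modularity`."""
    W = np.asarray(W, float)
    K = W.shape[0]
    if K > 10:
        raise ParameterError("brute force limited to K <= 10")

    best_q = -np.inf
    best = None

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [[first] + block] + part[i + 1:]
            yield [[first]] + part

    for part in partitions(list(range(K))):
        assign = np.empty(K, dtype=int)
        for i, block in enumerate(part):
            assign[block] = i
        q = modularity_score(W, assign)
        if q > best_q:
            best_q = q
            best = assign
    # contiguous relabel in order of appearance
    order = {}
    relab = np.empty(K, dtype=int)
    for i, a in enumerate(best):
        if a not in order:
            order[a] = len(order)
        relab[i] = order[a]
    return ModulePartition(assignment=relab, q=float(best_q),
                           n_modules=int(relab.max()) + 1)


def module_stage_profile(partition: ModulePartition, stage_dist: np.ndarray,
                         fo: np.ndarray) -> np.ndarray:
    """(n_modules, 6) FO-weighted average stage distribution per module."""
    stage_dist = np.atleast_2d(np.asarray(stage_dist, float))
    fo = np.asarray(fo, float)
    K = stage_dist.shape[0]
    if len(partition.assignment) != K or len(fo) != K:
        raise ParameterError("partition, stage_dist and fo must share K")
    out = np.zeros((partition.n_modules, stage_dist.shape[1]))
    for mdl in range(partition.n_modules):
        members = np.flatnonzero(partition.assignment == mdl)
        if members.size == 0:
            raise ParameterError(f"module {mdl} is empty")
        w = fo[members]
        if w.sum() == 0:
            w = np.ones(members.size)
        w = w / w.sum()
        row = w @ stage_dist[members]
        total = row.sum()
        out[mdl] = row / total if total > 0 else row
    return out
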