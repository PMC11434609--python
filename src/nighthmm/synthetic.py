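"""Hypnogram-structured multi-state Gaussian time-series generator.

The generator emulates the structure of a whole-night sleep fMRI recording:
a hypnogram cycles through the six polysomnography stages (Wake, N1, N2, N3,
REM, Undefined) with gamma-distributed bout durations; within each stage
bout a Markov chain switches among the brain states "pooled" under that
stage; each state emits multivariate Gaussian observations with a
state-specific mean activation pattern and covariance (the ground-truth
analog of a state's functional-connectivity matrix).

Stage bouts are gamma-distributed (super-Markov persistence, as real sleep
bouts are), while within-stage state dwells stay geometric — matching the
Markov assumption of the model that will be fitted. Default dwell means are
chosen so state lifetimes land in the 8.7-36 s range typical of fMRI-derived
sleep states at TR = 3 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, ParameterError
from .io_preprocess import (
    STAGES,
    RoiTimeSeries,
    read_hypnogram,
    read_roi_matrix,
    write_hypnogram,
    write_roi_matrix,
)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: Default stage cycle: (stage, mean bout duration in frames). At TR = 3 s
#: these means span 9-24 s.
DEFAULT_CYCLE: list[tuple[str, float]] = [
    ("Wake", 8.0),
    ("N1", 3.5),
    ("N2", 6.0),
    ("N3", 8.0),
    ("N2", 5.0),
    ("REM", 7.0),
    ("Undefined", 4.0),
]


@dataclass
class HypnogramSpec:
    """Stage-cycling plan for one synthetic night.

    ``dwell_dispersion`` is the coefficient of variation (SD/mean) of the
    gamma bout-duration distribution; 0 gives deterministic bouts.
    """

    cycle_template: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_CYCLE)
    )
    n_cycles: int = 1
    tr_seconds: float = 3.0
    dwell_dispersion: float = 0.4
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.dwell_dispersion < 0:
            raise ParameterError("dwell_dispersion must be >= 0")
        for stage, mean in self.cycle_template:
            if stage not in self.stages:
                raise ParameterError(f"unknown stage {stage!r}")
            if mean < 1:
                raise ParameterError(f"mean dwell for {stage} must be >= 1 frame")


@dataclass
class GenerativeModel:
    """Ground-truth state model: pools, transitions and Gaussian emissions."""

    K: int
    R: int
    stage_pools: dict[str, list[int]]
    A: np.ndarray
    pi: np.ndarray
    means: np.ndarray
    covs: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        if self.A.shape != (self.K, self.K):
            raise ParameterError("A must be K x K")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-12):
            raise ParameterError("rows of A must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-12):
            raise ParameterError("pi must sum to 1")
        if self.means.shape != (self.K, self.R) or self.covs.shape != (self.K, self.R, self.R):
            raise ParameterError("means/covs shapes inconsistent with K, R")
        for k in range(self.K):
            if not np.allclose(self.covs[k], self.covs[k].T, atol=1e-10):
                raise ParameterError(f"cov of state {k} is not symmetric")
            try:
                np.linalg.cholesky(self.covs[k])
            except np.linalg.LinAlgError:
                raise ParameterError(f"cov of state {k} is not positive-definite") from None
        pooled = set()
        for states in self.stage_pools.values():
            pooled.update(states)
        if pooled != set(range(self.K)):
            raise ParameterError("every state must belong to at least one stage pool")


@dataclass
class SyntheticDataset:
    """One participant-night with full ground truth attached."""

    observations: RoiTimeSeries
    true_path: np.ndarray
    hypnogram: np.ndarray
    model: GenerativeModel
    seed: int

    def __post_init__(self) -> None:
        n = self.observations.n_frames
        if len(self.true_path) != n or len(self.hypnogram) != n:
            raise ParameterError("observations, true_path, hypnogram frame counts differ")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_hypnogram(spec: HypnogramSpec, seed: int) -> np.ndarray:
    """Draw per-frame stage labels following the cycle template.

    Each bout duration is a gamma draw with the template's mean and the
    spec's coefficient of variation, rounded and floored at 1 frame.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    d = spec.dwell_dispersion
    for _ in range(spec.n_cycles):
        for stage, mean in spec.cycle_template:
            if d == 0:
                dwell = max(1, int(round(mean)))
            else:
                shape = 1.0 / d**2
                dwell = max(1, int(round(rng.gamma(shape, mean / shape))))
            labels.extend([stage] * dwell)
    return np.array(labels, dtype=object)


def simulate_state_sequence(
    hypnogram: np.ndarray, model: GenerativeModel, seed: int
) -> np.ndarray:
    """Run a pool-restricted Markov chain inside each stage bout.

    At a bout boundary the chain re-initializes from ``pi`` restricted to the
    new stage's pool; inside a bout it follows ``A`` restricted to the pool
    and row-renormalized.
    """
    rng = np.random.default_rng(seed)
    T = len(hypnogram)
    path = np.empty(T, dtype=int)
    t = 0
    while t < T:
        stage = hypnogram[t]
        end = t
        while end < T and hypnogram[end] == stage:
            end += 1
        pool = model.stage_pools.get(stage, [])
        if not pool:
            raise ConfigurationError(f"stage {stage!r} occurs but has an empty state pool")
        pool = np.asarray(pool)
        p0 = model.pi[pool]
        if p0.sum() == 0:
            p0 = np.ones(len(pool))
        p0 = p0 / p0.sum()
        Ar = model.A[np.ix_(pool, pool)]
        rows = Ar.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        Ar = Ar / rows
        j = rng.choice(len(pool), p=p0)
        path[t] = pool[j]
        for u in range(t + 1, end):
            j = rng.choice(len(pool), p=Ar[j])
            path[u] = pool[j]
        t = end
    return path


def simulate_observations(
    path: np.ndarray, model: GenerativeModel, seed: int, tr_seconds: float = 3.0,
    participant_id: str = "sub-01",
) -> RoiTimeSeries:
    """Emit one Gaussian observation per frame from the frame's state."""
    path = np.asarray(path, dtype=int)
    if path.size and path.max() >= model.K:
        raise ParameterError("path contains state indices >= K")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.covs)
    z = rng.standard_normal((len(path), model.R))
    data = model.means[path] + np.einsum("tij,tj->ti", chol[path], z)
    return RoiTimeSeries(data=data, tr_seconds=tr_seconds, participant_id=participant_id)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_generative_model(K: int = 6, R: int = 20, seed: int = 12345) -> GenerativeModel:
    """Ground-truth model with one state per stage and separable emissions.

    Means are unit-scale Gaussian patterns (well separated in R dimensions);
    covariances are random SPD matrices with eigenvalues in ~[0.4, 1.6] so
    every state carries a distinct connectivity structure. Self-transition
    probability 0.75 gives a geometric mean dwell of 4 frames (12 s at
    TR = 3 s) when several states share a pool.
    """
    rng = np.random.default_rng(seed)
    p_self = 0.75
    A = np.full((K, K), (1 - p_self) / (K - 1))
    np.fill_diagonal(A, p_self)
    pi = np.full(K, 1.0 / K)
    means = rng.normal(0.0, 1.0, size=(K, R))
    covs = np.empty((K, R, R))
    for k in range(K):
        Q, _ = np.linalg.qr(rng.standard_normal((R, R)))
        eig = rng.uniform(0.4, 1.6, size=R)
        covs[k] = (Q * eig) @ Q.T
        covs[k] = 0.5 * (covs[k] + covs[k].T)
    pools = {stage: [k] for k, stage in enumerate(STAGES[:K])}
    return GenerativeModel(K=K, R=R, stage_pools=pools, A=A, pi=pi, means=means, covs=covs)


def make_night(
    model: GenerativeModel,
    n_frames: int = 2000,
    tr_seconds: float = 3.0,
    seed: int = 0,
    participant_id: str = "sub-01",
    spec: HypnogramSpec | None = None,
) -> SyntheticDataset:
    """Generate one participant-night truncated to exactly ``n_frames``.

    With the default hypnogram plan, stages without a state pool in ``model``
    are dropped from the cycle (a reduced-K truth cycles through fewer
    stages)."""
    if spec is None:
        pooled = {s for s, v in model.stage_pools.items() if v}
        template = [(s, m) for s, m in DEFAULT_CYCLE if s in pooled]
        if not template:
            raise ParameterError("model pools cover no stage of the default cycle")
        spec = HypnogramSpec(cycle_template=template, tr_seconds=tr_seconds)
    frames_per_cycle = sum(m for _, m in spec.cycle_template)
    n_cycles = int(np.ceil(1.3 * n_frames / frames_per_cycle)) + 2
    spec = HypnogramSpec(
        cycle_template=spec.cycle_template,
        n_cycles=n_cycles,
        tr_seconds=tr_seconds,
        dwell_dispersion=spec.dwell_dispersion,
        stages=spec.stages,
    )
    hyp = simulate_hypnogram(spec, seed)[:n_frames]
    if len(hyp) < n_frames:  # extremely short draws; pad by regenerating longer
        raise ParameterError("cycle template too short for requested n_frames")
    path = simulate_state_sequence(hyp, model, seed + 1)
    obs = simulate_observations(
        path, model, seed + 2, tr_seconds=tr_seconds, participant_id=participant_id
    )
    return SyntheticDataset(
        observations=obs, true_path=path, hypnogram=hyp, model=model, seed=seed
    )


def make_study(
    model: GenerativeModel | None = None,
    n_participants: int = 3,
    n_frames: int = 2000,
    tr_seconds: float = 3.0,
    seed: int = 0,
) -> list[SyntheticDataset]:
    """Default synthetic study: 3 participants x 2000 frames x 20 channels,
    K_true = 6 states nested in six stages. Per-participant seeds are
    master + 10 * participant index (the three sub-draws of a night use
    seed, seed+1, seed+2)."""
    if model is None:
        model = default_generative_model()
    return [
        make_night(
            model,
            n_frames=n_frames,
            tr_seconds=tr_seconds,
            seed=seed + 10 * p,
            participant_id=f"sub-{p + 1:02d}",
        )
        for p in range(n_participants)
    ]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, directory) -> None:
    """Write observations, hypnogram, sidecar and ground-truth model as text."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_roi_matrix(ds.observations, directory / "bold.tsv", directory / "bold.yaml")
    write_hypnogram(ds.hypnogram, directory / "hypnogram.txt")
    np.savetxt(directory / "true_path.txt", ds.true_path, fmt="%d")
    m = ds.model
    truth = {
        "seed": int(ds.seed),
        "K": m.K,
        "R": m.R,
        "stage_pools": {s: list(map(int, v)) for s, v in m.stage_pools.items()},
        "A": m.A.tolist(),
        "pi": m.pi.tolist(),
        "means": m.means.tolist(),
        "covs": m.covs.tolist(),
    }
    (directory / "truth.json").write_text(json.dumps(truth))


def read_dataset(directory) -> SyntheticDataset:
    import json

    directory = Path(directory)
    obs = read_roi_matrix(directory / "bold.tsv", directory / "bold.yaml")
    hyp = read_hypnogram(directory / "hypnogram.txt")
    path = np.loadtxt(directory / "true_path.txt", dtype=int)
    truth = json.loads((directory / "truth.json").read_text())
    model = GenerativeModel(
        K=truth["K"],
        R=truth["R"],
        stage_pools={s: list(v) for s, v in truth["stage_pools"].items()},
        A=np.array(truth["A"]),
        pi=np.array(truth["pi"]),
        means=np.array(truth["means"]),
        covs=np.array(truth["covs"]),
    )
    return SyntheticDataset(
        observations=obs, true_path=path, hypnogram=hyp, model=model, seed=truth["seed"]
    )
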