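"""Reading/writing ROI time-series artifacts and preprocessing.

The on-disk layout is deliberately plain text: a tab-separated frames x ROIs
matrix with a header of ROI names, a YAML sidecar carrying the repetition
time, run-segment boundaries and the per-frame censor mask, a hypnogram with
one sleep-stage label per line, and a two-column ROI -> network table.

Preprocessing follows the standard group-HMM recipe: per-participant
standardization of every ROI channel (mean 0, sample SD 1 over the
uncensored frames), temporal concatenation across participants with censored
frames removed (a censored frame splits its run segment in two, so the HMM
never counts a transition across the gap), and PCA dimensionality reduction
of the concatenated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .exceptions import FormatError, PreprocessingError

#: The six hypnogram labels, in fixed priority order (used for winner-takes-all
#: tie-breaks downstream).
STAGES: tuple[str, ...] = ("Wake", "N1", "N2", "N3", "REM", "Undefined")

_FLOAT_FMT = "%.17g"  # lossless for float64 round-trips


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RoiTimeSeries:
    """One participant-night of ROI signals.

    data : (frames, channels) array
    tr_seconds : repetition time (one frame) in seconds
    segments : list of 0-based half-open [start, end) frame intervals, one per
        contiguous run; disjoint and ordered
    censor_mask : boolean per frame, True = keep
    """

    data: np.ndarray
    tr_seconds: float
    participant_id: str = "sub-01"
    segments: list[tuple[int, int]] = field(default_factory=list)
    censor_mask: np.ndarray | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("ROI time series must be a 2-D frames x channels matrix")
        n = self.n_frames
        if self.tr_seconds <= 0:
            raise FormatError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not self.segments:
            self.segments = [(0, n)]
        prev_end = 0
        for s, e in self.segments:
            if not (0 <= s < e <= n) or s < prev_end:
                raise FormatError(f"segments must be disjoint, ordered, within [0, {n}): {self.segments}")
            prev_end = e
        if self.censor_mask is None:
            self.censor_mask = np.ones(n, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.shape != (n,):
                raise FormatError("censor mask length must equal the frame count")
        if self.channel_names is None:
            self.channel_names = [f"ROI{i + 1:03d}" for i in range(self.n_channels)]
        elif len(self.channel_names) != self.n_channels:
            raise FormatError("channel_names length must equal the channel count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class ConcatData:
    """Concatenated multi-participant matrix with censored frames removed."""

    data: np.ndarray
    segment_index: np.ndarray  # per-frame contiguous-segment id
    participant_index: np.ndarray  # per-frame participant id
    tr_seconds: float
    channel_names: list[str]
    participant_ids: list[str]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Half-open [start, end) intervals of each contiguous segment."""
        ids = self.segment_index
        bounds = np.flatnonzero(np.diff(ids)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(ids)]])
        return list(zip(starts.tolist(), ends.tolist()))


@dataclass
class PcaModel:
    """PCA loadings used to reduce (and later back-project) ROI signals.

    ``mixing`` is channels x n_components with orthonormal columns; scores are
    ``(data - channel_means) @ mixing`` and are *not* whitened, so state
    covariances stay interpretable after back-projection.
    """

    mixing: np.ndarray
    component_variances: np.ndarray
    total_variance: float
    n_components: int
    channel_means: np.ndarray

    @property
    def explained_variance_fraction(self) -> float:
        return float(self.component_variances.sum() / self.total_variance)

    def transform(self, data: np.ndarray) -> np.ndarray:
        if data.shape[1] != self.mixing.shape[0]:
            raise FormatError(
                f"data has {data.shape[1]} channels, PCA expects {self.mixing.shape[0]}"
            )
        return (data - self.channel_means) @ self.mixing


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_roi_matrix(ts: RoiTimeSeries, path, sidecar_path) -> None:
    """Write the frames x ROIs matrix (TSV) plus its YAML sidecar."""
    df = pd.DataFrame(ts.data, columns=ts.channel_names)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "tr_seconds": float(ts.tr_seconds),
        "participant_id": ts.participant_id,
        "segments": [[int(s), int(e)] for s, e in ts.segments],
        "censor_mask": "".join("1" if k else "0" for k in ts.censor_mask),
    }
    Path(sidecar_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_roi_matrix(path, sidecar_path) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    meta = yaml.safe_load(Path(sidecar_path).read_text())
    mask = np.array([c == "1" for c in str(meta["censor_mask"])], dtype=bool)
    if mask.shape[0] != len(df):
        raise FormatError(
            f"sidecar censor mask has {mask.shape[0]} frames, matrix has {len(df)}"
        )
    return RoiTimeSeries(
        data=df.to_numpy(dtype=float),
        tr_seconds=float(meta["tr_seconds"]),
        participant_id=str(meta.get("participant_id", "sub-01")),
        segments=[tuple(seg) for seg in meta["segments"]],
        censor_mask=mask,
        channel_names=list(df.columns),
    )


def write_hypnogram(labels, path) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


def read_hypnogram(path) -> np.ndarray:
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    bad = sorted(set(labels) - set(STAGES))
    if bad:
        raise FormatError(f"unknown sleep-stage labels {bad}; allowed: {list(STAGES)}")
    return np.array(labels, dtype=object)


def read_network_table(path) -> dict[str, str]:
    """Two-column TSV (ROI name, network name) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("network table needs two columns: ROI, network")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_network_table(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        {"roi": list(mapping), "network": [mapping[r] for r in mapping]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def standardize(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Scale each channel to mean 0, sample SD 1 over the uncensored frames.

    The affine transform estimated on the kept frames is applied to every
    frame, so censored frames remain aligned. Sample SD uses denominator n-1.
    """
    kept = ts.data[ts.censor_mask]
    if kept.shape[0] < 2:
        raise PreprocessingError("need at least 2 uncensored frames to standardize")
    mean = kept.mean(axis=0)
    sd = kept.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [ts.channel_names[i] for i in zero]
        raise PreprocessingError(f"zero-variance channel(s): {names}")
    return replace(ts, data=(ts.data - mean) / sd)


def concatenate(sessions: list[RoiTimeSeries]) -> ConcatData:
    """Stack sessions in participant order, dropping censored frames.

    A censored frame splits its declared segment, so no state transition is
    ever counted across the gap.
    """
    if not sessions:
        raise PreprocessingError("cannot concatenate an empty session list")
    ref = sessions[0]
    blocks, seg_ids, part_ids = [], [], []
    seg_counter = 0
    for p, ts in enumerate(sessions):
        if ts.n_channels != ref.n_channels or ts.channel_names != ref.channel_names:
            raise PreprocessingError(
                f"session {ts.participant_id} channel layout differs from {ref.participant_id}"
            )
        for s, e in ts.segments:
            mask = ts.censor_mask[s:e]
            # maximal runs of kept frames inside this declared segment
            idx = np.flatnonzero(mask) + s
            if idx.size == 0:
                continue
            splits = np.flatnonzero(np.diff(idx) > 1) + 1
            for run in np.split(idx, splits):
                blocks.append(ts.data[run])
                seg_ids.append(np.full(run.size, seg_counter))
                part_ids.append(np.full(run.size, p))
                seg_counter += 1
    if not blocks:
        raise PreprocessingError("all frames are censored")
    return ConcatData(
        data=np.vstack(blocks),
        segment_index=np.concatenate(seg_ids),
        participant_index=np.concatenate(part_ids),
        tr_seconds=ref.tr_seconds,
        channel_names=list(ref.channel_names),
        participant_ids=[ts.participant_id for ts in sessions],
    )


def fit_pca(data: ConcatData, n_components: int) -> tuple[PcaModel, np.ndarray]:
    """SVD-based PCA of the column-centered concatenated matrix.

    Returns the fitted model and the unwhitened component scores
    (frames x n_components).
    """
    X = data.data
    if n_components > min(X.shape):
        raise PreprocessingError(
            f"n_components={n_components} exceeds min(frames, channels)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", whiten=False)
    scores = pca.fit_transform(X)
    model = PcaModel(
        mixing=pca.components_.T.copy(),
        component_variances=pca.explained_variance_.copy(),
        total_variance=float(np.var(X, axis=0, ddof=1).sum()),
        n_components=n_components,
        channel_means=pca.mean_.copy(),
    )
    return model, scores


def write_pca_model(model: PcaModel, path) -> None:
    import json

    payload = {
        "n_components": model.n_components,
        "total_variance": model.total_variance,
        "component_variances": model.component_variances.tolist(),
        "channel_means": model.channel_means.tolist(),
        "mixing": model.mixing.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_pca_model(path) -> PcaModel:
    import json

    payload = json.loads(Path(path).read_text())
    return PcaModel(
        mixing=np.array(payload["mixing"]),
        component_variances=np.array(payload["component_variances"]),
        total_variance=float(payload["total_variance"]),
        n_components=int(payload["n_components"]),
        channel_means=np.array(payload["channel_means"]),
    )
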