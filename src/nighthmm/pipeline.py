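"""Pipeline orchestration: config validation, staged execution, provenance.

A single YAML config drives the whole analysis: simulate (or load) ->
standardize/concatenate/PCA -> optional model-order scan -> VB-HMM fit ->
state statistics, transition modules, state maps -> optional frozen-model
application to a second night. One master seed fans out to fixed per-stage
offsets so stages are reproducible in isolation; every table is stamped with
the config hash, seed and package version in a '#' header line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .hmm import apply_model, fit, model_to_json
from .io_preprocess import (
    ConcatData,
    concatenate,
    fit_pca,
    read_hypnogram,
    read_roi_matrix,
    standardize,
    write_pca_model,
)
from .selection import scan_orders
from .state_maps import build_state_maps, fc_similarity, project_to_roi, relative_activation, state_fc
from .state_stats import cross_night_correlation, summarize
from .synthetic import default_generative_model, make_study, write_dataset
from .transitions import directed_modularity, module_stage_profile, off_diagonal_normalize

logger = logging.getLogger("nighthmm")

# master-seed offsets per stage
SEED_SIMULATE = 0
SEED_SIMULATE_NIGHT1 = 500
SEED_HMM = 100
SEED_SCAN = 200

_TOP_KEYS = {"output_dir", "seed", "synthetic", "inputs", "apply_night",
             "preprocessing", "hmm", "stats", "modularity", "maps"}
_SYN_KEYS = {"n_participants", "n_frames", "n_channels", "k_true", "tr_seconds",
             "model_seed"}
_HMM_KEYS = {"k", "k_range", "n_restarts", "tol", "max_iter"}


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    apply_night: dict | None = None
    preprocessing: dict = field(default_factory=lambda: {"n_components": 13})
    hmm: dict = field(default_factory=lambda: {"k": 6})
    stats: dict = field(default_factory=dict)
    modularity: dict = field(default_factory=lambda: {"symmetric": False})
    maps: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(source) -> PipelineConfig:
    """Parse and validate a config mapping or YAML path; every violation is
    collected and reported at once."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")
    if "output_dir" not in raw:
        problems.append("missing required key: output_dir")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        problems.append(f"seed must be a non-negative integer, got {seed!r}")
    syn = raw.get("synthetic")
    if syn is not None:
        bad = set(syn) - _SYN_KEYS
        if bad:
            problems.append(f"unknown synthetic keys: {sorted(bad)}")
    if raw.get("synthetic") is None and raw.get("inputs") is None:
        problems.append("one of 'synthetic' or 'inputs' is required")
    hmm_cfg = raw.get("hmm", {"k": 6})
    bad = set(hmm_cfg) - _HMM_KEYS
    if bad:
        problems.append(f"unknown hmm keys: {sorted(bad)}")
    if "k" not in hmm_cfg and "k_range" not in hmm_cfg:
        problems.append("hmm needs 'k' or 'k_range'")
    kr = hmm_cfg.get("k_range")
    if kr is not None:
        if len(kr) != 2 or kr[0] > kr[1] or kr[0] < 1:
            problems.append(f"k_range must be [min, max] with 1 <= min <= max, got {kr}")
    ap = raw.get("apply_night")
    if ap is not None:
        bad = set(ap) - {"synthetic", "sessions"}
        if bad:
            problems.append(f"unknown apply_night keys: {sorted(bad)}")
        if not ap.get("synthetic") and "sessions" not in ap:
            problems.append("apply_night needs 'synthetic: true' or 'sessions'")
    nc = raw.get("preprocessing", {}).get("n_components", 13)
    if not isinstance(nc, int) or nc < 1:
        problems.append(f"n_components must be a positive integer, got {nc!r}")
    if problems:
        raise ConfigurationError("; ".join(problems))
    kwargs = {k: raw[k] for k in raw if k in _TOP_KEYS}
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _header(cfg: PipelineConfig, stage: str) -> str:
    return (f"# nighthmm v{__version__} stage={stage} "
            f"config={cfg.config_hash} seed={cfg.seed}\n")


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg, stage))
        df.to_csv(fh, sep="\t", index=index, float_format="%.12g")


def _load_night(cfg: PipelineConfig, which: str):
    """Return (sessions, hypnograms, truth_or_none) for 'train' or 'apply'."""
    seed = cfg.seed + (SEED_SIMULATE if which == "train" else SEED_SIMULATE_NIGHT1)
    synthetic = cfg.synthetic is not None and (
        which == "train" or (cfg.apply_night or {}).get("synthetic", False)
    )
    if synthetic:
        syn = dict(cfg.synthetic)
        model = default_generative_model(
            K=syn.get("k_true", 6), R=syn.get("n_channels", 20),
            seed=syn.get("model_seed", 12345),
        )
        study = make_study(
            model,
            n_participants=syn.get("n_participants", 3),
            n_frames=syn.get("n_frames", 2000),
            tr_seconds=syn.get("tr_seconds", 3.0),
            seed=seed,
        )
        sessions = [ds.observations for ds in study]
        hyps = [ds.hypnogram for ds in study]
        return sessions, hyps, study
    spec = cfg.inputs if which == "train" else cfg.apply_night
    sessions, hyps = [], []
    for item in spec["sessions"]:
        sessions.append(read_roi_matrix(item["matrix"], item["sidecar"]))
        hyps.append(read_hypnogram(item["hypnogram"]))
    return sessions, hyps, None


def _preprocess(sessions, pca=None, n_components: int = 13):
    """Standardize per participant, concatenate, project (fitting PCA if not
    given). Returns (concat, pca, scores)."""
    std = [standardize(ts) for ts in sessions]
    concat = concatenate(std)
    if pca is None:
        pca, scores = fit_pca(concat, n_components)
    else:
        scores = pca.transform(concat.data)
    return concat, pca, scores


def _concat_hypnogram(sessions, hyps) -> np.ndarray:
    """Per-frame stage labels aligned with the censored-concatenated matrix."""
    parts = []
    for ts, hyp in zip(sessions, hyps):
        for s, e in ts.segments:
            keep = ts.censor_mask[s:e]
            parts.append(np.asarray(hyp[s:e])[keep])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config) -> dict:
    """Execute every configured stage; returns the key results in memory and
    writes all artifacts under ``output_dir``."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s [%(levelname)s] %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    results: dict = {"config_hash": cfg.config_hash}
    try:
        # ---- stage: inputs -------------------------------------------------
        logger.info("stage=inputs")
        sessions, hyps, study = _load_night(cfg, "train")
        if study is not None:
            for ds in study:
                write_dataset(ds, out / "data" / ds.observations.participant_id)
        tr = sessions[0].tr_seconds

        # ---- stage: preprocess --------------------------------------------
        logger.info("stage=preprocess")
        nc = cfg.preprocessing.get("n_components", 13)
        concat, pca, scores = _preprocess(sessions, n_components=nc)
        hyp_cat = _concat_hypnogram(sessions, hyps)
        _write_table(pd.DataFrame(scores), out / "scores.tsv", cfg, "preprocess")
        write_pca_model(pca, out / "pca.json")
        results["pca_variance_fraction"] = pca.explained_variance_fraction
        logger.info("PCA: %d components retain %.1f%% variance",
                    nc, 100 * pca.explained_variance_fraction)

        # ---- stage: model order -------------------------------------------
        hmm_cfg = dict(cfg.hmm)
        restarts = hmm_cfg.get("n_restarts", 5)
        tol = hmm_cfg.get("tol", 1e-5)
        max_iter = hmm_cfg.get("max_iter", 500)
        if "k_range" in hmm_cfg:
            logger.info("stage=select-k")
            kmin, kmax = hmm_cfg["k_range"]
            scan = scan_orders(
                scores, range(kmin, kmax + 1), segments=concat.segments,
                tr_seconds=tr, labels=hyp_cat, n_restarts=restarts,
                max_iter=max_iter, tol=tol, seed=cfg.seed + SEED_SCAN,
            )
            _write_table(scan.to_frame(), out / "order_scan.tsv", cfg, "select-k")
            K = scan.chosen_k
            results["chosen_k"] = K
            logger.info("chosen K=%d (free-energy first local minimum)", K)
        else:
            K = hmm_cfg["k"]

        # ---- stage: fit ----------------------------------------------------
        logger.info("stage=fit K=%d", K)
        res = fit(scores, K, segments=concat.segments, max_iter=max_iter,
                  tol=tol, n_restarts=restarts, seed=cfg.seed + SEED_HMM)
        (out / "model.json").write_text(
            model_to_json(res.model, pca_hash=hashlib.sha256(
                pca.mixing.tobytes()).hexdigest()[:12]))
        results["free_energy"] = res.free_energy
        results["converged"] = res.converged

        # ---- stage: stats --------------------------------------------------
        logger.info("stage=stats")
        summary = summarize(res.posteriors.gamma, res.posteriors.viterbi,
                            hyp_cat, concat.segments, tr)
        _write_table(summary.to_frame(), out / "state_summary.tsv", cfg, "stats")
        results["summary"] = summary

        # ---- stage: modules ------------------------------------------------
        logger.info("stage=modules")
        A = res.model.A
        _write_table(pd.DataFrame(A), out / "transition_matrix.tsv", cfg, "modules")
        W = off_diagonal_normalize(A)
        part = directed_modularity(W, symmetric=cfg.modularity.get("symmetric", False))
        _write_table(
            pd.DataFrame({"state": np.arange(K), "module": part.assignment}),
            out / "modules.tsv", cfg, "modules")
        profiles = module_stage_profile(part, summary.stage_dist, summary.fo)
        _write_table(pd.DataFrame(profiles, columns=list(summary.stages)),
                     out / "module_profiles.tsv", cfg, "modules")
        results["partition"] = part
        logger.info("found %d transition modules, Q=%.4f", part.n_modules, part.q)

        # ---- stage: maps ---------------------------------------------------
        logger.info("stage=maps")
        roi_means, roi_covs = project_to_roi(res.model, pca)
        rel = relative_activation(roi_means)
        _write_table(pd.DataFrame(rel, columns=concat.channel_names),
                     out / "activation.tsv", cfg, "maps")
        fcs = np.stack([state_fc(roi_covs[k]) for k in range(K)])
        sim = fc_similarity(fcs)
        _write_table(pd.DataFrame(sim), out / "fc_similarity.tsv", cfg, "maps")
        results["fc_similarity"] = sim

        # ---- stage: apply (second night) -----------------------------------
        if cfg.apply_night is not None:
            logger.info("stage=apply")
            sessions1, hyps1, study1 = _load_night(cfg, "apply")
            concat1, _, scores1 = _preprocess(sessions1, pca=pca)
            hyp_cat1 = _concat_hypnogram(sessions1, hyps1)
            post1 = apply_model(scores1, res.model, segments=concat1.segments)
            summary1 = summarize(post1.gamma, post1.viterbi, hyp_cat1,
                                 concat1.segments, tr)
            _write_table(summary1.to_frame(), out / "apply_state_summary.tsv",
                         cfg, "apply")
            r, p = cross_night_correlation(summary.stage_dist, summary1.stage_dist)
            _write_table(pd.DataFrame({"pearson_r": [r], "p_value": [p]}),
                         out / "cross_night.tsv", cfg, "apply")
            results["cross_night_r"] = r
            results["cross_night_p"] = p
            results["apply_summary"] = summary1
            logger.info("cross-night stage-distribution r=%.4f (p=%.2g)", r, p)
        return results
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
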