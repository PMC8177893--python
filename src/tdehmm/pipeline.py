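"""End-to-end orchestration: simulate -> preprocess -> fit -> spectra ->
modes -> networks -> match -> temporal, with per-stage artefacts and resume.

Every stage writes its outputs under a run directory; a stage whose outputs
already exist is skipped, so a partially failed run resumes from the last
completed stage.  A manifest records the configuration, its hash, package
versions and timestamps.  Defaults reproduce the reference configuration:
250 Hz, 60 ms embedding window, PCA to 2N components, K = 6 states,
transition prior diagonal 10, 7 tapers at time-bandwidth 4, 0.5 Hz bins,
1-45 Hz band, 4 frequency modes, alpha = 0.05, 100 ms lifetime filter.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .datatypes import ConcatenatedDataset
from .embedding import EmbeddedData, embed_dataset
from .hmm import VBGaussianHMM
from .io import read_timeseries, write_dataset, write_json, write_timeseries, read_dataset, read_json
from .matching import match_models
from .modes import build_group_coherence, nnmf_frequency_modes, project_onto_modes
from .network_stats import gmm_threshold, intermed_ttests
from .preprocessing import preprocess_cohort
from .spectra import compute_state_spectra, StateSpectra
from .synthetic import demo_cohort_spec, demo_state_specs, generate_cohort
from .temporal import anova_temporal, compute_temporal_metrics

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ["simulate", "preprocess", "fit", "spectra", "modes", "networks", "match", "temporal"]


@dataclass
class PipelineConfig:
    """All stage parameters, with defaults matching the reference study."""

    fs: float = 250.0
    window_ms: float = 60.0
    n_components: int | None = None  # None -> 2 x n_channels
    n_states: int = 6
    transition_prior_diag: float = 10.0
    n_tapers: int = 7
    time_bandwidth: float = 4.0
    resolution_hz: float = 0.5
    band_lo: float = 1.0
    band_hi: float = 45.0
    n_modes: int = 4
    alpha: float = 0.05
    min_lifetime_ms: float = 100.0
    seed: int = 0
    # synthetic-cohort parameters (used when no input data is given)
    n_subjects: int = 2
    duration_s: float = 120.0
    two_conditions: bool = True
    # optimiser knobs
    hmm_n_iter: int = 40
    hmm_n_init: int = 5
    hmm_stochastic: bool = False
    input_dir: str | None = None

    def validate(self) -> None:
        if self.fs <= 0 or self.window_ms <= 0:
            raise ValueError("fs and window_ms must be positive")
        if self.n_states < 1 or self.n_modes < 1 or self.n_tapers < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.band_lo < self.band_hi < self.fs / 2:
            raise ValueError("band must satisfy 0 < lo < hi < fs/2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _save_embedding(emb: EmbeddedData, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=emb.data)
        f.create_dataset("projection", data=emb.projection)
        f.create_dataset("mean", data=emb.mean)
        f.create_dataset("eigenvalues", data=emb.eigenvalues)
        f.attrs["n_lags"] = emb.n_lags
        f.attrs["n_channels"] = emb.n_channels
        f.attrs["fs"] = emb.fs
        f.create_dataset("boundaries", data=np.asarray(emb.boundaries))


def _load_embedding(path: Path) -> EmbeddedData:
    with h5py.File(path, "r") as f:
        return EmbeddedData(
            data=np.asarray(f["data"]),
            n_lags=int(f.attrs["n_lags"]),
            projection=np.asarray(f["projection"]),
            mean=np.asarray(f["mean"]),
            explained_variance=np.asarray(f["eigenvalues"])[: f["projection"].shape[0]],
            eigenvalues=np.asarray(f["eigenvalues"]),
            n_channels=int(f.attrs["n_channels"]),
            fs=float(f.attrs["fs"]),
            boundaries=[tuple(b) for b in np.asarray(f["boundaries"])],
        )


def _save_hmm(model: VBGaussianHMM, path: Path) -> None:
    post = model.posterior_
    with h5py.File(path, "w") as f:
        f.create_dataset("covariances", data=model.covariances_)
        f.create_dataset("transmat", data=model.transmat_)
        f.create_dataset("startprob", data=model.startprob_)
        f.create_dataset("free_energy_trace", data=model.free_energy_trace_)
        f.create_dataset("gamma", data=post.gamma)
        f.create_dataset("xi", data=post.xi)
        f.create_dataset("viterbi", data=post.viterbi_path)
        f.create_dataset("boundaries", data=np.asarray(post.boundaries))


def _save_spectra(sp: StateSpectra, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("psd", data=sp.psd)
        f.create_dataset("coherence", data=sp.coherence)
        f.create_dataset("freqs", data=sp.freqs)
        f.attrs["fs"] = sp.fs
        f.attrs["n_tapers"] = sp.n_tapers
        f.attrs["time_bandwidth"] = sp.time_bandwidth


def _load_spectra(path: Path) -> StateSpectra:
    with h5py.File(path, "r") as f:
        return StateSpectra(
            psd=np.asarray(f["psd"]), coherence=np.asarray(f["coherence"]),
            freqs=np.asarray(f["freqs"]), fs=float(f.attrs["fs"]),
            n_tapers=int(f.attrs["n_tapers"]), time_bandwidth=float(f.attrs["time_bandwidth"]),
        )


def run_pipeline(config: PipelineConfig, run_dir: str | Path, stages: list[str] | None = None) -> dict:
    """Execute the pipeline, resuming past completed stages.

    Returns a dict of artefact paths.  Deterministic under a fixed config
    (including its seed): numeric artefacts are byte-identical across runs.
    """
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    log_path = run_dir / "run.log"

    def log(msg: str) -> None:
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    artefacts: dict[str, Path] = {}
    conditions = ["A", "B"] if config.two_conditions else ["A"]

    # ---- simulate ---------------------------------------------------------
    cohort_dir = run_dir / "cohort"
    gt_path = cohort_dir / "ground_truth.json"
    if "simulate" in stages and config.input_dir is None:
        if not gt_path.exists():
            log(f"simulate: seed={config.seed}")
            spec = demo_cohort_spec(
                n_subjects=config.n_subjects, duration_s=config.duration_s,
                seed=config.seed, two_conditions=config.two_conditions,
            )
            data, gt = generate_cohort(spec, demo_state_specs())
            cohort_dir.mkdir(exist_ok=True)
            for cond, subjects in data.items():
                for ts in subjects:
                    write_timeseries(ts, cohort_dir / f"{cond}_{ts.subject_id}.h5")
            write_json(gt_path, {
                "n_states": gt.n_states, "fs": gt.fs,
                "sequences": {c: [s.tolist() for s in seqs] for c, seqs in gt.sequences.items()},
                "permutations": gt.permutations,
                "coherence_edges": {
                    c: {str(k): v for k, v in d.items()} for c, d in gt.coherence_edges.items()
                },
            })
        artefacts["ground_truth"] = gt_path

    # ---- preprocess -------------------------------------------------------
    for cond in conditions:
        out = run_dir / f"preprocessed_{cond}.h5"
        if "preprocess" in stages and not out.exists():
            log(f"preprocess: condition {cond}")
            src = Path(config.input_dir) if config.input_dir else cohort_dir
            files = sorted(src.glob(f"{cond}_*.h5")) + sorted(src.glob(f"{cond}_*.tsv"))
            if not files:
                raise FileNotFoundError(f"no input files for condition {cond} under {src}")
            subjects = [read_timeseries(p) for p in files]
            ds = preprocess_cohort(subjects, seed=config.seed)
            write_dataset(ds, out)
        artefacts[f"preprocessed_{cond}"] = out

    # ---- fit --------------------------------------------------------------
    for cond in conditions:
        emb_out = run_dir / f"embedding_{cond}.h5"
        hmm_out = run_dir / f"hmm_{cond}.h5"
        if "fit" in stages and not hmm_out.exists():
            log(f"fit: condition {cond} (K={config.n_states})")
            ds = read_dataset(artefacts[f"preprocessed_{cond}"])
            emb = embed_dataset(ds, window_ms=config.window_ms, n_components=config.n_components)
            _save_embedding(emb, emb_out)
            model = VBGaussianHMM(
                n_states=config.n_states,
                transition_prior_diag=config.transition_prior_diag,
                n_iter=config.hmm_n_iter, n_init=config.hmm_n_init,
                stochastic=config.hmm_stochastic, random_state=config.seed,
            ).fit(emb.data.T, lengths=[b - a for a, b in emb.boundaries])
            _save_hmm(model, hmm_out)
        artefacts[f"embedding_{cond}"] = emb_out
        artefacts[f"hmm_{cond}"] = hmm_out

    # ---- spectra ----------------------------------------------------------
    for cond in conditions:
        out = run_dir / f"spectra_{cond}.h5"
        if "spectra" in stages and not out.exists():
            log(f"spectra: condition {cond}")
            ds = read_dataset(artefacts[f"preprocessed_{cond}"])
            emb = _load_embedding(artefacts[f"embedding_{cond}"])
            with h5py.File(artefacts[f"hmm_{cond}"], "r") as f:
                gamma = np.asarray(f["gamma"])
            sp = compute_state_spectra(
                ds, gamma, emb.boundaries, config.n_states, emb.sample_offset,
                n_tapers=config.n_tapers, time_bandwidth=config.time_bandwidth,
                resolution_hz=config.resolution_hz, fmin=config.band_lo, fmax=config.band_hi,
            )
            _save_spectra(sp, out)
        artefacts[f"spectra_{cond}"] = out

    # ---- modes ------------------------------------------------------------
    for cond in conditions:
        out = run_dir / f"modes_{cond}.tsv"
        if "modes" in stages and not out.exists():
            log(f"modes: condition {cond}")
            sp = _load_spectra(artefacts[f"spectra_{cond}"])
            ds = read_dataset(artefacts[f"preprocessed_{cond}"])
            _, group = build_group_coherence(sp, ds.stn_indices, ds.cortical_indices)
            ms = nnmf_frequency_modes(group, sp.freqs, n_modes=config.n_modes, seed=config.seed)
            import pandas as pd

            df = pd.DataFrame({"freq_hz": ms.freqs})
            for i, lab in enumerate(ms.labels):
                df[f"mode_{i}_{lab}"] = ms.modes[i]
            df.to_csv(out, sep="\t", index=False)
        artefacts[f"modes_{cond}"] = out

    # ---- networks ---------------------------------------------------------
    for cond in conditions:
        out = run_dir / f"networks_{cond}.json"
        if "networks" in stages and not out.exists():
            log(f"networks: condition {cond}")
            res, proj, ms = _networks_for(artefacts, cond, config)
            write_json(out, {
                "labels": proj.labels, "alpha": res.alpha, "correction": res.correction,
                "significant": [
                    {"state": int(k), "mode": int(m),
                     "edges": [[int(i), int(j)] for i, j in res.significant_edges(k, m)]}
                    for k in range(res.values.shape[0]) for m in range(res.values.shape[1])
                ],
            })
        artefacts[f"networks_{cond}"] = out

    # ---- match ------------------------------------------------------------
    match_out = run_dir / "match.json"
    if "match" in stages and len(conditions) == 2 and not match_out.exists():
        log("match: A vs B")
        models, embs = {}, {}
        for cond in conditions:
            embs[cond] = _load_embedding(artefacts[f"embedding_{cond}"])
            models[cond] = _hmm_stub(artefacts[f"hmm_{cond}"])
        sm = match_models(models["A"], embs["A"], models["B"], embs["B"])
        write_json(match_out, {
            "distance_matrix": sm.distance_matrix, "pairing": sm.pairing,
            "total_distance": sm.total_distance,
        })
        artefacts["match"] = match_out

    # ---- temporal ---------------------------------------------------------
    temporal_out = run_dir / "temporal_anova.json"
    if "temporal" in stages and len(conditions) == 2 and not temporal_out.exists():
        log("temporal: metrics + ANOVA")
        metrics = {c: [] for c in conditions}
        for cond in conditions:
            with h5py.File(artefacts[f"hmm_{cond}"], "r") as f:
                path = np.asarray(f["viterbi"])
                bounds = np.asarray(f["boundaries"])
            for s, (a, b) in enumerate(bounds):
                metrics[cond].append(compute_temporal_metrics(
                    path[a:b], config.fs, config.n_states,
                    min_lifetime_ms=config.min_lifetime_ms,
                    subject_id=f"sub{s:02d}", condition=cond,
                ))
        results = {}
        for metric in ("fo", "lifetime", "interval"):
            try:
                r = anova_temporal(metrics["A"], metrics["B"], metric=metric)
                results[metric] = {
                    "table": {str(k): dict(v) for k, v in r.table.to_dict("index").items()},
                    "excluded_states": r.excluded_states,
                }
            except ValueError as e:
                results[metric] = {"error": str(e)}
        write_json(temporal_out, results)
        artefacts["temporal"] = temporal_out

    n_pca = config.n_components
    emb_path = artefacts.get("embedding_A")
    if emb_path is not None and Path(emb_path).exists():
        with h5py.File(emb_path, "r") as f:
            n_pca = int(f["projection"].shape[0])
    write_json(run_dir / "manifest.json", {
        "config": asdict(config), "config_hash": config.config_hash(),
        "package_version": __version__, "numpy_version": np.__version__,
        "completed": sorted(str(k) for k in artefacts),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_pca_components": n_pca if n_pca is not None else "2 x n_channels",
    })
    artefacts["manifest"] = run_dir / "manifest.json"
    return artefacts


def _networks_for(artefacts: dict, cond: str, config: PipelineConfig):
    import pandas as pd

    sp = _load_spectra(artefacts[f"spectra_{cond}"])
    modes_df = pd.read_csv(artefacts[f"modes_{cond}"], sep="\t")
    modes = modes_df.drop(columns="freq_hz").to_numpy().T
    labels = [c.split("_", 2)[2] for c in modes_df.columns[1:]]
    from .modes import FrequencyModeSet

    ms = FrequencyModeSet(modes=modes, freqs=modes_df["freq_hz"].to_numpy(), labels=labels)
    proj = project_onto_modes(sp, ms)
    res = gmm_threshold(proj, alpha=config.alpha)
    return res, proj, ms


def _hmm_stub(path: Path) -> VBGaussianHMM:
    """Reload just enough of a saved model for covariance-based matching."""
    m = VBGaussianHMM()
    with h5py.File(path, "r") as f:
        m.covariances_ = np.asarray(f["covariances"])
        m.transmat_ = np.asarray(f["transmat"])
        m.startprob_ = np.asarray(f["startprob"])
        m.free_energy_trace_ = np.asarray(f["free_energy_trace"])
    return m
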