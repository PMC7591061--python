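"""Config-driven orchestration of the full workflow.

One structured config drives the stage chain
denoise -> segment -> syllabize -> embed -> cluster -> metrics -> sequence,
each stage optional.  Input is either a directory of per-bout WAV files
(with an optional segment CSV and noise clip) or an in-memory synthetic
repertoire.  Every run returns a RunReport recording inputs, parameters,
counts and metric results; deterministic fields reproduce exactly for a
fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio import SpectrogramParams, Waveform, read_wav
from .denoise import GateConfig, reduce_noise
from .metrics import cluster_hdbscan, hopkins, overlap, silhouette
from .project import EmbeddingParams, embed_discrete
from .segment import (LowSNRError, SegmentationConfig,
                      dynamic_threshold_segment, read_segments_csv,
                      syllable_dataset_from_bouts)
from .sequence import Corpus, fit_markov


@dataclass
class PipelineConfig:
    input_dir: str | None = None
    noise_clip: str | None = None
    segments_csv: str | None = None
    output_dir: str | None = None
    seed: int = 0
    run_denoise: bool = False
    run_segment: bool = True
    run_embed: bool = True
    run_cluster: bool = True
    run_metrics: bool = True
    run_sequence: bool = False
    min_vocalizations_per_individual: int = 200
    apply_min_vocalization_filter: bool = False
    pad_frames: int = 32
    d_ref_s: float = 0.02  # reference duration for log-time rescaling
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    gate: GateConfig = field(default_factory=GateConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    min_cluster_frac: float = 0.01


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Pure config check; returns a list of human-readable issues."""
    issues = []
    p = cfg.spectrogram
    if not 0 <= p.fmin_hz < p.fmax_hz:
        issues.append("spectrogram: fmin_hz must be below fmax_hz")
    if cfg.input_dir is not None and not Path(cfg.input_dir).is_dir():
        issues.append(f"input_dir does not exist: {cfg.input_dir}")
    if cfg.noise_clip is not None and not Path(cfg.noise_clip).is_file():
        issues.append(f"noise_clip does not exist: {cfg.noise_clip}")
    if cfg.segments_csv is not None and not Path(cfg.segments_csv).is_file():
        issues.append(f"segments_csv does not exist: {cfg.segments_csv}")
    if cfg.run_denoise and cfg.noise_clip is None and cfg.input_dir is not None:
        issues.append("denoise stage enabled but no noise_clip given")
    if cfg.run_cluster and not cfg.run_embed:
        issues.append("cluster stage requires the embed stage")
    if not 0 < cfg.min_cluster_frac <= 1:
        issues.append("min_cluster_frac must be in (0, 1]")
    return issues


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig, waveforms: list[Waveform] | None = None,
                 labels=None) -> dict:
    """Execute the enabled stages and return a RunReport dict.

    ``waveforms`` (one per bout) may be passed directly instead of
    ``cfg.input_dir``; ``labels`` is an optional flat array of per-syllable
    ground-truth labels used by the metrics/sequence stages.
    """
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "config": _config_dict(cfg), "stages": {}}

    if waveforms is None and cfg.input_dir is not None:
        paths = sorted(Path(cfg.input_dir).glob("*.wav"))
        waveforms = [read_wav(p, mixdown=True) for p in paths]
        report["stages"]["input"] = {"n_files": len(waveforms)}
    if waveforms is None and any([cfg.run_denoise, cfg.run_segment, cfg.run_embed]):
        raise ValueError("no input: pass waveforms or set input_dir")

    if cfg.run_denoise:
        try:
            noise = read_wav(cfg.noise_clip, mixdown=True)
            waveforms = [reduce_noise(w, noise, cfg.spectrogram, cfg.gate)
                         for w in waveforms]
            report["stages"]["denoise"] = {"n_bouts": len(waveforms),
                                           "n_std": cfg.gate.n_std}
        except Exception as exc:
            raise StageError("denoise", exc) from exc

    segments = None
    if cfg.segments_csv is not None:
        df = read_segments_csv(cfg.segments_csv)
        segments = [g.reset_index(drop=True) for _, g in df.groupby("bout_id", sort=False)]
    elif cfg.run_segment and waveforms is not None:
        try:
            segments, rejected = [], 0
            for b, w in enumerate(waveforms):
                try:
                    segments.append(dynamic_threshold_segment(
                        w, cfg.segmentation, bout_id=b))
                except LowSNRError:
                    rejected += 1
                    segments.append(pd.DataFrame(
                        columns=["bout_id", "onset_s", "offset_s", "label"]))
            n_seg = int(sum(len(s) for s in segments))
            report["stages"]["segment"] = {"n_segments": n_seg,
                                           "n_rejected_bouts": rejected}
        except Exception as exc:
            raise StageError("segment", exc) from exc

    ds = None
    if cfg.run_embed and segments is not None:
        try:
            ds = syllable_dataset_from_bouts(
                waveforms, segments, cfg.spectrogram, pad_frames=cfg.pad_frames,
                d_ref_s=cfg.d_ref_s)
            if (cfg.apply_min_vocalization_filter
                    and len(ds) < cfg.min_vocalizations_per_individual):
                report["stages"]["filter"] = {
                    "passed": False, "n_syllables": len(ds),
                    "min_required": cfg.min_vocalizations_per_individual}
                return report
            emb = embed_discrete(ds, replace(cfg.embedding, seed=cfg.seed))
            report["stages"]["embed"] = {"n_syllables": len(ds),
                                         "n_components": emb.Z.shape[1],
                                         "method": cfg.embedding.method}
        except Exception as exc:
            raise StageError("embed", exc) from exc
    else:
        emb = None

    cluster_result = None
    if cfg.run_cluster and emb is not None:
        try:
            cluster_result = cluster_hdbscan(emb.Z, cfg.min_cluster_frac)
            report["stages"]["cluster"] = {
                "n_clusters": cluster_result.n_clusters,
                "n_noise": int(np.sum(
                    cluster_result.labels == cluster_result.noise_value)),
            }
        except Exception as exc:
            raise StageError("cluster", exc) from exc

    if cfg.run_metrics and emb is not None:
        try:
            m = max(1, min(len(ds), 500))
            hop = hopkins(emb.Z, m=m, seed=cfg.seed)
            metrics_rec = {"hopkins": hop.statistic, "hopkins_sampling": hop.sampling}
            if labels is None and ds.labels is not None:
                labels = ds.labels
            if labels is not None and cluster_result is not None:
                ov = overlap(labels, cluster_result.labels)
                metrics_rec.update(homogeneity=ov.homogeneity,
                                   completeness=ov.completeness,
                                   v_measure=ov.v_measure)
                if len(np.unique(labels)) > 1:
                    metrics_rec["silhouette"] = silhouette(emb.Z, labels).score
            report["stages"]["metrics"] = metrics_rec
        except Exception as exc:
            raise StageError("metrics", exc) from exc

    if cfg.run_sequence and cluster_result is not None and segments is not None:
        try:
            labeled = []
            pos = 0
            for seg in segments:
                seg = seg.copy()
                seg["label"] = [str(x) for x in
                                cluster_result.labels[pos:pos + len(seg)]]
                pos += len(seg)
                if len(seg):
                    labeled.append(seg)
            corpus = Corpus.from_bouts([list(s.sort_values("onset_s")["label"])
                                        for s in labeled])
            markov = fit_markov(corpus, pseudocount=0.5)
            report["stages"]["sequence"] = {
                "n_bouts": len(corpus.bouts),
                "alphabet_size": len(corpus.alphabet),
                "transition_matrix": markov.transition.tolist(),
            }
        except Exception as exc:
            raise StageError("sequence", exc) from exc

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if segments is not None:
            pd.concat(segments, ignore_index=True).to_csv(
                out / "segments.csv", index=False)
        if emb is not None:
            emb_df = pd.DataFrame(emb.Z, columns=[f"dim_{i}"
                                                  for i in range(emb.Z.shape[1])])
            if cluster_result is not None:
                emb_df["cluster"] = cluster_result.labels
            emb_df.to_csv(out / "embedding.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d
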