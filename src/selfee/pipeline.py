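"""End-to-end pipeline driver: preprocess -> embed -> downstream analyses.

A run is described by a nested config (YAML on disk) with per-stage blocks;
the config is validated against the known keys, serialized verbatim into
the output directory for provenance, and every stage routes its randomness
through one seeded generator hierarchy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .anomaly import detect_anomalies
from .classify import LabelSeries, evaluate, knn_predict, leave_one_video_out, temporal_vote
from .embed import embed_video, save_embeddings
from .model import NetworkConfig
from .objective import LossConfig
from .preprocess import FrameStore
from .synthetic import default_two_agent_script, generate_scene_video
from .timeseries import dtw_align, fit_arhmm, fit_pca_95
from .train import TrainConfig, fit

_KNOWN_BLOCKS = {"seed", "out_dir", "synthetic", "preprocess", "train", "embed",
                 "classify", "anomaly", "timeseries", "network", "loss", "augment"}


def validate_config(config: dict) -> dict:
    """Reject unknown top-level keys (the error names the offending key)."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key in config:
        if key not in _KNOWN_BLOCKS:
            raise ValueError(f"invalid config key: {key!r}")
    return config


def config_hash(config: dict) -> str:
    """Hash of the scientific configuration (output paths excluded)."""
    payload = {k: v for k, v in config.items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _dump_provenance(out: Path, config: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    payload = dict(config)
    payload_text = json.dumps(payload, indent=1, sort_keys=True)
    (out / "run_config.json").write_text(payload_text)
    (out / "config_hash.txt").write_text(config_hash(config) + "\n")


def run_demo(out_dir, seed: int = 0, n_videos: int = 4, frames_per_video: int = 400,
             arena: int = 48, steps: int = 60, batch_size: int = 16,
             proj_dim: int = 128, quiet: bool = False) -> dict:
    """Synthetic end-to-end pipeline: scenes -> preprocess -> short training
    -> embeddings -> leave-one-video-out k-NN -> anomaly scan -> AR-HMM.

    Desk-scale by construction; returns the summary dict it also writes to
    ``summary.json``.
    """
    out = Path(out_dir)
    config = {"seed": seed, "out_dir": str(out),
              "synthetic": {"n_videos": n_videos, "frames": frames_per_video,
                            "arena": arena},
              "train": {"steps": steps, "batch_size": batch_size,
                        "proj_dim": proj_dim}}
    _dump_provenance(out, config)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_videos + 1)

    stores, labels = [], []
    for i in range(n_videos):
        script = default_two_agent_script(duration=frames_per_video,
                                          seed=int(seeds[i] % (2**31)))
        scene = generate_scene_video(script, arena=(arena, arena))
        stores.append(FrameStore.from_array(scene.frames, video_id=f"scene{i}"))
        labels.append(scene.labels)

    net_cfg = NetworkConfig(backbone="small", proj_dim=proj_dim,
                            pred_hidden=max(proj_dim // 4, 8),
                            disc_dim=max(proj_dim // 2, 8), small_width=8)
    loss_cfg = LossConfig(n_clusters=min(8, batch_size))
    train_cfg = TrainConfig(steps=steps, batch_size=batch_size, stride=1,
                            seed=int(seeds[-1] % (2**31)), checkpoint_every=max(steps, 1))
    net, log = fit(stores, net_cfg, loss_cfg, train_cfg, out_dir=out / "train")

    series = [embed_video(st, net, stride=1) for st in stores]
    frame_labels = [LabelSeries(labels=lab[s.center_indices], video_id=st.video_id)
                    for lab, s, st in zip(labels, series, stores)]
    for s in series:
        save_embeddings(s, out / f"emb_{s.video_id}")

    # leave-one-video-out weighted k-NN with temporal vote
    from .embed import EmbeddingSeries

    f1s = []
    for held, train_idx in leave_one_video_out(series, frame_labels):
        ref = EmbeddingSeries(
            matrix=np.vstack([series[j].matrix for j in train_idx]),
            center_indices=np.arange(sum(len(series[j]) for j in train_idx)),
            video_id="ref")
        ref_lab = LabelSeries(labels=np.concatenate(
            [frame_labels[j].labels for j in train_idx]))
        pred = knn_predict(series[held], ref, ref_lab, k=5)
        pred = temporal_vote(pred, window=21)
        f1s.append(evaluate(pred, frame_labels[held])["f1"])

    report = detect_anomalies(series[:2], series[2:], control_group=None)
    pca = fit_pca_95(np.vstack([s.matrix for s in series]))
    arhmm = fit_arhmm([pca.transform(s.matrix) for s in series], K=3, lag=1,
                      n_iter=20, seed=seed, n_restarts=2)
    path = dtw_align(series[0].matrix, series[1].matrix)

    summary = {
        "config_hash": config_hash(config),
        "final_loss": log[-1]["loss"],
        "final_collapse": log[-1]["collapse"],
        "lovo_knn_f1_mean": float(np.mean(f1s)),
        "anomaly_video_scores": [float(v) for v in report.video_scores],
        "pca95_components": int(pca.n_components),
        "arhmm_states_used": int(arhmm.params.n_states),
        "dtw_cost_scene0_vs_scene1": float(path.cost),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    if not quiet:
        for key, val in summary.items():
            print(f"{key}: {val}")
    return summary
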