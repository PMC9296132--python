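"""Batch inference: videos -> per-frame Meta-representation matrices."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import SelfeeNet
from .nn import l2_normalize
from .preprocess import FrameStore, live_frame_stack
from .train import _to_input

__all__ = ["EmbeddingSeries", "embed_video", "smooth_embeddings",
           "save_embeddings", "load_embeddings"]


@dataclass
class EmbeddingSeries:
    """Per-video matrix of frame representations aligned to live-frame centers."""

    matrix: np.ndarray          # n x D float32
    center_indices: np.ndarray  # n, strictly increasing frame indices
    video_id: str = "video"
    stride: int = 1
    normalized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        self.center_indices = np.asarray(self.center_indices)
        if len(self.matrix) != len(self.center_indices):
            raise ValueError("matrix rows must align with center indices")

    def __len__(self) -> int:
        return len(self.matrix)

    def normalized_matrix(self) -> np.ndarray:
        return self.matrix if self.normalized else l2_normalize(self.matrix)


def embed_video(store: FrameStore, net: SelfeeNet, stride: int = 1,
                batch_size: int = 64) -> EmbeddingSeries:
    """Eval-mode projector outputs for every live-frame of a video, in order.

    Deterministic given the weights; batching does not change the result.
    """
    imgs, centers = live_frame_stack(store, stride)
    rows = []
    for start in range(0, len(imgs), batch_size):
        x = _to_input(imgs[start:start + batch_size])
        rows.append(net.forward_infer(x).astype(np.float32))
    return EmbeddingSeries(matrix=np.vstack(rows), center_indices=centers,
                           video_id=store.video_id, stride=stride)


def smooth_embeddings(series: EmbeddingSeries, window: int = 3) -> EmbeddingSeries:
    """Centered moving average over rows (edges truncated to available
    neighbors); re-normalized when the series is flagged normalized.

    Averaging the embeddings of a few tandem frames suppresses frame-level
    noise before visualization or alignment.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return series
    half = window // 2
    n = len(series)
    csum = np.cumsum(np.vstack([np.zeros((1, series.matrix.shape[1]),
                                         dtype=np.float64), series.matrix]), axis=0)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    out = out.astype(series.matrix.dtype)
    if series.normalized:
        out = l2_normalize(out)
    return EmbeddingSeries(matrix=out, center_indices=series.center_indices.copy(),
                           video_id=series.video_id, stride=series.stride,
                           normalized=series.normalized)


def save_embeddings(series: EmbeddingSeries, path) -> Path:
    """Write ``<path>.npy`` plus a ``<path>.json`` sidecar with metadata."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npy" else path
    np.save(base.with_suffix(".npy"), series.matrix)
    sidecar = {
        "video_id": series.video_id,
        "stride": int(series.stride),
        "normalized": bool(series.normalized),
        "center_indices": [int(i) for i in series.center_indices],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))
    return base.with_suffix(".npy")


def load_embeddings(path) -> EmbeddingSeries:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npy", ".json") else path
    matrix = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return EmbeddingSeries(matrix=matrix,
                           center_indices=np.array(meta["center_indices"]),
                           video_id=meta["video_id"], stride=meta["stride"],
                           normalized=meta["normalized"])
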