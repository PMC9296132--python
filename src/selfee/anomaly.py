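"""Frame-level anomaly detection on embedding series.

For query frames ``q_i`` and reference frames ``r_j`` the anomaly score is

    score(q_i) = IES(q_i) - IAS(q_i)

where IES (inter-group score) is the k-th smallest cosine distance from
``q_i`` to any reference frame and IAS (intra-group score) is the k-th
smallest cosine distance to other frames of the query group, excluding
frames of the same video within +/-``exclusion`` frames (temporal
neighbors are trivially similar).  ``k = 1`` throughout by default.  A
video's summary score is the mean of its top-T most anomalous frames
(T = 100), and with negative-control videos a frame is flagged anomalous
when its score strictly exceeds the maximum score seen in the controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .embed import EmbeddingSeries

__all__ = [
    "AnomalyReport",
    "frame_anomaly_scores",
    "video_anomaly_score",
    "anomaly_threshold",
    "flag_anomalies",
    "detect_anomalies",
]


@dataclass
class AnomalyReport:
    """Per-video frame scores, summary scores, and flags vs a threshold."""

    frame_scores: list[np.ndarray]          # one array per query video
    video_scores: list[float]
    video_ids: list[str]
    threshold: float | None = None
    flagged: list[np.ndarray] | None = None  # per-video flagged frame positions


def _as_matrices(group) -> list[np.ndarray]:
    mats = []
    for item in group:
        if isinstance(item, EmbeddingSeries):
            mats.append(item.normalized_matrix().astype(np.float64))
        else:
            arr = np.asarray(item, dtype=np.float64)
            norm = np.linalg.norm(arr, axis=1, keepdims=True)
            mats.append(arr / np.maximum(norm, 1e-12))
    return mats


def frame_anomaly_scores(query_group, reference_group, k: int = 1,
                         exclusion: int = 50, chunk: int = 512) -> list[np.ndarray]:
    """IES - IAS per frame, one score array per query video.

    Distances are cosine distances on L2-normalized embeddings.  The
    temporal exclusion applies only within the same video; frames of other
    query-group videos are always eligible intra-group partners.  Results
    are independent of the chunk size (memory-only knob).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q_mats = _as_matrices(query_group)
    r_mats = _as_matrices(reference_group)
    if not q_mats or not r_mats:
        raise ValueError("query and reference groups must be nonempty")
    ref = np.vstack(r_mats)
    qall = np.vstack(q_mats)
    sizes = [len(m) for m in q_mats]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_total = offsets[-1]
    if len(q_mats) == 1 and sizes[0] < 2 * exclusion + 2:
        raise ValueError(
            f"intra-group candidates empty: a single query video needs more than "
            f"{2 * exclusion + 1} frames (got {sizes[0]})")

    scores = []
    for vi, qm in enumerate(q_mats):
        n = len(qm)
        s = np.empty(n)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            block = qm[start:stop]
            # inter-group: k-th smallest distance to all reference frames
            d_ref = 1.0 - block @ ref.T
            ies = _kth_smallest(d_ref, k)
            # intra-group: exclude own video's frames within +/- exclusion
            d_q = 1.0 - block @ qall.T
            rows = np.arange(start, stop)
            lo = np.maximum(rows - exclusion, 0) + offsets[vi]
            hi = np.minimum(rows + exclusion + 1, n) + offsets[vi]
            for r, (a, b) in enumerate(zip(lo, hi)):
                d_q[r, a:b] = np.inf
            ias = _kth_smallest(d_q, k)
            if not np.all(np.isfinite(ias)):
                raise ValueError("intra-group candidate set is empty for some frames")
            s[start:stop] = ies - ias
        scores.append(s)
    return scores


def _kth_smallest(d: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return d.min(axis=1)
    if k > d.shape[1]:
        raise ValueError(f"k={k} exceeds candidate count {d.shape[1]}")
    part = np.partition(d, k - 1, axis=1)
    return part[:, k - 1]


def video_anomaly_score(scores: np.ndarray, top_t: int = 100) -> float:
    """Mean of the ``top_t`` largest frame scores (all frames, with a
    warning, when the video is shorter)."""
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("no frame scores")
    if scores.size < top_t:
        warnings.warn(f"only {scores.size} frames; averaging all of them")
        return float(scores.mean())
    top = np.partition(scores, scores.size - top_t)[-top_t:]
    return float(top.mean())


def anomaly_threshold(negative_control_scores) -> float:
    """Maximum frame score over all negative-control videos."""
    flat = np.concatenate([np.ravel(s) for s in negative_control_scores])
    if flat.size == 0:
        raise ValueError("no negative-control scores")
    return float(flat.max())


def flag_anomalies(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of frames scoring strictly above the threshold."""
    return np.flatnonzero(np.asarray(scores) > threshold)


def detect_anomalies(query_group, reference_group, control_group=None,
                     k: int = 1, exclusion: int = 50, top_t: int = 100) -> AnomalyReport:
    """Full anomaly pipeline: frame scores, per-video summaries, and (when
    negative controls are given) the control-derived threshold and flags."""
    frame_scores = frame_anomaly_scores(query_group, reference_group,
                                        k=k, exclusion=exclusion)
    video_ids = [s.video_id if isinstance(s, EmbeddingSeries) else f"query{i}"
                 for i, s in enumerate(query_group)]
    video_scores = [video_anomaly_score(s, top_t=top_t) for s in frame_scores]
    threshold = None
    flagged = None
    if control_group is not None:
        control_scores = frame_anomaly_scores(control_group, reference_group,
                                              k=k, exclusion=exclusion)
        threshold = anomaly_threshold(control_scores)
        flagged = [flag_anomalies(s, threshold) for s in frame_scores]
    return AnomalyReport(frame_scores=frame_scores, video_scores=video_scores,
                         video_ids=video_ids, threshold=threshold, flagged=flagged)
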