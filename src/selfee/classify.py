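"""Weighted k-NN classification, temporal smoothing, temporal features,
and evaluation metrics.

The classifier is the soft-voting k-NN of the contrastive-learning
literature: neighbors are ranked by cosine similarity and each contributes
``exp(sim / tau)`` to its class.  Inferred labels are then forced to be
continuous through time by a majority vote over a centered window (21
frames for fast fly-style dynamics, 81 for mouse/rat-style).  For learners
that exploit temporal context explicitly, :func:`temporal_features`
augments per-frame features with sliding means/stds and the dominant
short-time Fourier component per dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.metrics import average_precision_score, f1_score

from .embed import EmbeddingSeries
from .nn import l2_normalize

__all__ = [
    "LabelSeries",
    "knn_predict",
    "temporal_vote",
    "temporal_features",
    "evaluate",
    "leave_one_video_out",
    "BoostedFrameClassifier",
]


@dataclass
class LabelSeries:
    """Per-center-frame class labels aligned to an EmbeddingSeries."""

    labels: np.ndarray
    class_names: list[str] | None = None
    video_id: str = "video"
    scores: np.ndarray | None = None  # n x n_classes, e.g. k-NN class scores

    def __post_init__(self):
        self.labels = np.asarray(self.labels)


def knn_predict(query: EmbeddingSeries, reference: EmbeddingSeries,
                reference_labels: LabelSeries, k: int = 20,
                tau: float = 0.07, chunk: int = 1024) -> LabelSeries:
    """Soft-voting k-NN on cosine similarity.

    Each of the k nearest reference frames votes ``exp(sim / tau)`` for its
    class; the argmax wins.  Per-class scores are kept for average-precision
    evaluation.  ``k`` is clamped (with a warning) when the reference is
    smaller.
    """
    ref_labels = np.asarray(reference_labels.labels)
    m = len(reference)
    if m == 0:
        raise ValueError("reference is empty")
    if len(ref_labels) != m:
        raise ValueError("reference labels misaligned with reference embeddings")
    if k > m:
        warnings.warn(f"k={k} larger than reference size {m}; clamping")
        k = m
    classes = np.unique(ref_labels)
    n_classes = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    ref = reference.normalized_matrix()
    q = query.normalized_matrix()
    n = len(q)
    scores = np.zeros((n, n_classes))
    for start in range(0, n, chunk):
        sims = q[start:start + chunk] @ ref.T
        if k < m:
            nbr = np.argpartition(-sims, k - 1, axis=1)[:, :k]
        else:
            nbr = np.broadcast_to(np.arange(m), (sims.shape[0], m))
        w = np.exp(np.take_along_axis(sims, nbr, axis=1) / tau)
        lab = ref_labels[nbr]
        for ci, c in enumerate(classes):
            scores[start:start + chunk, ci] = np.where(lab == c, w, 0.0).sum(axis=1)
    pred = classes[scores.argmax(axis=1)]
    return LabelSeries(labels=pred, video_id=query.video_id, scores=scores,
                       class_names=[str(c) for c in classes])


def temporal_vote(series: LabelSeries, window: int = 21) -> LabelSeries:
    """Majority vote over a centered window (truncated at the edges).

    Ties keep the frame's own pre-vote label.  Use 21 frames for fly-style
    and 81 for mouse/rat-style dynamics.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    labels = np.asarray(series.labels)
    n = len(labels)
    half = window // 2
    classes, inv = np.unique(labels, return_inverse=True)
    out = labels.copy()
    for i in range(n):
        seg = inv[max(0, i - half):min(n, i + half + 1)]
        counts = np.bincount(seg, minlength=len(classes))
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        if len(winners) == 1:
            out[i] = classes[winners[0]]
        # ties: keep the frame's own label
    return LabelSeries(labels=out, class_names=series.class_names,
                       video_id=series.video_id, scores=series.scores)


def temporal_features(series: np.ndarray, window: int = 81) -> np.ndarray:
    """Sliding temporal statistics: per dimension and frame, the centered
    moving mean, moving std, dominant short-time Fourier frequency
    (cycles/frame) and that component's magnitude.

    Output is ``n x (4 d)`` ordered (mean, std, freq, magnitude) per input
    dimension; the caller concatenates it to the raw features.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if n < window:
        raise ValueError(f"series of length {n} shorter than window {window}")
    mean = uniform_filter1d(x, size=window, axis=0, mode="reflect")
    sq = uniform_filter1d(x * x, size=window, axis=0, mode="reflect")
    std = np.sqrt(np.maximum(sq - mean ** 2, 0.0))
    half = window // 2
    xp = np.pad(x, ((half, half), (0, 0)), mode="reflect")
    freqs = np.fft.rfftfreq(window, d=1.0)
    dom_f = np.empty((n, d))
    dom_m = np.empty((n, d))
    win_view = np.lib.stride_tricks.sliding_window_view(xp, window, axis=0)  # n x d x w
    for j in range(d):
        spec = np.abs(np.fft.rfft(win_view[:, j, :], axis=1)) / window
        idx = spec.argmax(axis=1)
        dom_f[:, j] = freqs[idx]
        dom_m[:, j] = spec[np.arange(n), idx]
    return np.concatenate([mean, std, dom_f, dom_m], axis=1)


def evaluate(pred: LabelSeries, truth: LabelSeries, average: str = "macro") -> dict:
    """F1 and mean average precision.

    ``macro`` averages over behavior classes; ``micro`` pools frames (used
    for graded intensity scores).  mAP needs per-class scores on the
    prediction; without them only F1 is returned.
    """
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    y_true = np.asarray(truth.labels)
    y_pred = np.asarray(pred.labels)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction and truth are misaligned")
    truth_classes = np.unique(y_true)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = f1_score(y_true, y_pred, labels=truth_classes, average=average,
                      zero_division=0)
    out = {"f1": float(f1)}
    if pred.scores is not None and pred.class_names is not None:
        score_classes = np.array(pred.class_names)
        aps = []
        y_true_str = y_true.astype(str)
        present = []
        for ci, c in enumerate(score_classes):
            mask = y_true_str == c
            if not mask.any():
                warnings.warn(f"class {c!r} absent from truth; skipped in mAP")
                continue
            present.append(ci)
            aps.append(average_precision_score(mask, pred.scores[:, ci]))
        if average == "micro" and present:
            y_bin = np.stack([y_true_str == score_classes[ci] for ci in present], axis=1)
            out["mAP"] = float(average_precision_score(
                y_bin, pred.scores[:, present], average="micro"))
        elif aps:
            out["mAP"] = float(np.mean(aps))
    return out


def leave_one_video_out(series_list: list[EmbeddingSeries],
                        label_list: list[LabelSeries]):
    """Folds for cross-validation at the video level (never frame-level
    splits, which would leak temporally adjacent frames across folds).

    Yields ``(held_out_index, train_indices)``.
    """
    n = len(series_list)
    if n != len(label_list):
        raise ValueError("series and labels must pair up")
    if n < 2:
        raise ValueError("need at least two videos")
    for i in range(n):
        yield i, [j for j in range(n) if j != i]


class BoostedFrameClassifier:
    """Gradient-boosted frame classifier behind a fit/predict contract.

    The learner is injected (any object with sklearn-style ``fit`` /
    ``predict``; default LightGBM) — only the temporal feature engineering
    is bespoke.  An optional PCA step reduces embedding dimensionality
    before the sliding-window features are computed.
    """

    def __init__(self, window: int = 81, pca_dim: int | None = 16,
                 learner=None, early_stopping_rounds: int = 20, seed: int = 0):
        self.window = window
        self.pca_dim = pca_dim
        self.seed = seed
        self.early_stopping_rounds = early_stopping_rounds
        self._learner = learner
        self._pca = None

    def _make_learner(self):
        if self._learner is not None:
            return self._learner
        from lightgbm import LGBMClassifier

        return LGBMClassifier(n_estimators=200, random_state=self.seed, verbose=-1)

    def _features(self, matrix: np.ndarray, fit_pca: bool) -> np.ndarray:
        x = np.asarray(matrix, dtype=float)
        if self.pca_dim is not None and x.shape[1] > self.pca_dim:
            if fit_pca:
                from sklearn.decomposition import PCA

                self._pca = PCA(n_components=self.pca_dim, random_state=self.seed).fit(x)
            x = self._pca.transform(x)
        return np.concatenate([x, temporal_features(x, self.window)], axis=1)

    def fit(self, series_list, label_list, valid_series=None, valid_labels=None):
        xs = [self._features(s.matrix, fit_pca=(i == 0))
              for i, s in enumerate(series_list)]
        x = np.vstack(xs)
        y = np.concatenate([np.asarray(l.labels) for l in label_list])
        self.model = self._make_learner()
        fit_kw = {}
        if valid_series is not None:
            xv = self._features(valid_series.matrix, fit_pca=False)
            yv = np.asarray(valid_labels.labels)
            try:
                import lightgbm as lgb

                fit_kw = {"eval_set": [(xv, yv)],
                          "callbacks": [lgb.early_stopping(self.early_stopping_rounds,
                                                           verbose=False)]}
            except ImportError:
                pass
        self.model.fit(x, y, **fit_kw)
        return self

    def predict(self, series: EmbeddingSeries) -> LabelSeries:
        x = self._features(series.matrix, fit_pca=False)
        pred = self.model.predict(x)
        scores = None
        class_names = None
        if hasattr(self.model, "predict_proba"):
            scores = self.model.predict_proba(x)
            class_names = [str(c) for c in self.model.classes_]
        return LabelSeries(labels=pred, video_id=series.video_id,
                           scores=scores, class_names=class_names)


def ensemble_vote(predictions: list[LabelSeries]) -> LabelSeries:
    """Majority vote of per-fold classifiers.

    Per-class scores are not propagated (average precision is undefined for
    a vote), matching how ensembled classifiers are reported.
    """
    stacked = np.stack([np.asarray(p.labels) for p in predictions], axis=0)
    n = stacked.shape[1]
    out = np.empty(n, dtype=stacked.dtype)
    for i in range(n):
        vals, counts = np.unique(stacked[:, i], return_counts=True)
        out[i] = vals[counts.argmax()]
    return LabelSeries(labels=out, video_id=predictions[0].video_id)
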