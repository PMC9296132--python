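"""Training objective: stop-gradient cosine loss + cluster-discrimination loss.

The total loss is ``Loss = Loss1 + lambda * Loss2`` with

* ``Loss1``: symmetric mean cosine distance between each branch's
  stop-gradient projector output and the other branch's predictor output,
* ``Loss2`` (cross-level instance-group discrimination): each sample's
  unit-norm discriminator output is compared against the in-batch k-means
  centroids of the *other* branch; the temperature-scaled affinities are
  trained with cross-entropy toward the counterpart sample's cluster label.

A collapse-level monitor quantifies how close the batch is to the
degenerate all-identical-representation solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import BranchOutputs
from .nn import l2_normalize

__all__ = [
    "LossConfig",
    "ClusterResult",
    "cosine_distance",
    "similarity_loss",
    "similarity_loss_grads",
    "cluster_batch",
    "cld_loss",
    "cld_loss_grads",
    "total_loss",
    "collapse_level",
]


@dataclass
class LossConfig:
    theta: float = 0.07   # softmax temperature of the affinity logits
    lam: float = 2.0      # weight of the cluster-discrimination term
    n_clusters: int = 10  # k of the in-batch k-means
    kmeans_iters: int = 10

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class ClusterResult:
    """Spherical k-means result: unit-norm centroids and hard assignments."""

    M: np.ndarray       # k x d, unit-norm rows
    labels: np.ndarray  # n, integer cluster index per sample

    @property
    def onehot(self) -> np.ndarray:
        eye = np.eye(self.M.shape[0])
        return eye[self.labels]


def cosine_distance(m: np.ndarray, n: np.ndarray) -> float:
    """``1 - cos(m, n)``; in [0, 2]. Rejects zero vectors."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    nm, nn = np.linalg.norm(m), np.linalg.norm(n)
    if nm == 0 or nn == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - (m @ n) / (nm * nn))


def _rowwise_cosdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 1.0 - np.sum(l2_normalize(a) * l2_normalize(b), axis=1)


def similarity_loss(a: BranchOutputs, b: BranchOutputs) -> float:
    """Stop-gradient similarity term (Loss1), value in [0, 2].

    Mean of ``cosdist(sg(z_i), p'_i)`` and ``cosdist(sg(z'_i), p_i)``, each
    weighted 1/2.  Purely the value; see :func:`similarity_loss_grads` for
    the gradients used in training.
    """
    n = a.z.shape[0]
    if n == 0 or b.z.shape[0] != n:
        raise ValueError("branches must have equal, nonzero batch size")
    t1 = _rowwise_cosdist(a.z, b.p).mean()
    t2 = _rowwise_cosdist(b.z, a.p).mean()
    return float(0.5 * (t1 + t2))


def _cosdist_grad_wrt_p(z_const: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d cosdist(const z, p) / dp, row-wise."""
    zhat = l2_normalize(z_const)
    pnorm = np.maximum(np.linalg.norm(p, axis=1, keepdims=True), 1e-12)
    phat = p / pnorm
    return -(zhat - np.sum(zhat * phat, axis=1, keepdims=True) * phat) / pnorm


def similarity_loss_grads(a: BranchOutputs, b: BranchOutputs):
    """(loss1, dp_a, dp_b).  The gradient with respect to z and z' is exactly
    zero: the projector outputs enter only through the stop-gradient."""
    n = a.z.shape[0]
    if n == 0 or b.z.shape[0] != n:
        raise ValueError("branches must have equal, nonzero batch size")
    loss = similarity_loss(a, b)
    dpa = _cosdist_grad_wrt_p(b.z, a.p) / (2 * n)
    dpb = _cosdist_grad_wrt_p(a.z, b.p) / (2 * n)
    return loss, dpa, dpb


def cluster_batch(v: np.ndarray, cfg: LossConfig,
                  rng: np.random.Generator | None = None) -> ClusterResult:
    """Spherical k-means (cosine similarity) with hard assignments.

    Centroids are re-normalized to the unit sphere after every Lloyd
    update.  An emptied cluster is re-seeded from the point farthest (in
    cosine) from its assigned centroid.
    """
    v = np.asarray(v, dtype=float)
    n, d = v.shape
    k = cfg.n_clusters
    if n < k:
        raise ValueError(f"batch of {n} cannot be split into {k} clusters")
    rng = rng or np.random.default_rng(0)
    vn = l2_normalize(v)
    centroids = vn[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max(cfg.kmeans_iters, 1)):
        sims = vn @ centroids.T
        labels = sims.argmax(axis=1)
        for j in range(k):
            members = vn[labels == j]
            if len(members) == 0:
                worst = np.argmin(sims[np.arange(n), labels])
                centroids[j] = vn[worst]
                labels[worst] = j
            else:
                centroids[j] = l2_normalize(members.mean(axis=0)[None, :])[0]
    return ClusterResult(M=centroids, labels=labels)


def _cross_entropy_rows(logits: np.ndarray, targets: np.ndarray):
    """Per-row ``-x[t] + log(sum exp(x))`` and the softmax for gradients."""
    lse = logsumexp(logits, axis=1)
    ce = lse - logits[np.arange(len(targets)), targets]
    soft = np.exp(logits - lse[:, None])
    return ce, soft


def cld_loss(a: BranchOutputs, b: BranchOutputs,
             ca: ClusterResult, cb: ClusterResult, cfg: LossConfig) -> float:
    """Cluster-discrimination term (Loss2), value only."""
    return cld_loss_grads(a, b, ca, cb, cfg)[0]


def cld_loss_grads(a: BranchOutputs, b: BranchOutputs,
                   ca: ClusterResult, cb: ClusterResult, cfg: LossConfig):
    """(loss2, dv_a, dv_b).

    Logits for branch-A sample i are ``(v_i / theta) . M_B^T``; its target
    is sample i's cluster label in branch B (the counterpart's label).
    Assignments are constants; gradients flow through v and through the
    centroids M (centroid = normalized mean of its members' v).
    """
    if ca.M.shape != cb.M.shape or ca.M.shape[1] != a.v.shape[1]:
        raise ValueError("cluster centroid dimensions do not match branch outputs")
    n = a.v.shape[0]
    theta = cfg.theta

    def one_side(v_query, M_other, target_labels):
        logits = (v_query / theta) @ M_other.T
        ce, soft = _cross_entropy_rows(logits, target_labels)
        g = soft.copy()
        g[np.arange(n), target_labels] -= 1.0
        # weight 1/2 for this side, mean over batch
        g /= (2.0 * n)
        dv_query = (g @ M_other) / theta
        dM_other = (g.T @ v_query) / theta
        return ce.mean() / 2.0, dv_query, dM_other

    l_a, dva_direct, dMb = one_side(a.v, cb.M, cb.labels)
    l_b, dvb_direct, dMa = one_side(b.v, ca.M, ca.labels)

    def centroid_backward(dM, cluster: ClusterResult, v_source: np.ndarray):
        """Backprop through centroid = normalize(mean of assigned rows)."""
        dv = np.zeros_like(v_source)
        vn_norm = np.maximum(np.linalg.norm(v_source, axis=1, keepdims=True), 1e-12)
        for j in range(cluster.M.shape[0]):
            members = np.flatnonzero(cluster.labels == j)
            if len(members) == 0:
                continue
            vn_members = v_source[members] / vn_norm[members]
            m_raw = vn_members.mean(axis=0)
            m_norm = max(np.linalg.norm(m_raw), 1e-12)
            mhat = cluster.M[j]
            dm = (dM[j] - (dM[j] @ mhat) * mhat) / m_norm
            dvn = np.broadcast_to(dm / len(members), vn_members.shape)
            # through the row normalization of v used inside clustering
            dv_rows = (dvn - np.sum(dvn * vn_members, axis=1, keepdims=True) * vn_members)
            dv[members] += dv_rows / vn_norm[members]
        return dv

    dva = dva_direct + centroid_backward(dMa, ca, a.v)
    dvb = dvb_direct + centroid_backward(dMb, cb, b.v)
    return float(l_a + l_b), dva, dvb


def total_loss(a: BranchOutputs, b: BranchOutputs, cfg: LossConfig,
               rng: np.random.Generator | None = None):
    """``Loss1 + lambda * Loss2`` with in-batch clustering of each branch.

    Returns ``(loss, loss1, loss2)``.  With ``lambda == 0`` the clustering
    is skipped and the value equals the similarity loss alone.
    """
    loss1 = similarity_loss(a, b)
    if cfg.lam == 0:
        return loss1, loss1, 0.0
    ca = cluster_batch(a.v, cfg, rng)
    cb = cluster_batch(b.v, cfg, rng)
    loss2 = cld_loss(a, b, ca, cb, cfg)
    return loss1 + cfg.lam * loss2, loss1, loss2


def collapse_level(v: np.ndarray) -> float:
    """``1 - mean_c(std_c) * sqrt(C)`` over a batch of unit-norm rows.

    Population (ddof 0) standard deviation per channel.  All rows identical
    gives 1 (full collapse); per-channel std exactly ``C**-0.5`` (an
    isotropic spread on the sphere) gives 0.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("collapse level needs a batch of at least 2 rows")
    c = v.shape[1]
    return float(1.0 - v.std(axis=0, ddof=0).mean() * np.sqrt(c))
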