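"""Long-range temporal analyses: DTW alignment and AR-HMM segmentation.

Dynamic time warping aligns two embedding series under the classic
symmetric step pattern (diagonal weight 2, horizontal/vertical weight 1)
with cosine local costs, yielding a monotone warping path from (0, 0) to
(n-1, m-1); per-index delay curves read off which series leads.

Behavior segmentation uses a finite-K autoregressive hidden Markov model:
embeddings are first projected onto the principal components explaining
95% of the *control* group's variance, then an AR-HMM with at most K
states (default 10) is fitted by expectation-maximization (forward-backward
E-step, weighted-least-squares M-step), giving per-frame state sequences
and per-video state usages.  Usages are compared across groups with
two-sided Mann-Whitney tests and Benjamini-Hochberg correction.  The
finite-K EM is a deliberate substitution for the weak-limit Gibbs samplers
used by depth-imaging pipelines: K acts as the explicit module cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import false_discovery_control, mannwhitneyu

from .embed import EmbeddingSeries
from .nn import l2_normalize

__all__ = [
    "WarpingPath",
    "ARHMMParams",
    "ARHMMResult",
    "dtw_align",
    "delay_curve",
    "group_delay_curves",
    "fit_pca_95",
    "fit_arhmm",
    "state_usages",
    "compare_usages",
]


# --------------------------------------------------------------------- DTW
@dataclass
class WarpingPath:
    """Monotone alignment from (0, 0) to (n-1, m-1) with its total cost."""

    pairs: np.ndarray  # (L, 2) int, (query index, reference index)
    cost: float
    step_pattern: str = "symmetric2"

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs)


def _local_cost_matrix(query, reference, metric: str) -> np.ndarray:
    if metric == "cosine":
        q = np.asarray(query, dtype=float)
        r = np.asarray(reference, dtype=float)
        if q.ndim == 1 or r.ndim == 1:
            raise ValueError("cosine metric needs 2-D series (frames x dims)")
        return 1.0 - l2_normalize(q) @ l2_normalize(r).T
    if metric == "absolute":
        q = np.asarray(query, dtype=float).reshape(len(query), -1)
        r = np.asarray(reference, dtype=float).reshape(len(reference), -1)
        return np.abs(q[:, None, 0] - r[None, :, 0]) if q.shape[1] == 1 else \
            np.abs(q[:, None, :] - r[None, :, :]).sum(axis=2)
    raise ValueError(f"unknown metric {metric!r}")


def dtw_align(query, reference, metric: str = "cosine") -> WarpingPath:
    """Dynamic-programming alignment under the symmetric (1, 2, 1) step
    pattern; local cost is cosine distance for embeddings or absolute
    difference for scalar series.
    """
    query = np.asarray(query)
    reference = np.asarray(reference)
    if len(query) < 2 or len(reference) < 2:
        raise ValueError("both series need length >= 2")
    d = _local_cost_matrix(query, reference, metric)
    n, m = d.shape
    acc = np.full((n, m), np.inf)
    move = np.zeros((n, m), dtype=np.int8)  # 0 diag, 1 up(i-1), 2 left(j-1)
    acc[0, 0] = 2 * d[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + d[0, j]
        move[0, j] = 2
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + d[i, 0]
        move[i, 0] = 1
        row_prev = acc[i - 1]
        row = acc[i]
        di = d[i]
        for j in range(1, m):
            best = row_prev[j - 1] + 2 * di[j]
            mv = 0
            alt = row_prev[j] + di[j]
            if alt < best:
                best, mv = alt, 1
            alt = row[j - 1] + di[j]
            if alt < best:
                best, mv = alt, 2
            row[j] = best
            move[i, j] = mv
    # backtrack
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        mv = move[i, j]
        if mv == 0:
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return WarpingPath(pairs=np.array(path), cost=float(acc[n - 1, m - 1]))


def delay_curve(path: WarpingPath, n_reference: int | None = None) -> np.ndarray:
    """Per-reference-index delay ``mean(matched i) - j``.

    Positive values mean the query is ahead of the reference at that point
    of the recording; swapping query and reference flips the sign.
    """
    pairs = path.pairs
    m = (n_reference or pairs[:, 1].max() + 1)
    delays = np.zeros(m)
    for j in range(m):
        matched = pairs[pairs[:, 1] == j, 0]
        delays[j] = matched.mean() - j
    return delays


def group_delay_curves(query_series: list, reference_series: list,
                       metric: str = "cosine", grid_size: int = 100):
    """Mean +/- SEM delay over all query x reference pairs, after resampling
    each pair's delay curve onto a common relative-position grid.

    Returns ``(grid in [0, 1], mean, sem)``.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    curves = []
    for q in query_series:
        for r in reference_series:
            qm = q.matrix if isinstance(q, EmbeddingSeries) else np.asarray(q)
            rm = r.matrix if isinstance(r, EmbeddingSeries) else np.asarray(r)
            path = dtw_align(qm, rm, metric=metric)
            dc = delay_curve(path, n_reference=len(rm))
            pos = np.linspace(0.0, 1.0, len(dc))
            curves.append(np.interp(grid, pos, dc))
    stack = np.vstack(curves)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 \
        else np.zeros_like(mean)
    return grid, mean, sem


# ------------------------------------------------------------------ PCA-95
class PCAProjection:
    """A PCA fit on the control group, truncated at 95% explained variance."""

    def __init__(self, mean, components, explained_ratio, n_components):
        self.mean = mean
        self.components = components[:n_components]
        self.explained_ratio = explained_ratio
        self.n_components = n_components

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.components.T


def fit_pca_95(control: np.ndarray, threshold: float = 0.95) -> PCAProjection:
    """Smallest number of principal components whose cumulative explained
    variance reaches the threshold, fitted on the control group only.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(control, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D stack with at least 2 samples")
    pca = PCA().fit(x)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    n_comp = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    n_comp = min(n_comp, len(ratios))
    return PCAProjection(pca.mean_, pca.components_, ratios, n_comp)


# ------------------------------------------------------------------ AR-HMM
@dataclass
class ARHMMParams:
    """Per-state autoregression ``x_t ~ N(A_s [x_{t-lag..t-1}] + b_s, Sigma_s)``
    plus the state-transition matrix and initial distribution."""

    A: np.ndarray          # (K, d, d*lag), history ordered oldest first
    b: np.ndarray          # (K, d)
    sigma: np.ndarray      # (K, d, d) positive definite
    transition: np.ndarray  # (K, K) row-stochastic
    initial: np.ndarray | None = None  # (K,)
    lag: int = 1

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        for s in self.sigma:
            if np.any(np.linalg.eigvalsh(s) <= 0):
                raise ValueError("noise covariances must be positive definite")
        if self.initial is not None:
            self.initial = np.asarray(self.initial, dtype=float)

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def dim(self) -> int:
        return self.A.shape[1]


@dataclass
class ARHMMResult:
    params: ARHMMParams
    state_sequences: list[np.ndarray]
    log_likelihoods: np.ndarray  # per EM iteration, non-decreasing
    usages: np.ndarray           # (n_videos, K)


def _design(series: np.ndarray, lag: int):
    """Regression design: predict x_t from [x_{t-lag..t-1}, 1] for t >= lag."""
    n, d = series.shape
    t_idx = np.arange(lag, n)
    hist = np.stack([series[t - lag:t].reshape(-1) for t in t_idx])
    x = np.concatenate([hist, np.ones((len(t_idx), 1))], axis=1)
    y = series[lag:]
    return x, y


def _emission_loglik(x, y, A, b, sigma):
    d = y.shape[1]
    resid = y - x[:, :-1] @ A.T - b
    chol = np.linalg.cholesky(sigma)
    solved = np.linalg.solve(chol, resid.T)
    quad = np.sum(solved ** 2, axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (quad + logdet + d * np.log(2 * np.pi))


def _forward_backward(loglik: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi_sum, total loglik)."""
    t_len, k = loglik.shape
    alpha = np.empty((t_len, k))
    scale = np.empty(t_len)
    emis = np.exp(loglik - loglik.max(axis=1, keepdims=True))
    corr = loglik.max(axis=1)
    a = init * emis[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ trans) * emis[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((t_len, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 2, -1, -1):
        bt = beta[t + 1] * emis[t + 1]
        beta[t] = (trans @ bt) / scale[t + 1]
        xi = alpha[t][:, None] * trans * bt[None, :] / scale[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    total = float(np.log(scale).sum() + corr.sum())
    return gamma, xi_sum, total


def _viterbi(loglik, trans, init):
    t_len, k = loglik.shape
    logtrans = np.log(np.maximum(trans, 1e-300))
    delta = np.log(np.maximum(init, 1e-300)) + loglik[0]
    back = np.zeros((t_len, k), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + logtrans
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + loglik[t]
    states = np.empty(t_len, dtype=int)
    states[-1] = delta.argmax()
    for t in range(t_len - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def fit_arhmm(series_list, K: int = 10, lag: int = 1, n_iter: int = 50,
              seed: int = 0, n_restarts: int = 3, tol: float = 1e-4,
              ridge: float = 1e-6) -> ARHMMResult:
    """Finite-K AR-HMM fitted by EM with multi-restart best-likelihood.

    E-step: forward-backward over per-state Gaussian AR likelihoods.
    M-step: per-state weighted least squares for (A_s, b_s), weighted
    residual covariance for Sigma_s, expected transition counts for the
    transition matrix.  The log-likelihood is non-decreasing across
    iterations; states with (near-)zero occupancy are pruned with a warning.
    Viterbi decoding yields the per-frame state sequences.
    """
    mats = [s.matrix if isinstance(s, EmbeddingSeries) else np.asarray(s, dtype=float)
            for s in series_list]
    if any(len(m) <= lag for m in mats):
        raise ValueError("every series must be longer than the AR lag")
    total_frames = sum(len(m) for m in mats)
    if K > total_frames / 10:
        raise ValueError(f"K={K} too large for {total_frames} frames")
    d = mats[0].shape[1]
    designs = [_design(m, lag) for m in mats]

    best = None
    root = np.random.SeedSequence(seed)
    for restart, child in enumerate(root.spawn(max(n_restarts, 1))):
        rng = np.random.default_rng(child)
        fit = _em_run(designs, K, d, lag, n_iter, rng, tol, ridge)
        if best is None or fit[1][-1] > best[1][-1]:
            best = fit
    params, logliks = best

    # prune states never used
    occupancy = params._occupancy
    keep = occupancy > 1e-8
    if not np.all(keep):
        warnings.warn(f"pruning {int((~keep).sum())} zero-occupancy states")
        idx = np.flatnonzero(keep)
        trans = params.transition[np.ix_(idx, idx)]
        trans = trans / trans.sum(axis=1, keepdims=True)
        init = params.initial[idx]
        init = init / init.sum()
        params = ARHMMParams(A=params.A[idx], b=params.b[idx], sigma=params.sigma[idx],
                             transition=trans, initial=init, lag=lag)

    seqs = []
    for (x, y), m in zip(designs, mats):
        ll = np.stack([_emission_loglik(x, y, params.A[s], params.b[s], params.sigma[s])
                       for s in range(params.n_states)], axis=1)
        core = _viterbi(ll, params.transition, params.initial)
        # frames before the first prediction inherit the first decoded state
        seqs.append(np.concatenate([np.full(lag, core[0]), core]))
    usages = np.stack([state_usages(s, params.n_states) for s in seqs])
    return ARHMMResult(params=params, state_sequences=seqs,
                       log_likelihoods=np.asarray(logliks), usages=usages)


def _em_run(designs, K, d, lag, n_iter, rng, tol, ridge):
    # init: random hard assignment -> M-step
    gammas = []
    for x, y in designs:
        g = rng.dirichlet(np.ones(K), size=len(y))
        gammas.append(g)
    trans = np.full((K, K), 1.0 / K)
    init = np.full(K, 1.0 / K)
    A = np.zeros((K, d, d * lag))
    b = np.zeros((K, d))
    sigma = np.stack([np.eye(d)] * K)
    logliks = []
    occupancy = np.ones(K)
    xi_total = None
    init_acc = None
    for it in range(n_iter + 1):
        # M-step from the responsibilities of the previous E-step (the first
        # iteration uses the random initialization)
        occupancy = np.zeros(K)
        for s in range(K):
            xtx = np.zeros((d * lag + 1, d * lag + 1))
            xty = np.zeros((d * lag + 1, d))
            wsum = 0.0
            for (x, y), g in zip(designs, gammas):
                w = g[:, s]
                xw = x * w[:, None]
                xtx += xw.T @ x
                xty += xw.T @ y
                wsum += w.sum()
            occupancy[s] = wsum
            if wsum < 1e-8:
                continue
            coef = np.linalg.solve(xtx + ridge * np.eye(d * lag + 1), xty)
            A[s] = coef[:-1].T
            b[s] = coef[-1]
            num = np.zeros((d, d))
            for (x, y), g in zip(designs, gammas):
                resid = y - x[:, :-1] @ A[s].T - b[s]
                num += (resid * g[:, s][:, None]).T @ resid
            sigma[s] = num / wsum + ridge * np.eye(d)
        if xi_total is not None:
            row_sums = xi_total.sum(axis=1, keepdims=True)
            trans = np.where(row_sums > 0, xi_total / np.maximum(row_sums, 1e-300),
                             1.0 / K)
            init = init_acc / init_acc.sum()
        # E-step under the freshly updated parameters
        new_gammas = []
        xi_total = np.zeros((K, K))
        init_acc = np.zeros(K)
        total_ll = 0.0
        for x, y in designs:
            ll = np.stack([_emission_loglik(x, y, A[s], b[s], sigma[s])
                           for s in range(K)], axis=1)
            gamma, xi_sum, ll_total = _forward_backward(ll, trans, init)
            new_gammas.append(gamma)
            xi_total += xi_sum
            init_acc += gamma[0]
            total_ll += ll_total
        logliks.append(total_ll)
        gammas = new_gammas
        if it >= 2 and abs(logliks[-1] - logliks[-2]) < tol * abs(logliks[-2]):
            break
    params = ARHMMParams(A=A.copy(), b=b.copy(), sigma=sigma.copy(),
                         transition=trans.copy(), initial=init.copy(), lag=lag)
    params._occupancy = occupancy / max(occupancy.sum(), 1e-300)
    return params, logliks


def state_usages(states: np.ndarray, K: int) -> np.ndarray:
    """Fraction of frames per state; always a point on the simplex."""
    counts = np.bincount(np.asarray(states), minlength=K).astype(float)
    return counts / counts.sum()


@dataclass
class UsageComparison:
    statistic: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    pca_coords: np.ndarray  # (nA+nB, 2) for visualization
    group_sizes: tuple[int, int]


def compare_usages(group_a, group_b) -> UsageComparison:
    """Per-state two-sided Mann-Whitney tests with Benjamini-Hochberg
    correction, plus 2-component PCA coordinates of the pooled usage
    vectors for outlier/batch-effect inspection."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the state count")
    if len(a) < 3 or len(b) < 3:
        warnings.warn("fewer than 3 videos per group; rank tests are weak")
    k = a.shape[1]
    stats = np.empty(k)
    pvals = np.empty(k)
    for s in range(k):
        if np.ptp(a[:, s]) == 0 and np.ptp(b[:, s]) == 0 and a[0, s] == b[0, s]:
            stats[s], pvals[s] = len(a) * len(b) / 2.0, 1.0
            continue
        res = mannwhitneyu(a[:, s], b[:, s], alternative="two-sided")
        stats[s], pvals[s] = res.statistic, res.pvalue
    qvals = false_discovery_control(pvals, method="bh")
    from sklearn.decomposition import PCA

    pooled = np.vstack([a, b])
    n_comp = min(2, pooled.shape[1], len(pooled))
    coords = PCA(n_components=n_comp).fit_transform(pooled)
    return UsageComparison(statistic=stats, p_values=pvals, q_values=qvals,
                           pca_coords=coords, group_sizes=(len(a), len(b)))
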