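"""Ground-truth-labeled synthetic inputs for the whole pipeline.

Three generators:

* :func:`generate_scene_video` — top-view grayscale "arena" videos of one or
  two agents rendered as Gaussian-smoothed oriented ellipses, driven by a
  Markov chain over named behavior states (e.g. idle / chase / contact).
  Labels and agent tracks come back alongside the frames.
* :func:`generate_embedding_clusters` — unit-norm vectors around random
  orthonormal class centroids, a fixture for classifier/anomaly tests.
* :func:`generate_arhmm_series` — a switching linear-autoregressive series
  with known hidden states, a fixture for segmentation-recovery tests.

Frames are the time unit throughout; there is no real-time clock.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StateMotion",
    "EthogramScript",
    "SyntheticScene",
    "generate_scene_video",
    "generate_embedding_clusters",
    "generate_arhmm_series",
    "write_scene",
    "default_two_agent_script",
]


@dataclass
class StateMotion:
    """Per-state motion rule for the scene generator.

    speed: agent speed in px/frame; target_distance: desired inter-agent
    centroid distance in px; contact: whether blobs should overlap;
    jitter: random heading/position noise in px/frame.
    """

    speed: float = 0.0
    target_distance: float = 60.0
    contact: bool = False
    jitter: float = 0.5


@dataclass
class EthogramScript:
    """A Markov chain over named behavior states plus per-state motion rules."""

    states: list[str]
    transition_matrix: np.ndarray
    motion: dict[str, StateMotion]
    duration: int
    seed: int = 0

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.states)
        tm = self.transition_matrix
        if tm.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}")
        if np.any(tm < 0) or np.any(tm > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.duration < 3:
            raise ValueError("duration must be at least 3 frames")
        missing = set(self.states) - set(self.motion)
        if missing:
            raise ValueError(f"no motion rule for states {sorted(missing)}")


@dataclass
class SyntheticScene:
    """Frames (T,H,W) uint8, per-frame state labels, per-agent centroid tracks."""

    frames: np.ndarray        # (T, H, W) uint8
    labels: np.ndarray        # (T,) int state index
    agent_tracks: np.ndarray  # (T, n_agents, 2) float, (x, y), 0-based px
    state_names: list[str]

    def __post_init__(self):
        if not (len(self.labels) == len(self.frames) == len(self.agent_tracks)):
            raise ValueError("frames, labels and tracks must have equal length")


def simulate_markov_chain(tm: np.ndarray, n: int, rng: np.random.Generator,
                          start: int | None = None) -> np.ndarray:
    k = tm.shape[0]
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(k) if start is None else start
    cdf = tm.cumsum(axis=1)
    u = rng.random(n - 1)
    for t in range(1, n):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t - 1], side="right")
    return states


def _render_frame(h: int, w: int, positions, headings, semi_axes) -> np.ndarray:
    """Anti-aliased oriented Gaussian ellipses on a dark background.

    A brightness gradient along the major axis marks the "head", giving
    rotation-sensitive texture.
    """
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.zeros((h, w), dtype=float)
    for (x, y), th, (a, b) in zip(positions, headings, semi_axes):
        dx, dy = xx - x, yy - y
        along = dx * np.cos(th) + dy * np.sin(th)
        across = -dx * np.sin(th) + dy * np.cos(th)
        q = (along / a) ** 2 + (across / b) ** 2
        blob = 230.0 * np.exp(-0.5 * q * 4.0)
        blob *= 1.0 + 0.35 * np.tanh(along / a)  # head brighter than tail
        img = np.maximum(img, blob)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_scene_video(script: EthogramScript, arena: tuple[int, int] = (224, 224),
                         n_agents: int = 2,
                         semi_axes: tuple[float, float] | None = None,
                         start_state: int | None = None) -> SyntheticScene:
    """Render a two-agent (or single-agent) behavior video from a script.

    Deterministic given ``script.seed``.  Agent 0 wanders; agent 1 (if
    present) steers to hold the state's target centroid distance, with
    contact states collapsing that distance below the blob size.  Ellipse
    semi-axes default to arena/12 and arena/27: an animal's body spans
    roughly a quarter of a tight top-view arena crop, as in a fly
    courtship chamber.
    """
    h, w = arena
    if semi_axes is None:
        semi_axes = (min(h, w) / 12.0, min(h, w) / 27.0)
    a_ax, b_ax = semi_axes
    if 2 * a_ax >= min(h, w) or 2 * b_ax >= min(h, w):
        raise ValueError("agent ellipse does not fit into the arena")
    if n_agents not in (1, 2):
        raise ValueError("n_agents must be 1 or 2")
    rng = np.random.default_rng(script.seed)
    t_total = script.duration
    labels = simulate_markov_chain(script.transition_matrix, t_total, rng, start_state)

    margin = 2.5 * a_ax
    pos = rng.uniform([margin, margin], [w - margin, h - margin], size=(n_agents, 2))
    headings = rng.uniform(0, 2 * np.pi, size=n_agents)
    frames = np.empty((t_total, h, w), dtype=np.uint8)
    tracks = np.empty((t_total, n_agents, 2), dtype=float)

    for t in range(t_total):
        rule = script.motion[script.states[labels[t]]]
        target_d = 0.0 if rule.contact else rule.target_distance
        # agent 0: wander with smooth heading noise
        headings[0] += rng.normal(0, 0.25) + rule.jitter * rng.normal(0, 0.1)
        step0 = rule.speed + rule.jitter * rng.normal()
        pos[0] += step0 * np.array([np.cos(headings[0]), np.sin(headings[0])])
        if n_agents == 2:
            # agent 1: steer toward the circle of radius target_d around agent 0
            delta = pos[0] - pos[1]
            dist = np.linalg.norm(delta)
            radial = (dist - target_d)
            direction = delta / dist if dist > 1e-9 else np.array([1.0, 0.0])
            # corrective speed large enough that a state change settles within
            # a few frames, keeping per-state pixel statistics distinct
            follow_speed = max(2.0 * rule.speed, 3.0)
            gain = min(abs(radial), follow_speed) * np.sign(radial)
            pos[1] += gain * direction + rule.jitter * rng.normal(size=2)
            headings[1] = np.arctan2(direction[1], direction[0])
        # keep inside the arena
        for i in range(n_agents):
            for axis, limit in ((0, w), (1, h)):
                if pos[i, axis] < margin:
                    pos[i, axis] = margin + (margin - pos[i, axis])
                    if i == 0:
                        headings[0] = np.pi - headings[0] if axis == 0 else -headings[0]
                if pos[i, axis] > limit - margin:
                    pos[i, axis] = 2 * (limit - margin) - pos[i, axis]
                    if i == 0:
                        headings[0] = np.pi - headings[0] if axis == 0 else -headings[0]
        frames[t] = _render_frame(h, w, pos, headings, [(a_ax, b_ax)] * n_agents)
        tracks[t] = pos
    return SyntheticScene(frames=frames, labels=labels, agent_tracks=tracks,
                          state_names=list(script.states))


def default_two_agent_script(duration: int = 1000, seed: int = 0,
                             arena_size: int = 224) -> EthogramScript:
    """A 3-state chase / contact / idle ethogram with sticky transitions.

    Target inter-agent distances scale with the arena so the same ethogram
    works at full resolution and at small test scales: idle keeps the
    agents far apart and slow, chase is fast pursuit at a moderate
    distance, contact overlaps the blobs.
    """
    tm = np.array([
        [0.95, 0.03, 0.02],
        [0.04, 0.92, 0.04],
        [0.03, 0.05, 0.92],
    ])
    far = 0.55 * arena_size
    near = 0.18 * arena_size
    motion = {
        "idle": StateMotion(speed=0.2, target_distance=far, jitter=0.3),
        "chase": StateMotion(speed=4.0, target_distance=near, jitter=1.0),
        "contact": StateMotion(speed=0.8, target_distance=0.0, contact=True, jitter=0.5),
    }
    return EthogramScript(states=["idle", "chase", "contact"], transition_matrix=tm,
                          motion=motion, duration=duration, seed=seed)


def generate_embedding_clusters(n_classes: int, n_per_class: int, dim: int,
                                separation: float, seed: int = 0):
    """Unit-norm rows around random orthonormal class centroids.

    Angular dispersion shrinks as ``separation`` grows; ``separation == inf``
    (or very large) collapses every row onto its class centroid.
    Returns ``(matrix (n_classes*n_per_class) x dim, labels)``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if dim < n_classes:
        raise ValueError("dim must be >= n_classes to place near-orthogonal centroids")
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(dim, n_classes))
    q, _ = np.linalg.qr(g)
    centroids = q.T[:n_classes]  # orthonormal rows
    rows, labels = [], []
    for c in range(n_classes):
        noise = rng.normal(size=(n_per_class, dim))
        if separation == 0:
            x = noise
        elif np.isinf(separation):
            x = np.tile(centroids[c], (n_per_class, 1))
        else:
            x = centroids[c] + noise / separation
        norm = np.linalg.norm(x, axis=1, keepdims=True)
        rows.append(x / np.maximum(norm, 1e-12))
        labels.append(np.full(n_per_class, c))
    return np.vstack(rows), np.concatenate(labels)


def generate_arhmm_series(params, n_frames: int, seed: int = 0):
    """Simulate a switching vector-autoregression with hidden Markov states.

    ``x_t = A_s [x_{t-lag}; ...; x_{t-1}] + b_s + noise`` where ``s`` follows
    the transition matrix.  Returns ``(observations (n_frames x d), states)``.
    Warns if any AR matrix is (near-)unstable.
    """
    from .timeseries import ARHMMParams  # local import to avoid a cycle

    if not isinstance(params, ARHMMParams):
        raise TypeError("params must be ARHMMParams")
    if n_frames <= params.lag:
        raise ValueError("n_frames must exceed the AR lag order")
    d, lag, k = params.dim, params.lag, params.n_states
    for s in range(k):
        comp = _companion_matrix(params.A[s], d, lag)
        if np.max(np.abs(np.linalg.eigvals(comp))) >= 1.05:
            warnings.warn(f"AR matrix of state {s} is unstable (spectral radius >= 1.05)")
    rng = np.random.default_rng(seed)
    if params.initial is not None:
        start = int(rng.choice(k, p=params.initial))
    else:
        start = None
    states = simulate_markov_chain(params.transition, n_frames, rng, start)
    x = np.zeros((n_frames, d))
    chol = [np.linalg.cholesky(params.sigma[s]) for s in range(k)]
    x[:lag] = params.b[states[0]] + rng.normal(size=(lag, d)) @ chol[states[0]].T
    for t in range(lag, n_frames):
        s = states[t]
        hist = x[t - lag:t].reshape(-1)  # oldest first
        noise = chol[s] @ rng.normal(size=d) if np.any(params.sigma[s]) else np.zeros(d)
        x[t] = params.A[s] @ hist + params.b[s] + noise
    return x, states


def _companion_matrix(A: np.ndarray, d: int, lag: int) -> np.ndarray:
    comp = np.zeros((d * lag, d * lag))
    if lag > 1:
        comp[:-d, d:] = np.eye(d * (lag - 1))
    comp[-d:, :] = A
    return comp


def write_scene(scene: SyntheticScene, out_dir) -> Path:
    """Write frames as zero-padded PNGs plus labels.csv and tracks.csv."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(scene.frames):
        iio.imwrite(out / f"{i:06d}.png", frame)
    with open(out / "labels.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame", "label"])
        for i, lab in enumerate(scene.labels):
            wr.writerow([i, int(lab)])
    with open(out / "tracks.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame", "agent", "x", "y"])
        for i in range(len(scene.frames)):
            for a in range(scene.agent_tracks.shape[1]):
                x, y = scene.agent_tracks[i, a]
                wr.writerow([i, a, f"{x:.3f}", f"{y:.3f}"])
    return out
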