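"""Batch samplers, one-cycle learning-rate schedule, and the training loop.

Defaults follow the published recipe: 20,000 steps of SGD (momentum 0.9,
weight decay 1e-4, decay excluded from batch-norm parameters and biases),
batch size 256, one-cycle learning-rate policy with pct_start 0.025 and a
base learning rate of 0.025 per 256 samples (0.05 for fine-tuning), and a
choice of cross-video or within-video batch composition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentPolicy, augment_live_frame
from .model import NetworkConfig, SelfeeNet, load_checkpoint, save_checkpoint
from .nn import SGD, l2_normalize
from .objective import LossConfig, cld_loss_grads, cluster_batch, collapse_level, similarity_loss_grads
from .preprocess import FrameStore

__all__ = ["TrainConfig", "sample_batches", "one_cycle_lr", "fit"]


@dataclass
class TrainConfig:
    steps: int = 20000
    batch_size: int = 256
    momentum: float = 0.9
    weight_decay: float = 1e-4
    base_lr_per_256: float = 0.025  # 0.05 for fine-tuning runs
    pct_start: float = 0.025
    div_factor: float = 25.0
    final_div: float = 1e4
    sampler_mode: str = "cross_video"
    stride: int = 1
    seed: int = 0
    checkpoint_every: int = 1000

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.base_lr_per_256 <= 0:
            raise ValueError("base learning rate must be positive")
        if self.sampler_mode not in ("cross_video", "within_video"):
            raise ValueError(f"unknown sampler mode {self.sampler_mode!r}")

    @property
    def max_lr(self) -> float:
        """Linear-scaling rule: base rate per 256 samples."""
        return self.base_lr_per_256 * self.batch_size / 256.0


def sample_batches(manifest: dict[str, "np.ndarray | range | list"], mode: str,
                   batch_size: int, seed: int = 0):
    """Infinite iterator of ``[(video_id, frame_index), ...]`` batches.

    ``cross_video``: all (video, frame) pairs are globally shuffled each
    epoch and consumed in order, so batches mix videos.  ``within_video``:
    videos are visited in shuffled order and every batch is drawn from a
    single video (sampling with replacement, with a warning, when a video is
    shorter than the batch).  Deterministic under ``seed``.
    """
    if mode not in ("cross_video", "within_video"):
        raise ValueError(f"unknown sampler mode {mode!r}")
    items = {vid: np.asarray(list(idx)) for vid, idx in manifest.items()}
    if not items or all(len(v) == 0 for v in items.values()):
        raise ValueError("manifest contains no frames")
    rng = np.random.default_rng(seed)
    if mode == "cross_video":
        pool = [(vid, int(i)) for vid, idx in sorted(items.items()) for i in idx]
        if len(pool) < batch_size:
            raise ValueError("not enough frames for a single batch")
        while True:
            order = rng.permutation(len(pool))
            for start in range(0, len(pool) - batch_size + 1, batch_size):
                yield [pool[j] for j in order[start:start + batch_size]]
    else:
        vids = sorted(items)
        warned = set()
        while True:
            for vi in rng.permutation(len(vids)):
                vid = vids[vi]
                idx = items[vid]
                if len(idx) < batch_size:
                    if vid not in warned:
                        warnings.warn(
                            f"video {vid!r} shorter than batch size; sampling with replacement")
                        warned.add(vid)
                    chosen = rng.choice(idx, size=batch_size, replace=True)
                    yield [(vid, int(i)) for i in chosen]
                    continue
                perm = rng.permutation(len(idx))
                for start in range(0, len(idx) - batch_size + 1, batch_size):
                    yield [(vid, int(idx[j])) for j in perm[start:start + batch_size]]


def one_cycle_lr(step: int, cfg: TrainConfig) -> float:
    """Cosine-annealed one-cycle schedule.

    Rises from ``max_lr / div_factor`` to ``max_lr`` over the first
    ``pct_start * steps`` steps, then anneals to ``max_lr / final_div``.
    """
    if not 0 <= step < cfg.steps:
        raise ValueError(f"step {step} outside [0, {cfg.steps})")
    peak = int(round(cfg.pct_start * cfg.steps))
    max_lr = cfg.max_lr
    initial = max_lr / cfg.div_factor
    final = max_lr / cfg.final_div
    if step <= peak and peak > 0:
        t = step / peak
        return initial + (max_lr - initial) * (1 - np.cos(np.pi * t)) / 2
    denom = max(cfg.steps - 1 - peak, 1)
    t = (step - peak) / denom
    return final + (max_lr - final) * (1 + np.cos(np.pi * t)) / 2


def _to_input(batch_u8: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 (N, 3, H, W) scaled to [-1, 1]."""
    x = batch_u8.astype(np.float32) / 255.0
    return np.ascontiguousarray((x - 0.5) / 0.5).transpose(0, 3, 1, 2)


def fit(stores: list[FrameStore], net_cfg: NetworkConfig, loss_cfg: LossConfig,
        train_cfg: TrainConfig, policy: AugmentPolicy | None = None,
        out_dir=None, resume_from=None, log_every: int = 1):
    """Train the twin network on preprocessed frame stores.

    Per step: draw a batch of (video, center) pairs, build live-frames,
    augment each twice, run both views through the shared network as one
    concatenated pass, apply the combined loss, and take an SGD step at the
    one-cycle learning rate.  Loss terms and the collapse level are logged
    each step.  Fully deterministic given ``train_cfg.seed`` (per-step RNG
    streams are derived from the seed and the step index, so a resumed run
    reproduces the original step-for-step).

    Returns ``(net, log)`` where ``log`` is a list of per-step records.
    """
    if not stores:
        raise ValueError("at least one video is required")
    policy = policy or AugmentPolicy()
    stride = train_cfg.stride
    manifest = {}
    store_by_id = {}
    for st in stores:
        if len(st) < 2 * stride + 1:
            raise ValueError(f"video {st.video_id!r} too short for stride {stride}")
        manifest[st.video_id] = range(stride, len(st) - stride)
        store_by_id[st.video_id] = st

    start_step = 0
    if resume_from is not None:
        net, meta = load_checkpoint(resume_from)
        start_step = meta["step"]
        opt = SGD(net.params(), momentum=train_cfg.momentum,
                  weight_decay=train_cfg.weight_decay)
        if meta["opt_state"]:
            opt.load_state_dict(meta["opt_state"])
    else:
        net = SelfeeNet(net_cfg, seed=train_cfg.seed)
        opt = SGD(net.params(), momentum=train_cfg.momentum,
                  weight_decay=train_cfg.weight_decay)

    batches = sample_batches(manifest, train_cfg.sampler_mode,
                             train_cfg.batch_size, seed=train_cfg.seed)
    for _ in range(start_step):  # fast-forward the deterministic sampler
        next(batches)

    out_path = Path(out_dir) if out_dir is not None else None
    log_fh = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "config.json").write_text(json.dumps({
            "network": asdict(net_cfg), "loss": asdict(loss_cfg),
            "train": asdict(train_cfg), "augment": asdict(policy)}, indent=1))
        log_fh = open(out_path / "train_log.jsonl", "a")

    log: list[dict] = []
    collapse_run = 0
    try:
        for step in range(start_step, train_cfg.steps):
            batch = next(batches)
            rng_step = np.random.default_rng([train_cfg.seed, 7919, step])
            n = len(batch)
            views_a, views_b = [], []
            for vid, c in batch:
                f = store_by_id[vid].frames
                live = np.stack([f[c - stride], f[c], f[c + stride]], axis=2)
                views_a.append(augment_live_frame(live, policy, rng_step))
                views_b.append(augment_live_frame(live, policy, rng_step))
            xa = _to_input(np.stack(views_a))
            xb = _to_input(np.stack(views_b))

            out_a, out_b, cache = net.forward_train(xa, xb)
            loss1, dpa, dpb = similarity_loss_grads(out_a, out_b)
            if loss_cfg.lam > 0:
                ca = cluster_batch(out_a.v, loss_cfg, rng_step)
                cb = cluster_batch(out_b.v, loss_cfg, rng_step)
                loss2, dva, dvb = cld_loss_grads(out_a, out_b, ca, cb, loss_cfg)
            else:
                loss2 = 0.0
                dva = np.zeros_like(out_a.v)
                dvb = np.zeros_like(out_b.v)
            loss = loss1 + loss_cfg.lam * loss2

            dz = np.zeros((2 * n, out_a.z.shape[1]), dtype=np.float32)
            dp = np.concatenate([dpa, dpb]).astype(np.float32)
            dv = (loss_cfg.lam * np.concatenate([dva, dvb])).astype(np.float32)
            lr = one_cycle_lr(step, train_cfg)
            opt.zero_grad()
            net.backward(dz, dp, dv, cache)
            opt.step(lr)

            clp = collapse_level(l2_normalize(out_a.z))
            collapse_run = collapse_run + 1 if clp > 0.95 else 0
            record = {"step": step, "loss": float(loss), "loss1": float(loss1),
                      "loss2": float(loss2), "lr": float(lr), "collapse": float(clp)}
            if collapse_run >= 500:
                record["warning"] = "mode collapse"
                if collapse_run == 500:
                    warnings.warn("mode collapse: collapse level > 0.95 for 500 steps")
            if step % log_every == 0 or step == train_cfg.steps - 1:
                log.append(record)
                if log_fh is not None:
                    log_fh.write(json.dumps(record) + "\n")
                    log_fh.flush()
            if out_path is not None and (
                    (step + 1) % train_cfg.checkpoint_every == 0
                    or step == train_cfg.steps - 1):
                save_checkpoint(out_path / f"checkpoint_{step + 1:06d}.npz",
                                net, step=step + 1, optimizer=opt)
    finally:
        if log_fh is not None:
            log_fh.close()
    return net, log
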