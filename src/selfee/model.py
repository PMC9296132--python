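"""The twin-branch feature-extraction network.

A single weight-shared network processes both augmented views of each
live-frame.  It is composed of

* a convolutional backbone (a standard 50-layer residual CNN by default, or
  a small 4-block CNN for CPU-scale work) ending in global average pooling,
* a 3-layer MLP *projector* (hidden layers BN+ReLU, output layer BN only)
  whose output ``z`` is the Meta-representation used at inference time,
* a 2-layer bottleneck MLP *predictor* producing ``p``,
* a *group discriminator*: one weight-normalized linear map followed by L2
  normalization, producing unit-norm ``v`` for the cluster-discrimination
  loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (
    SGD,
    BatchNorm,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    NormalizedLinear,
    ReLU,
    Residual,
    Sequential,
)

__all__ = ["NetworkConfig", "BranchOutputs", "SelfeeNet", "save_checkpoint", "load_checkpoint"]


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    Defaults reproduce the published architecture: ResNet-50-style backbone,
    2048-d projector, 512-d predictor bottleneck, 1024-d discriminator.
    Smaller widths are intended for CPU-scale experiments.
    """

    backbone: str = "resnet50"
    proj_dim: int = 2048
    pred_hidden: int = 512
    disc_dim: int = 1024
    in_channels: int = 3
    small_width: int = 16  # first-stage width of the small backbone

    def __post_init__(self):
        if self.backbone not in ("resnet50", "small"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        for name in ("proj_dim", "pred_hidden", "disc_dim", "in_channels", "small_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class BranchOutputs:
    """Per-batch projector (z), predictor (p) and discriminator (v) outputs."""

    z: np.ndarray  # n x proj_dim
    p: np.ndarray  # n x proj_dim
    v: np.ndarray  # n x disc_dim, unit-norm rows


def _conv_bn_relu(cin, cout, k, stride, rng, name):
    return [Conv2d(cin, cout, k, stride, rng=rng, name=f"{name}.conv"),
            BatchNorm(cout, name=f"{name}.bn"), ReLU()]


def _small_backbone(cfg: NetworkConfig, rng) -> tuple[Sequential, int]:
    """Four stride-2 conv blocks + global average pooling."""
    w = cfg.small_width
    widths = [w, 2 * w, 4 * w, 8 * w]
    layers: list[Layer] = []
    cin = cfg.in_channels
    for i, cout in enumerate(widths):
        layers += _conv_bn_relu(cin, cout, 3, 2, rng, f"b{i}")
        cin = cout
    layers.append(GlobalAvgPool())
    return Sequential(*layers), widths[-1]


def _bottleneck(cin, width, stride, rng, name) -> Residual:
    cout = 4 * width
    main = Sequential(
        Conv2d(cin, width, 1, 1, pad=0, rng=rng, name=f"{name}.c1"),
        BatchNorm(width, name=f"{name}.bn1"), ReLU(),
        Conv2d(width, width, 3, stride, rng=rng, name=f"{name}.c2"),
        BatchNorm(width, name=f"{name}.bn2"), ReLU(),
        Conv2d(width, cout, 1, 1, pad=0, rng=rng, name=f"{name}.c3"),
        BatchNorm(cout, name=f"{name}.bn3"),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = Sequential(
            Conv2d(cin, cout, 1, stride, pad=0, rng=rng, name=f"{name}.down"),
            BatchNorm(cout, name=f"{name}.downbn"),
        )
    return Residual(main, shortcut)


def _resnet50_backbone(cfg: NetworkConfig, rng) -> tuple[Sequential, int]:
    layers: list[Layer] = [
        Conv2d(cfg.in_channels, 64, 7, 2, pad=3, rng=rng, name="stem.conv"),
        BatchNorm(64, name="stem.bn"), ReLU(),
        MaxPool2d(3, 2, pad=1),
    ]
    cin = 64
    for stage, (width, blocks) in enumerate(zip((64, 128, 256, 512), (3, 4, 6, 3))):
        for b in range(blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(_bottleneck(cin, width, stride, rng, f"s{stage}.b{b}"))
            cin = 4 * width
    layers.append(GlobalAvgPool())
    return Sequential(*layers), cin


class SelfeeNet:
    """Backbone + projector + predictor + group discriminator.

    The discriminator acts on the projector output.  ``forward_train`` runs
    both views through the network as one concatenated batch, so batch-norm
    statistics are computed (and running statistics updated) exactly once
    per optimizer step.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        builder = _resnet50_backbone if cfg.backbone == "resnet50" else _small_backbone
        self.backbone, feat_dim = builder(cfg, rng)
        self.feature_dim = feat_dim
        d = cfg.proj_dim
        self.projector = Sequential(
            Linear(feat_dim, d, bias=False, rng=rng, name="proj.fc1"),
            BatchNorm(d, name="proj.bn1"), ReLU(),
            Linear(d, d, bias=False, rng=rng, name="proj.fc2"),
            BatchNorm(d, name="proj.bn2"), ReLU(),
            Linear(d, d, bias=False, rng=rng, name="proj.fc3"),
            BatchNorm(d, name="proj.bn3"),
        )
        self.predictor = Sequential(
            Linear(d, cfg.pred_hidden, bias=False, rng=rng, name="pred.fc1"),
            BatchNorm(cfg.pred_hidden, name="pred.bn1"), ReLU(),
            Linear(cfg.pred_hidden, d, bias=True, rng=rng, name="pred.fc2"),
        )
        self.discriminator = NormalizedLinear(d, cfg.disc_dim, rng=rng, name="disc")
        self._modules = {
            "backbone": self.backbone,
            "projector": self.projector,
            "predictor": self.predictor,
            "discriminator": self.discriminator,
        }

    # ---------------------------------------------------------------- params
    def params(self):
        return [p for m in self._modules.values() for p in m.params()]

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # --------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, train: bool):
        """One pass: returns (z, p, v, cache)."""
        f, c_bb = self.backbone.forward(x, train)
        z, c_pj = self.projector.forward(f, train)
        p, c_pd = self.predictor.forward(z, train)
        v, c_ds = self.discriminator.forward(z, train)
        return z, p, v, (c_bb, c_pj, c_pd, c_ds)

    def backward(self, dz: np.ndarray, dp: np.ndarray, dv: np.ndarray, cache) -> None:
        """Accumulate parameter gradients for one forward pass.

        ``dz`` is the *direct* gradient on z (zero under the stop-gradient
        similarity loss); gradients through the predictor and discriminator
        are added to it before the projector/backbone backward.
        """
        c_bb, c_pj, c_pd, c_ds = cache
        dz_total = np.asarray(dz, dtype=dp.dtype).copy()
        dz_total += self.predictor.backward(dp, c_pd)
        dz_total += self.discriminator.backward(dv, c_ds)
        df = self.projector.backward(dz_total, c_pj)
        self.backbone.backward(df, c_bb)

    def forward_train(self, view_a: np.ndarray, view_b: np.ndarray):
        """Two views, one concatenated pass; returns (out_a, out_b, cache)."""
        if view_a.shape[0] != view_b.shape[0]:
            raise ValueError(
                f"mismatched batch sizes: {view_a.shape[0]} vs {view_b.shape[0]}")
        n = view_a.shape[0]
        x = np.concatenate([view_a, view_b], axis=0)
        z, p, v, cache = self.forward(x, train=True)
        out_a = BranchOutputs(z[:n], p[:n], v[:n])
        out_b = BranchOutputs(z[n:], p[n:], v[n:])
        return out_a, out_b, cache

    def forward_infer(self, x: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode pass; the representation is the projector
        output (not the predictor, not the discriminator)."""
        _, c_bb = (None, None)
        f, _ = self.backbone.forward(x, train=False)
        z, _ = self.projector.forward(f, train=False)
        return z

    # ------------------------------------------------------------ state i/o
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for mname, mod in self._modules.items():
            for p in mod.params():
                out[f"{mname}.{p.name}"] = p.value
            for key, buf in mod.buffers().items():
                out[f"{mname}.buffer.{key}"] = buf
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing arrays: {sorted(missing)[:5]} ...")
        for key, arr in own.items():
            src = np.asarray(state[key])
            if src.shape != arr.shape:
                raise ValueError(
                    f"checkpoint/backbone mismatch for {key}: {src.shape} vs {arr.shape}")
            arr[...] = src.astype(arr.dtype)


def save_checkpoint(path, net: SelfeeNet, step: int = 0,
                    optimizer: SGD | None = None, rng_state: dict | None = None) -> None:
    """Single-archive checkpoint: weights + NetworkConfig + training step."""
    arrays = {f"net.{k}": v for k, v in net.state_dict().items()}
    if optimizer is not None:
        arrays.update({f"opt.{k}": v for k, v in optimizer.state_dict().items()})
    meta = {"config": asdict(net.cfg), "step": int(step)}
    if rng_state is not None:
        meta["rng_state"] = rng_state
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[SelfeeNet, dict]:
    """Load a checkpoint; validates array shapes against the stored config."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        cfg = NetworkConfig(**meta["config"])
        net = SelfeeNet(cfg, seed=0)
        net.load_state_dict({k[4:]: data[k] for k in data.files if k.startswith("net.")})
        meta["opt_state"] = {k[4:]: data[k] for k in data.files if k.startswith("opt.")}
    return net, meta
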