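"""Pretext classifier: residual CNN backbone plus a 3-layer projection head.

Two presets ship: ``resnet18`` — an 18-layer residual network (stem, four
stages of two basic blocks, 512-d pooled features) matching the reference
training recipe at 256x256 — and ``tiny``, a small residual network for
64x64 inputs that trains in seconds on one CPU and is used by the test
suite. The embedding tap defaults to the backbone's global-pooled vector;
the head's penultimate activation is available as an alternative.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn

__all__ = [
    "TrainConfig",
    "PretextModel",
    "build_model",
    "pretext_loss",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
]

BACKBONES = ("tiny", "resnet18")
EMBED_TAPS = ("backbone", "head_penultimate")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the pretext training recipe.

    Defaults follow the reference recipe: SGD with initial learning rate
    0.03, momentum 0.9, weight decay 3e-5, batch size 64, 256 epochs,
    cycle cosine annealing, best checkpoint by validation AUC.
    """

    backbone: str = "resnet18"
    head_layers: int = 3
    batch_size: int = 64
    lr: float = 0.03
    momentum: float = 0.9
    weight_decay: float = 3e-5
    epochs: int = 256
    schedule: str = "cycle_cosine"
    cycle_len: int | None = None
    image_size: int = 256
    seed: int = 0
    device: str = "cpu"
    embed_tap: str = "backbone"

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.embed_tap not in EMBED_TAPS:
            raise ValueError(f"unknown embed_tap {self.embed_tap!r}")
        if self.lr <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("epochs >= 1 and batch_size >= 2 required")

    @classmethod
    def tiny(cls, **kw) -> "TrainConfig":
        """Small CPU preset used by tests and the scaled-down evaluation."""
        kw.setdefault("backbone", "tiny")
        kw.setdefault("image_size", 64)
        kw.setdefault("epochs", 20)
        kw.setdefault("batch_size", 32)
        return cls(**kw)


def _build_backbone(name: str, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    if name == "tiny":
        net = nn.Sequential(
            nn.Conv2d(1, 16, 3, stride=2, pad=1, rng=rng),
            nn.BatchNorm2d(16),
            nn.ReLU(),
            nn.ResidualBlock(16, 32, 2, rng=rng),
            nn.ResidualBlock(32, 64, 2, rng=rng),
            nn.ResidualBlock(64, 128, 2, rng=rng),
            nn.GlobalAvgPool(),
        )
        return net, 128
    # resnet18: 7x7/2 stem + maxpool + stages (64,64,128,128,256,256,512,512)
    blocks = [
        nn.ResidualBlock(64, 64, 1, rng=rng),
        nn.ResidualBlock(64, 64, 1, rng=rng),
        nn.ResidualBlock(64, 128, 2, rng=rng),
        nn.ResidualBlock(128, 128, 1, rng=rng),
        nn.ResidualBlock(128, 256, 2, rng=rng),
        nn.ResidualBlock(256, 256, 1, rng=rng),
        nn.ResidualBlock(256, 512, 2, rng=rng),
        nn.ResidualBlock(512, 512, 1, rng=rng),
    ]
    net = nn.Sequential(
        nn.Conv2d(1, 64, 7, stride=2, pad=3, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(),
        *blocks,
        nn.GlobalAvgPool(),
    )
    return net, 512


def _head_widths(embed_dim: int, n_layers: int) -> list[int]:
    widths = [embed_dim]
    for _ in range(n_layers - 1):
        widths.append(max(8, widths[-1] // 2))
    widths.append(2)
    return widths


class PretextModel:
    """Backbone + projection head with an embedding tap."""

    def __init__(self, config: TrainConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB0DE]))
        self.backbone, self.embed_dim = _build_backbone(config.backbone, rng)
        widths = _head_widths(self.embed_dim, config.head_layers)
        layers: list[nn.Module] = []
        for i in range(len(widths) - 1):
            layers.append(nn.Dense(widths[i], widths[i + 1], rng=rng))
            if i < len(widths) - 2:
                layers.append(nn.ReLU())
        self.head = nn.Sequential(*layers)
        self.norm_mean: float = 0.0
        self.norm_std: float = 1.0

    # --- forward/backward -------------------------------------------------
    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] != self.config.image_size or x.shape[-2] != self.config.image_size:
            raise ValueError(
                f"expected {self.config.image_size}x{self.config.image_size} images, "
                f"got {x.shape[-2]}x{x.shape[-1]}"
            )
        return (x - np.float32(self.norm_mean)) / np.float32(self.norm_std)

    def forward(self, images: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Returns (logits (N,2), embedding (N,D)) for a stack of images."""
        x = self._prepare(images)
        pooled = self.backbone.forward(x, train)
        if self.config.embed_tap == "backbone":
            embed = pooled
            logits = self.head.forward(pooled, train)
        else:
            h = pooled
            for layer in self.head.layers[:-1]:
                h = layer.forward(h, train)
            embed = h
            logits = self.head.layers[-1].forward(h, train)
        return logits, embed

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits)
        self.backbone.backward(g)

    def parameters(self) -> list[nn.Param]:
        return self.backbone.parameters() + self.head.parameters()

    def zero_grad(self) -> None:
        self.backbone.zero_grad()
        self.head.zero_grad()

    # --- state ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        arrays = self.backbone.state_arrays() + self.head.state_arrays()
        return {f"arr_{i:04d}": a.copy() for i, a in enumerate(arrays)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        arrays = self.backbone.state_arrays() + self.head.state_arrays()
        if len(arrays) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model needs {len(arrays)}")
        for i, a in enumerate(arrays):
            src = state[f"arr_{i:04d}"]
            if src.shape != a.shape:
                raise ValueError(f"array {i} shape mismatch: {src.shape} vs {a.shape}")
            a[...] = src

    def checksum(self) -> float:
        return float(sum(np.abs(a.astype(np.float64)).sum() for a in self.backbone.state_arrays() + self.head.state_arrays()))


def build_model(config: TrainConfig) -> PretextModel:
    """Construct a pretext model with seeded weight initialization."""
    return PretextModel(config)


def pretext_loss(
    pred_normal: np.ndarray, pred_aug: np.ndarray, from_logits: bool = False
) -> float:
    """Mean over image pairs of CE(pred_normal, 0) + CE(pred_aug, 1).

    Inputs are (N, 2) probability pairs, or logits with ``from_logits=True``.
    """
    pn = np.atleast_2d(np.asarray(pred_normal, dtype=np.float64))
    pa = np.atleast_2d(np.asarray(pred_aug, dtype=np.float64))
    if pn.shape != pa.shape or pn.shape[1] != 2:
        raise ValueError("predictions must be matching (N, 2) arrays")
    if not (np.isfinite(pn).all() and np.isfinite(pa).all()):
        raise ValueError("non-finite predictions")
    if from_logits:
        lpn, lpa = nn.log_softmax(pn), nn.log_softmax(pa)
    else:
        if pn.min() < 0 or pa.min() < 0 or pn.max() > 1 or pa.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        eps = 1e-12
        lpn, lpa = np.log(np.clip(pn, eps, 1.0)), np.log(np.clip(pa, eps, 1.0))
    return float(np.mean(-lpn[:, 0] - lpa[:, 1]))


def extract_features(
    model: PretextModel, images: np.ndarray | list[np.ndarray], batch_size: int = 64
) -> np.ndarray:
    """Deterministic (N, D) embeddings in inference mode.

    Uses batch-norm running statistics, so the result is independent of how
    the images are batched.
    """
    stack = np.stack([np.asarray(im) for im in images]) if isinstance(images, list) else np.asarray(images)
    if stack.ndim == 2:
        stack = stack[None]
    out = []
    for start in range(0, stack.shape[0], batch_size):
        _, emb = model.forward(stack[start : start + batch_size], train=False)
        out.append(emb.astype(np.float64))
    return np.concatenate(out, axis=0)


def save_checkpoint(model: PretextModel, path: str) -> None:
    """Bundle weights, config, and normalization stats into one .npz file."""
    meta = {
        "config": asdict(model.config),
        "norm_mean": model.norm_mean,
        "norm_std": model.norm_std,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path: str) -> PretextModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(TrainConfig(**meta["config"]))
    model.load_state_dict(state)
    model.norm_mean = meta["norm_mean"]
    model.norm_std = meta["norm_std"]
    return model
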