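"""The feature-extraction model: backbone → GeM pooling → embedding head.

Architecture (mirroring the retrieval system this package implements):

* a convolutional **backbone** producing a final W×H×K activation map —
  either an inception-style network with K = 1024 final channels
  (``googlenet`` preset) or a 4-block small CNN (``tiny`` preset, K
  configurable) for desk-scale experiments;
* **GeM pooling** with fixed exponent p = 3 collapsing the map to a
  K-vector;
* an **embedding head** FC → BatchNorm → PReLU reducing K to 256 (or 64 /
  128 / 512 for the dimension sweep);
* an **ArcFace head** (scale 64, additive angular margin 38°) used only
  during training; retrieval uses the L2-normalized embedding.

Training is single-stage SGD with momentum on random mini-batches, with
augmentation applied to training images only.  Everything is numpy, so a
fixed seed yields an identical loss trace and identical weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .dicom_io import UIDTriple
from .preprocess import MODEL_INPUT_SIZE, AugmentParams, augment
from .retrieval import FeatureVector

__all__ = [
    "TrainConfig",
    "FeatureExtractor",
    "train_model",
    "extract_features",
    "extract_feature",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Model + optimization configuration.

    The full preset follows the reference conditions (inception-class
    backbone, 150k iterations); :meth:`desk` is the scaled-down preset used
    for CPU-only experiments and tests.
    """

    backbone: str = "googlenet"  # "googlenet" | "tiny"
    embedding_dim: int = 256
    gem_p: float = 3.0
    arcface_scale: float = 64.0
    arcface_margin_deg: float = 38.0
    n_classes: int = 7
    batch_size: int = 32
    iterations: int = 150_000
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0
    optimizer: str = "sgd"
    seed: int = 0
    tiny_channels: int = 64
    sampling: str = "balanced"  # "balanced" (uniform over classes) | "uniform"
    lr_schedule: str = "cosine"  # "cosine" | "constant"
    warmup_iterations: int = 150  # linear LR ramp; stabilizes the margin loss early
    augment: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (BatchNorm in train mode)")
        if self.backbone not in ("googlenet", "tiny"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be positive")
        if self.optimizer != "sgd":
            raise ValueError("only the 'sgd' optimizer is implemented")
        if self.sampling not in ("balanced", "uniform"):
            raise ValueError("sampling must be 'balanced' or 'uniform'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """CPU-scale preset: tiny backbone, short single-stage cosine schedule."""
        base = dict(backbone="tiny", iterations=1100, batch_size=24, lr=0.015, weight_decay=1e-4)
        base.update(overrides)
        return cls(**base)

    def to_json(self) -> str:
        d = asdict(self)
        d["augment"] = asdict(self.augment)
        d["augment"]["scale_range"] = list(d["augment"]["scale_range"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainConfig":
        d = json.loads(text)
        aug = d.pop("augment")
        aug["scale_range"] = tuple(aug["scale_range"])
        return cls(augment=AugmentParams(**aug), **d)


def _tiny_backbone(channels: int, rng) -> tuple[nn.Sequential, int]:
    """4-block small CNN: 224 -> 7 spatial, ``channels`` final maps."""
    c = channels
    net = nn.Sequential(
        nn.AvgPool2d(2),  # 224 -> 112, parameter-free
        nn.Conv2d(3, 16, 5, stride=2, pad=2, rng=rng, input_grad=False), nn.BatchNorm2d(16), nn.ReLU(),  # 56
        nn.Conv2d(16, 32, 3, stride=2, pad=1, rng=rng), nn.BatchNorm2d(32), nn.ReLU(),  # 28
        nn.Conv2d(32, 48, 3, stride=2, pad=1, rng=rng), nn.BatchNorm2d(48), nn.ReLU(),  # 14
        nn.Conv2d(48, c, 3, stride=2, pad=1, rng=rng), nn.BatchNorm2d(c), nn.ReLU(),  # 7
    )
    return net, c


def _inception_block(in_ch: int, c1: int, r3: int, c3: int, r5: int, c5: int, rng) -> nn.Concat:
    """Parallel 1x1 / 1x1->3x3 / 1x1->5x5 branches, channel-concatenated."""
    return nn.Concat(
        nn.Sequential(nn.Conv2d(in_ch, c1, 1, rng=rng), nn.BatchNorm2d(c1), nn.ReLU()),
        nn.Sequential(
            nn.Conv2d(in_ch, r3, 1, rng=rng), nn.BatchNorm2d(r3), nn.ReLU(),
            nn.Conv2d(r3, c3, 3, pad=1, rng=rng), nn.BatchNorm2d(c3), nn.ReLU(),
        ),
        nn.Sequential(
            nn.Conv2d(in_ch, r5, 1, rng=rng), nn.BatchNorm2d(r5), nn.ReLU(),
            nn.Conv2d(r5, c5, 5, pad=2, rng=rng), nn.BatchNorm2d(c5), nn.ReLU(),
        ),
    )


def _inception_backbone(rng) -> tuple[nn.Sequential, int]:
    """Compact inception-style backbone ending at 1024 channels, 7x7 spatial.

    No auxiliary classifiers (single-stage training); average pooling is
    used between stages.
    """
    net = nn.Sequential(
        nn.Conv2d(3, 32, 7, stride=4, pad=3, rng=rng, input_grad=False), nn.BatchNorm2d(32), nn.ReLU(),  # 56
        nn.AvgPool2d(2),  # 28
        _inception_block(32, 32, 24, 48, 8, 16, rng),  # 96
        nn.AvgPool2d(2),  # 14
        _inception_block(96, 96, 64, 128, 24, 32, rng),  # 256
        nn.AvgPool2d(2),  # 7
        _inception_block(256, 384, 192, 512, 48, 128, rng),  # 1024
    )
    return net, 1024


def _iter_layers(layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    elif isinstance(layer, nn.Concat):
        for b in layer.branches:
            yield from _iter_layers(b)


class FeatureExtractor:
    """Backbone + GeM + embedding head (+ ArcFace head for training)."""

    def __init__(self, config: TrainConfig, rng: Optional[np.random.Generator] = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        if config.backbone == "tiny":
            self.backbone, self.feature_channels = _tiny_backbone(config.tiny_channels, rng)
        else:
            self.backbone, self.feature_channels = _inception_backbone(rng)
        self.fc = nn.Linear(self.feature_channels, config.embedding_dim, rng=rng)
        self.bn = nn.BatchNorm1d(config.embedding_dim)
        self.prelu = nn.PReLU()
        self.gem = nn.GeMPool(p=config.gem_p)
        self.arcface = nn.ArcFaceHead(
            nn.ArcFaceParams(
                n_classes=config.n_classes,
                dim=config.embedding_dim,
                scale=config.arcface_scale,
                margin_deg=config.arcface_margin_deg,
                seed=config.seed + 1,
            )
        )

    # ---- structure ----
    def params(self) -> list[nn.Param]:
        return (
            self.backbone.params()
            + self.fc.params()
            + self.bn.params()
            + self.prelu.params()
            + self.arcface.params()
        )

    def _bn_layers(self):
        out = [l for l in _iter_layers(self.backbone) if isinstance(l, nn._BatchNorm)]
        out.append(self.bn)
        return out

    # ---- forward paths ----
    def feature_map(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Final convolutional activations, shape (N, K, H, W), post-ReLU."""
        return self.backbone.forward(np.asarray(x, dtype=np.float32), train=train)

    def embed(self, pooled: np.ndarray, train: bool = False) -> np.ndarray:
        """Embedding head FC → BatchNorm → PReLU over pooled K-vectors."""
        z = self.fc.forward(pooled, train=train)
        z = self.bn.forward(z, train=train)
        return self.prelu.forward(z, train=train)

    def forward_embedding(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fmap = self.feature_map(x, train=train)
        pooled = self.gem.forward(fmap, train=train)
        return self.embed(pooled, train=train)

    def extract(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference: L2-normalized embeddings for a batch of model inputs."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        outs = []
        for start in range(0, x.shape[0], batch_size):
            emb = self.forward_embedding(x[start : start + batch_size], train=False)
            outs.append(nn.l2_normalize(emb, axis=1))
        return np.concatenate(outs, axis=0).astype(np.float32)

    # ---- training ----
    def train_step(self, xb: np.ndarray, yb: np.ndarray, opt: nn.SGD) -> float:
        opt.zero_grad()
        fmap = self.backbone.forward(xb, train=True)
        pooled = self.gem.forward(fmap, train=True)
        emb = self.embed(pooled, train=True)
        loss, _ = self.arcface.loss(emb, yb, train=True)
        g = self.arcface.backward()
        g = self.prelu.backward(g)
        g = self.bn.backward(g)
        g = self.fc.backward(g)
        g = self.gem.backward(g)
        self.backbone.backward(g)
        opt.step()
        self.arcface.renormalize()
        return loss

    # ---- serialization ----
    def save(self, path: str | Path) -> Path:
        """Write a versioned checkpoint (weights + running stats + config echo)."""
        path = Path(path)
        arrs = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, l in enumerate(self._bn_layers()):
            arrs[f"bn_mean_{i}"] = l.running_mean
            arrs[f"bn_var_{i}"] = l.running_var
        meta = json.dumps({"version": CHECKPOINT_VERSION, "config": self.config.to_json()})
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrs)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureExtractor":
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            model = cls(TrainConfig.from_json(meta["config"]))
            for i, p in enumerate(model.params()):
                val = z[f"param_{i}"]
                if val.shape != p.value.shape:
                    raise ValueError("checkpoint does not match the configured architecture")
                p.value = val.copy()
                p.grad = np.zeros_like(p.value)
                p.velocity = np.zeros_like(p.value)
            for i, l in enumerate(model._bn_layers()):
                l.running_mean = z[f"bn_mean_{i}"].copy()
                l.running_var = z[f"bn_var_{i}"].copy()
        return model


def train_model(
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    log_every: int = 0,
) -> tuple[FeatureExtractor, np.ndarray]:
    """Train a feature extractor on preprocessed training images.

    ``images``: (N, 224, 224) float32 in [0, 1] — the single grayscale plane
    of each model input (the 3 identical channels are stacked per batch).
    ``labels``: integer class ids in [0, n_classes).  Returns the trained
    model and the per-iteration loss trace.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    n = images.shape[0]
    if images.ndim != 3 or images.shape[1:] != (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE):
        raise ValueError(f"images must be (N, {MODEL_INPUT_SIZE}, {MODEL_INPUT_SIZE})")
    present = set(np.unique(labels).tolist())
    missing = sorted(set(range(config.n_classes)) - present)
    if missing:
        raise ValueError(f"training split has no examples for class id(s) {missing}")

    rng = np.random.default_rng(config.seed)
    model = FeatureExtractor(config, rng=np.random.default_rng(config.seed + 17))
    opt = nn.SGD(model.params(), lr=config.lr, momentum=config.momentum, weight_decay=config.weight_decay)

    # class-balanced sampling draws each batch uniformly over classes, so
    # minority classes are not starved by the larger lesion-free pool
    by_class = [np.flatnonzero(labels == c) for c in range(config.n_classes)]

    b = config.batch_size
    losses = np.empty(config.iterations, dtype=np.float64)
    xb = np.empty((b, 3, MODEL_INPUT_SIZE, MODEL_INPUT_SIZE), dtype=np.float32)
    warm = min(config.warmup_iterations, config.iterations // 2)
    for it in range(config.iterations):
        if it < warm:
            opt.lr = config.lr * (it + 1) / warm
        elif config.lr_schedule == "cosine":
            opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * (it - warm) / max(config.iterations - warm, 1)))
        else:
            opt.lr = config.lr
        if config.sampling == "balanced":
            cls = rng.integers(0, config.n_classes, size=b)
            idx = np.array([by_class[c][rng.integers(0, by_class[c].size)] for c in cls])
        else:
            idx = rng.integers(0, n, size=b)
        for j, i in enumerate(idx):
            x3 = np.repeat(images[i][None], 3, axis=0)
            xb[j] = augment(x3, config.augment, rng, split="train")
        losses[it] = model.train_step(xb, labels[idx], opt)
        if log_every and (it + 1) % log_every == 0:
            window = losses[max(0, it - log_every + 1) : it + 1]
            print(f"iter {it + 1}/{config.iterations}  loss {window.mean():.4f}", flush=True)
    return model, losses


def extract_features(
    model: FeatureExtractor,
    images: np.ndarray,
    uids: Optional[list[UIDTriple]] = None,
    labels_text: Optional[list[str]] = None,
    batch_size: int = 64,
) -> list[FeatureVector]:
    """Embed preprocessed (N, 224, 224) images into UID-keyed feature vectors."""
    images = np.asarray(images, dtype=np.float32)
    n = images.shape[0]
    vecs = []
    for start in range(0, n, batch_size):
        chunk = images[start : start + batch_size]
        x = np.repeat(chunk[:, None], 3, axis=1)
        vecs.append(model.extract(x, batch_size=batch_size))
    emb = np.concatenate(vecs, axis=0)
    out = []
    for i in range(n):
        out.append(
            FeatureVector(
                values=emb[i],
                uids=uids[i] if uids else None,
                label=labels_text[i] if labels_text else None,
            )
        )
    return out


def extract_feature(model: FeatureExtractor, model_input: np.ndarray, uids: Optional[UIDTriple] = None,
                    label: Optional[str] = None) -> FeatureVector:
    """Embed one (3, 224, 224) model input into a unit-norm feature vector."""
    emb = model.extract(model_input)
    return FeatureVector(values=emb[0], uids=uids, label=label)
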