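"""3D UNet++ for voxel-level pericardium segmentation.

A nested encoder–decoder: encoder column nodes X(i,0) with 2× max-pool
downsampling between levels, and nested decoder nodes X(i,j) (j ≥ 1) that
concatenate all same-level predecessors X(i,0..j−1) with a
transposed-convolution upsampling of X(i+1,j−1) — the dense skip pathways
that distinguish UNet++ from a plain UNet. Every node is a block of two
(3³ conv → instance norm → LeakyReLU) stages. A single 1×1×1 head with
per-class sigmoid sits on the last top-level node X(0, L−1); deep
supervision is not used.

The training recipe follows the reference setup: per-voxel binary
cross-entropy summed over independent class channels (background /
pericardium / redundant — the channels are disjoint by construction, so
the multi-label formulation is consistent), RMSProp at a fixed learning
rate of 1e-4, no scheduler, mini-batch size 1, random weight init.

The reference clinical configuration is five levels with encoder channels
[32, 32, 64, 128, 256] on 128³ cubes; a reduced configuration (e.g. four
levels, [4, 8, 16, 32], 64³ cubes) trains in minutes on one CPU.
Everything here runs on numpy; determinism is machine-local (fixed seed,
fixed inputs, single BLAS backend → bitwise-reproducible traces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _nn
from .ct_io import CTVolume, SegmentationMask
from .preprocess import PreprocessConfig, apply_pipeline, invert_to_native

__all__ = [
    "UNetPPConfig",
    "TrainConfig",
    "UNetPP",
    "build_model",
    "train",
    "predict_pericardium",
    "save_model",
    "load_model",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class UNetPPConfig:
    """Architecture hyper-parameters.

    ``encoder_channels[i]`` is the channel width of every node at level i;
    the transposed convolution feeding level i outputs
    ``encoder_channels[i]`` channels, so the final upsampling feature size
    equals ``encoder_channels[0]`` (32 in the reference configuration).
    """

    levels: int = 5
    encoder_channels: tuple[int, ...] = (32, 32, 64, 128, 256)
    negative_slope: float = 0.1
    out_classes: int = 3
    cube_size: int = 128
    foreground_prior: float | None = None

    def __post_init__(self) -> None:
        if self.foreground_prior is not None and not (0.0 < self.foreground_prior < 1.0):
            raise ValueError("foreground_prior must lie in (0, 1)")
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        if len(self.encoder_channels) != self.levels:
            raise ValueError(
                f"encoder_channels has {len(self.encoder_channels)} entries "
                f"for {self.levels} levels"
            )
        if any(c < 1 for c in self.encoder_channels):
            raise ValueError("all channel counts must be >= 1")
        if self.cube_size % (2 ** (self.levels - 1)) != 0:
            raise ValueError(
                f"cube_size {self.cube_size} must be divisible by "
                f"2^(levels-1) = {2 ** (self.levels - 1)}"
            )

    @property
    def final_up_channels(self) -> int:
        return self.encoder_channels[0]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    """Optimisation recipe (clinical-scale reference defaults)."""

    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 25
    seed: int = 0
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only mini-batch size 1 is supported")

    def to_dict(self) -> dict:
        return asdict(self)


class _ConvBlock:
    """Two (conv3 → instance norm → LeakyReLU) stages."""

    def __init__(self, cin, cout, rng, slope):
        self.layers = [
            _nn.Conv3d(cin, cout, rng),
            _nn.InstanceNorm(cout),
            _nn.LeakyReLU(slope),
            _nn.Conv3d(cout, cout, rng),
            _nn.InstanceNorm(cout),
            _nn.LeakyReLU(slope),
        ]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNetPP:
    """Nested encoder–decoder segmentation network (see module docstring)."""

    def __init__(self, cfg: UNetPPConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        L = cfg.levels
        ch = cfg.encoder_channels
        slope = cfg.negative_slope

        self.blocks: dict[tuple[int, int], _ConvBlock] = {}
        self.pools: dict[int, _nn.MaxPool2x] = {}
        self.ups: dict[tuple[int, int], _nn.ConvTranspose2x] = {}

        for i in range(L):
            cin = 1 if i == 0 else ch[i - 1]
            self.blocks[(i, 0)] = _ConvBlock(cin, ch[i], rng, slope)
            if i > 0:
                self.pools[i] = _nn.MaxPool2x()
        for j in range(1, L):
            for i in range(L - j):
                self.ups[(i, j)] = _nn.ConvTranspose2x(ch[i + 1], ch[i], rng)
                self.blocks[(i, j)] = _ConvBlock(ch[i] * (j + 1), ch[i], rng, slope)
        self.head = _nn.Conv1x1(ch[0], cfg.out_classes, rng)
        if cfg.foreground_prior is not None:
            # class-prior logit init of the head biases: the foreground
            # channels start near their prevalence instead of 0.5, so the
            # optimiser spends its budget on boundary discrimination rather
            # than on learning class frequencies (useful in the short-budget
            # small-dataset regime; weights remain randomly initialised)
            import math as _math

            logit = _math.log(cfg.foreground_prior / (1.0 - cfg.foreground_prior))
            self.head.b.value[:] = np.float32(logit)
            self.head.b.value[0] = np.float32(-logit)  # background channel

        self._order: list[tuple[int, int]] = [(i, 0) for i in range(L)] + [
            (i, j) for j in range(1, L) for i in range(L - j)
        ]
        self._acts: dict[tuple[int, int], np.ndarray] | None = None

    @property
    def params(self):
        out = []
        for key in self._order:
            out.extend(self.blocks[key].params)
        for key in sorted(self.ups):
            out.extend(self.ups[key].params)
        out.extend(self.head.params)
        return out

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, D, H, W) in [0, 1] → logits (out_classes, D, H, W)."""
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected input of shape (1, D, H, W), got {x.shape}")
        if any(s % (2 ** (self.cfg.levels - 1)) for s in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} not divisible by "
                f"2^(levels-1) = {2 ** (self.cfg.levels - 1)}"
            )
        L = self.cfg.levels
        x = np.asarray(x)
        if x.dtype != np.float64:  # float64 kept for numerical verification
            x = x.astype(np.float32)
        acts: dict[tuple[int, int], np.ndarray] = {}
        acts[(0, 0)] = self.blocks[(0, 0)].forward(x)
        for i in range(1, L):
            acts[(i, 0)] = self.blocks[(i, 0)].forward(
                self.pools[i].forward(acts[(i - 1, 0)])
            )
        for j in range(1, L):
            for i in range(L - j):
                up = self.ups[(i, j)].forward(acts[(i + 1, j - 1)])
                cat = np.concatenate([acts[(i, jj)] for jj in range(j)] + [up], axis=0)
                acts[(i, j)] = self.blocks[(i, j)].forward(cat)
        self._acts = acts
        return self.head.forward(acts[(0, L - 1)])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid class probabilities; drops cached activations."""
        logits = self.forward(x)
        self._acts = None
        return _nn.sigmoid(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate; accumulates parameter gradients."""
        if self._acts is None:
            raise RuntimeError("backward called before forward")
        L = self.cfg.levels
        ch = self.cfg.encoder_channels
        grads: dict[tuple[int, int], np.ndarray] = {
            key: np.zeros_like(a) for key, a in self._acts.items()
        }
        grads[(0, L - 1)] += self.head.backward(dlogits)
        for key in reversed(self._order):
            i, j = key
            dy = grads.pop(key)
            dx = self.blocks[key].backward(dy)
            if j == 0:
                if i > 0:
                    grads[(i - 1, 0)] += self.pools[i].backward(dx)
            else:
                splits = np.split(dx, np.cumsum([ch[i]] * j), axis=0)
                for jj in range(j):
                    grads[(i, jj)] += splits[jj]
                grads[(i + 1, j - 1)] += self.ups[(i, j)].backward(splits[j])
        self._acts = None


def build_model(cfg: UNetPPConfig | None = None, seed: int = 0) -> UNetPP:
    """Construct a randomly initialised network (deterministic per seed)."""
    return UNetPP(cfg or UNetPPConfig(), seed=seed)


def _as_image_array(sample) -> np.ndarray:
    data = getattr(sample, "data", sample)
    return np.asarray(data, dtype=np.float32)[None]


def _as_target(label, out_classes: int) -> np.ndarray:
    data = np.asarray(getattr(label, "data", label))
    target = np.zeros((out_classes,) + data.shape, dtype=np.float32)
    for c in range(out_classes):
        target[c] = data == c
    return target


def train(
    model: UNetPP,
    samples: list[tuple],
    cfg: TrainConfig | None = None,
    callback=None,
) -> tuple[UNetPP, list[float]]:
    """Optimise on (image cube, label cube) pairs; returns the loss trace.

    The label cube over {0,1,2} is expanded to per-class binary channels
    for the summed binary cross-entropy target. Sample order is reshuffled
    every epoch from the config seed, so a fixed seed gives a reproducible
    trace on one machine. Raises :class:`DivergenceError` on a non-finite
    loss, naming the epoch.
    """
    cfg = cfg or TrainConfig()
    if not samples:
        raise ValueError("need at least one training sample")
    pairs = [
        (_as_image_array(img), _as_target(lab, model.cfg.out_classes))
        for img, lab in samples
    ]
    opt = _nn.RMSProp(
        model.params, lr=cfg.learning_rate, alpha=cfg.rmsprop_alpha, eps=cfg.rmsprop_eps
    )
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        total = 0.0
        for idx in order:
            x, target = pairs[idx]
            logits = model.forward(x)
            loss, dz = _nn.bce_with_logits(logits, target)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            total += loss
        trace.append(total / len(pairs))
        if callback is not None:
            callback(epoch, trace[-1])
    return model, trace


def predict_pericardium(
    model: UNetPP,
    vol: CTVolume,
    cfg: PreprocessConfig | None = None,
    postprocess: str = "none",
    threshold: float = 0.5,
) -> SegmentationMask:
    """Segment the pericardium of a native-grid volume.

    Preprocess (image only) → forward → pericardium-channel probability ≥
    threshold → optional largest 26-connected component → map back to the
    native grid. The redundant channel is discarded at inference.
    """
    if postprocess not in ("none", "largest_component"):
        raise ValueError(f"unknown postprocess {postprocess!r}")
    cfg = cfg or PreprocessConfig()
    if cfg.cube_size != model.cfg.cube_size:
        raise ValueError(
            f"preprocess cube_size {cfg.cube_size} != model cube_size "
            f"{model.cfg.cube_size}"
        )
    img_cube, _, t = apply_pipeline(vol, None, cfg)
    proba = model.predict_proba(img_cube.data[None])
    mask = (proba[1] >= threshold).astype(np.uint8)
    if postprocess == "largest_component" and mask.any():
        from scipy import ndimage

        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    cube_mask = SegmentationMask(mask, img_cube.spacing, img_cube.origin, img_cube.axcodes)
    return invert_to_native(cube_mask, t, vol)


def save_model(model: UNetPP, path) -> None:
    """Single-file checkpoint: config JSON + parameter arrays."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    meta = json.dumps({"config": model.cfg.to_dict(), "seed": model.seed})
    np.savez_compressed(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> UNetPP:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = UNetPPConfig(**meta["config"])
        model = UNetPP(cfg, seed=meta.get("seed", 0))
        params = model.params
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p.value = arr.astype(np.float32)
    return model
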