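"""Modified U-net semantic segmenter for cardiomyocyte ultrastructure.

The network is a symmetric encoder/decoder with skip connections and a
densely connected bottleneck: four encoder blocks, the bottleneck, and four
decoder blocks — nine blocks in total. Feature channels double with every
encoder block and halve with every decoder block; 2x2 max-pooling (stride 2)
downsamples between blocks and nearest-neighbour 2x upsampling followed by
convolution restores resolution. Activations are ReLU throughout except the
bottleneck, whose densely connected convolutions use trainable linear units
(TLUs), and the output, a SoftMax over the four classes (background,
mitochondria, myofibrils, Z-discs).

Training pairs the SoftMax output with categorical cross-entropy and Adam;
both are configurable. The loss, optimizer and dense-bottleneck depth/growth
are package choices documented in the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .imio import DatasetSplit
from .nn import autograd as ag
from .volumes import IntensityVolume, LabelVolume


class SpecError(ValueError):
    """Raised for inconsistent network specifications."""


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""

    def __init__(self, msg, epoch=None):
        super().__init__(msg)
        self.epoch = epoch


def softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exponential normalization of activations into class probabilities,
    stabilized by max-subtraction (invariant to adding a constant)."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise FloatingPointError("softmax received non-finite activations")
    shifted = a - a.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities ``p[n, ...]`` (class axis first) and,
    optionally, the raw activations they were normalized from."""

    probabilities: np.ndarray
    activations: np.ndarray | None = None

    def __post_init__(self):
        s = self.probabilities.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-6):
            raise ValueError("class probabilities must sum to 1 at every pixel")

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[0]

    def argmax_labels(self) -> np.ndarray:
        return self.probabilities.argmax(axis=0).astype(np.uint8)


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyper-parameters.

    Defaults mirror the full-scale network (512x512 input, 64 base channels,
    nine blocks); ``input_size`` and ``base_channels`` scale down for CPU
    experiments without changing the topology.
    """

    input_size: int = 512
    base_channels: int = 64
    n_encoder_blocks: int = 4
    n_decoder_blocks: int = 4
    n_classes: int = 4
    dense_layers: int = 4
    dense_growth: int | None = None  # default: base_channels
    upsample: str = "nearest_conv"

    @property
    def n_blocks(self) -> int:
        return self.n_encoder_blocks + self.n_decoder_blocks + 1

    def validate(self) -> None:
        if self.input_size % (2**self.n_encoder_blocks) != 0:
            raise SpecError(
                f"input_size {self.input_size} not divisible by 2^{self.n_encoder_blocks}"
            )
        if self.n_encoder_blocks != self.n_decoder_blocks:
            raise SpecError("encoder and decoder must have the same number of blocks")
        if self.base_channels < 1 or self.n_classes < 2:
            raise SpecError("need at least 1 base channel and 2 classes")


@dataclass
class BlockInfo:
    kind: str  # encoder | bottleneck | decoder
    in_channels: int
    out_channels: int
    spatial: int


class _EncoderBlock(nn.Module):
    def __init__(self, c_in, c_out, rng):
        self.conv1 = nn.Conv2d(c_in, c_out, rng=rng)
        self.conv2 = nn.Conv2d(c_out, c_out, rng=rng)

    def __call__(self, x):
        x = ag.relu(self.conv1(x))
        return ag.relu(self.conv2(x))


class _DenseBottleneck(nn.Module):
    """Densely connected convolutions with TLU activations: every layer sees
    the concatenation of the block input and all previous layer outputs."""

    def __init__(self, c_in, c_out, n_layers, growth, rng):
        self.layers = []
        self.acts = []
        c = c_in
        for _ in range(n_layers):
            self.layers.append(nn.Conv2d(c, growth, rng=rng))
            self.acts.append(nn.TLU(growth))
            c += growth
        self.project = nn.Conv2d(c, c_out, k=1, rng=rng)
        self.project_act = nn.TLU(c_out)

    def __call__(self, x):
        feats = [x]
        for conv, act in zip(self.layers, self.acts):
            inp = feats[0] if len(feats) == 1 else ag.concat(feats, axis=1)
            feats.append(act(conv(inp)))
        return self.project_act(self.project(ag.concat(feats, axis=1)))


class _DecoderBlock(nn.Module):
    def __init__(self, c_in, c_skip, c_out, rng, upsample="nearest_conv"):
        self.upsample = upsample
        self.up_conv = nn.Conv2d(c_in, c_out, rng=rng)
        self.conv1 = nn.Conv2d(c_out + c_skip, c_out, rng=rng)
        self.conv2 = nn.Conv2d(c_out, c_out, rng=rng)

    def __call__(self, x, skip):
        x = ag.relu(self.up_conv(ag.upsample2d(x)))
        x = ag.concat([x, skip], axis=1)
        x = ag.relu(self.conv1(x))
        return ag.relu(self.conv2(x))


class UNet(nn.Module):
    """The nine-block U-net; ``blocks`` exposes the topology for introspection."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        b = spec.base_channels
        growth = spec.dense_growth or b
        self.encoders = []
        self.blocks: list[BlockInfo] = []
        c_in, size = 1, spec.input_size
        enc_out = []
        for i in range(spec.n_encoder_blocks):
            c_out = b * 2**i
            self.encoders.append(_EncoderBlock(c_in, c_out, rng))
            self.blocks.append(BlockInfo("encoder", c_in, c_out, size))
            enc_out.append(c_out)
            c_in, size = c_out, size // 2
        c_bottle = b * 2**spec.n_encoder_blocks
        self.bottleneck = _DenseBottleneck(c_in, c_bottle, spec.dense_layers, growth, rng)
        self.blocks.append(BlockInfo("bottleneck", c_in, c_bottle, size))
        self.decoders = []
        c_in = c_bottle
        for i in range(spec.n_decoder_blocks):
            c_out = b * 2 ** (spec.n_decoder_blocks - 1 - i)
            skip = enc_out[-(i + 1)]
            size *= 2
            self.decoders.append(_DecoderBlock(c_in, skip, c_out, rng, spec.upsample))
            self.blocks.append(BlockInfo("decoder", c_in, c_out, size))
            c_in = c_out
        self.head = nn.Conv2d(c_in, spec.n_classes, k=1, rng=rng)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def output_channels(self) -> int:
        return self.head.c_out

    def forward(self, x) -> ag.Tensor:
        """Logits for a (B, 1, H, W) batch."""
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = ag.maxpool2d(x)
        x = self.bottleneck(x)
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(x, skip)
        return self.head(x)

    __call__ = forward

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities (B, N, H, W) for a (B, H, W) image batch."""
        logits = self.forward(np.asarray(images, dtype=np.float32)[:, None]).data
        return softmax(logits, axis=1)


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Construct the modified U-net from a spec (default: full-scale spec)."""
    return UNet(spec or UNetSpec(), seed=seed)


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "categorical_cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 4
    seed: int = 0
    patience: int | None = None  # early stop on validation loss
    class_weights: tuple | None = None

    def validate(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.loss != "categorical_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer not in {"adam", "sgd"}:
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict
    best_epoch: int


def _epoch_loss(network, images, labels, idx, batch_size, cw) -> float:
    total, n = 0.0, 0
    for s in range(0, len(idx), batch_size):
        b = idx[s : s + batch_size]
        logits = network.forward(images[b][:, None])
        loss = ag.softmax_cross_entropy(logits, labels[b], class_weights=cw)
        total += float(loss.data) * len(b)
        n += len(b)
    return total / max(n, 1)


def train(
    network: UNet,
    images: np.ndarray,
    labels: np.ndarray,
    split: DatasetSplit,
    cfg: TrainConfig,
) -> TrainResult:
    """Train on the patches indexed by ``split.train``, monitoring loss on
    ``split.val``; returns the checkpoint with the best validation loss.

    Reproducible for a fixed seed on one device: the per-epoch example order
    and all parameter updates are driven by a single seeded generator.
    """
    cfg.validate()
    if not split.train:
        raise ValueError("empty training split")
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    train_idx = np.asarray(split.train, dtype=int)
    val_idx = np.asarray(split.val, dtype=int) if split.val else train_idx
    cw = np.asarray(cfg.class_weights, dtype=np.float32) if cfg.class_weights else None
    opt_cls = nn.Adam if cfg.optimizer == "adam" else nn.SGD
    opt = opt_cls(network.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    rows = []
    best_state, best_val, best_epoch = network.copy_state(), np.inf, -1
    stale = 0
    for epoch in range(cfg.epochs):
        order = train_idx[rng.permutation(len(train_idx))]
        total, n = 0.0, 0
        for s in range(0, len(order), cfg.batch_size):
            b = order[s : s + cfg.batch_size]
            opt.zero_grad()
            logits = network.forward(images[b][:, None])
            loss = ag.softmax_cross_entropy(logits, labels[b], class_weights=cw)
            if not np.isfinite(loss.data):
                raise TrainingError(f"loss diverged at epoch {epoch}", epoch=epoch)
            loss.backward()
            opt.step()
            total += float(loss.data) * len(b)
            n += len(b)
        val_loss = _epoch_loss(network, images, labels, val_idx, cfg.batch_size, cw)
        rows.append({"epoch": epoch, "train_loss": total / n, "val_loss": val_loss})
        if val_loss < best_val:
            best_val, best_epoch, best_state = val_loss, epoch, network.copy_state()
            stale = 0
        else:
            stale += 1
            if cfg.patience is not None and stale > cfg.patience:
                break
    return TrainResult(pd.DataFrame(rows), best_state, best_epoch)


def predict(
    network: UNet,
    volume: IntensityVolume,
    tile: int | None = None,
    overlap: int | None = None,
    pad_policy: str | None = "reflect",
) -> tuple[LabelVolume, ProbabilityMap]:
    """Segment a volume slice by slice with overlap-averaged tiling.

    Probabilities of overlapping tiles are averaged before the per-pixel
    argmax, so tile seams never show in the label map.
    """
    tile = tile or network.spec.input_size
    overlap = tile // 2 if overlap is None else overlap
    if overlap >= tile:
        raise ValueError("overlap must be smaller than the tile size")
    nz, ny, nx = volume.data.shape
    if (ny < tile or nx < tile) and pad_policy is None:
        raise ValueError(
            f"volume slices ({ny}, {nx}) smaller than tile {tile} and no padding policy"
        )
    py, px = max(0, tile - ny), max(0, tile - nx)
    data = volume.data.astype(np.float32)
    if py or px:
        data = np.pad(data, ((0, 0), (0, py), (0, px)), mode=pad_policy)
    _, Y, X = data.shape
    stride = tile - overlap
    ys = sorted({min(y, Y - tile) for y in range(0, Y - tile + stride, stride)})
    xs = sorted({min(x, X - tile) for x in range(0, X - tile + stride, stride)})
    n_cls = network.spec.n_classes
    probs = np.zeros((n_cls, nz, Y, X), dtype=np.float64)
    counts = np.zeros((Y, X), dtype=np.float64)
    first = True
    for y in ys:
        for x in xs:
            batch = data[:, y : y + tile, x : x + tile]
            p = network.predict_proba(batch)  # (nz, n_cls, tile, tile)
            probs[:, :, y : y + tile, x : x + tile] += p.transpose(1, 0, 2, 3)
            counts[y : y + tile, x : x + tile] += 1.0
            first = False
    assert not first
    probs /= counts[None, None]
    probs = probs[:, :, :ny, :nx]
    pmap = ProbabilityMap(probs)
    return LabelVolume(pmap.argmax_labels(), volume.voxel_size_um), pmap
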