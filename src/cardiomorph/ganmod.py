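"""Conditional style-based generative model of segmented cardiomyocyte slices.

A desk-scale style-based GAN with the workflow's three distinctive traits:

* synthesis starts from a learned constant base tensor (no latent input
  layer) with per-convolution noise injection, and a two-stage latent — a
  mapping network turns the latent ``z`` into a style vector ``w`` that
  modulates every synthesis block;
* a one-hot *slice-pair* label enters the generator (and a projection in the
  discriminator) through an embedding, so the model can condition on the
  position of consecutive-slice pairs in the source stack; records are
  consumed in stack order, without shuffling;
* convergence is monitored with the Fréchet distance (FID) between feature
  summaries of generated and training slices, and the reported checkpoint is
  the FID minimizer.

The feature extractor behind the FID is pluggable; the default is a
deterministic average-pool pixel embedding so that the distance itself — the
Gaussian-moment formula — is exact and testable on a CPU. Generator output
is a 4-channel class-probability slice, decoded to labels by argmax.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from . import nn
from .assembly import assemble_volume, order_slices
from .imio import SlicePairRecord
from .morpho import label_components, shape_stats
from .nn import autograd as ag
from .nn.autograd import Tensor
from .volumes import N_CLASSES, LabelVolume, SliceStack


# ---------------------------------------------------------------------------
# FID


@dataclass
class FIDResult:
    value: float
    extractor: str
    n_a: int
    n_b: int
    mu_a: np.ndarray
    mu_b: np.ndarray
    sigma_a: np.ndarray
    sigma_b: np.ndarray

    def __float__(self):
        return self.value


def fid(
    features_a: np.ndarray,
    features_b: np.ndarray,
    covariance: str = "population",
    extractor: str = "unknown",
    eps: float = 1e-10,
) -> FIDResult:
    """Fréchet distance between Gaussians fitted to two feature sets.

    ``||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})`` with a stabilized
    matrix square root; tiny negative eigenvalues are clamped at zero.
    Covariances use the population convention (divide by n) by default.
    """
    fa = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    fb = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if fa.shape[1] != fb.shape[1]:
        raise ValueError(f"feature dimension mismatch: {fa.shape[1]} vs {fb.shape[1]}")
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors per set")
    ddof = 0 if covariance == "population" else 1
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    sa = np.cov(fa.T, ddof=ddof)
    sb = np.cov(fb.T, ddof=ddof)
    sa, sb = np.atleast_2d(sa), np.atleast_2d(sb)
    diff = mu_a - mu_b
    prod = sa @ sb
    with warnings.catch_warnings():
        # rank-deficient covariances are routine for small sets; we only
        # escalate when the square root actually fails
        warnings.simplefilter("ignore")
        covmean = np.asarray(linalg.sqrtm(prod))
    if not np.isfinite(covmean).all():
        warnings.warn(
            "singular covariance product; applying epsilon regularization", stacklevel=2
        )
        off = eps * np.eye(sa.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            covmean = np.asarray(linalg.sqrtm((sa + off) @ (sb + off)))
    covmean = np.real(covmean)
    value = float(diff @ diff + np.trace(sa) + np.trace(sb) - 2.0 * np.trace(covmean))
    value = max(value, 0.0)
    return FIDResult(value, extractor, fa.shape[0], fb.shape[0], mu_a, mu_b, sa, sb)


def feature_extractor(
    images, extractor: str = "downsample_pixels", pool_to: int = 8
) -> np.ndarray:
    """Map a set of 2D images to feature vectors.

    ``downsample_pixels`` average-pools each image to ``pool_to`` squared and
    flattens — a deterministic stand-in embedding; any callable
    ``images -> (n, d)`` may be passed instead to slot in a pretrained
    feature network at full scale.
    """
    if callable(extractor):
        return np.asarray(extractor(images))
    if extractor != "downsample_pixels":
        raise ValueError(f"unknown extractor {extractor!r}")
    imgs = np.asarray(images, dtype=np.float64)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.shape[0] == 0:
        raise ValueError("empty image set")
    n, h, w = imgs.shape
    fh, fw = h // pool_to, w // pool_to
    if fh < 1 or fw < 1:
        raise ValueError(f"images {h}x{w} smaller than pool grid {pool_to}")
    imgs = imgs[:, : fh * pool_to, : fw * pool_to]
    pooled = imgs.reshape(n, pool_to, fh, pool_to, fw).mean(axis=(2, 4))
    return pooled.reshape(n, pool_to * pool_to)


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class GANConfig:
    """Desk-scale defaults: 32x32 slices, 64-d latent, 2-layer mapping."""

    resolution: int = 32
    latent_dim: int = 64
    mapping_depth: int = 2
    n_pair_labels: int = 8
    embedding_dim: int = 16
    base_channels: int = 64
    noise_injection: bool = True
    iterations: int = 200
    batch_size: int = 4
    lr_g: float = 2e-3
    lr_d: float = 2e-3
    seed: int = 0
    shuffle: bool = False  # records are consumed in stack order
    fid_interval: int = 20
    fid_pool: int = 8
    fid_samples: int = 64
    covariance: str = "population"
    n_classes: int = N_CLASSES

    def validate(self):
        r = self.resolution
        if r < 8 or (r & (r - 1)) != 0:
            raise ValueError(f"resolution must be a power of two >= 8, got {r}")
        if self.n_pair_labels < 1:
            raise ValueError("conditioning requires n_pair_labels >= 1")
        if self.batch_size < 1 or self.iterations < 1:
            raise ValueError("iterations and batch size must be positive")


def _softmax_channels(logits):
    m = Tensor(logits.data.max(axis=1, keepdims=True))
    e = ag.exp(ag.sub(logits, m))
    return ag.mul(e, ag.pow_const(ag.tsum(e, axis=1, keepdims=True), -1.0))


class Generator(nn.Module):
    """Style-based synthesis from a learned constant tensor."""

    BASE = 4  # spatial size of the learned constant

    def __init__(self, cfg: GANConfig, rng):
        self.cfg = cfg
        n_up = int(np.log2(cfg.resolution // self.BASE))
        c0 = cfg.base_channels
        self.embed = nn.Dense(cfg.n_pair_labels, cfg.embedding_dim, rng=rng)
        self.mapping = [
            nn.Dense(
                cfg.latent_dim + cfg.embedding_dim if i == 0 else cfg.latent_dim,
                cfg.latent_dim,
                rng=rng,
            )
            for i in range(cfg.mapping_depth)
        ]
        self.const = Tensor(
            rng.normal(0, 1, size=(1, c0, self.BASE, self.BASE)), requires_grad=True, name="const"
        )
        self.convs, self.noise_w, self.style_scale, self.style_shift = [], [], [], []
        c = c0
        self.channel_plan = []
        for i in range(n_up):
            c_out = max(c // 2, 8)
            self.convs.append(nn.Conv2d(c, c_out, rng=rng))
            self.noise_w.append(
                Tensor(np.zeros((1, c_out, 1, 1)), requires_grad=True, name=f"noise_w{i}")
            )
            self.style_scale.append(nn.Dense(cfg.latent_dim, c_out, rng=rng))
            self.style_shift.append(nn.Dense(cfg.latent_dim, c_out, rng=rng))
            self.channel_plan.append((c, c_out))
            c = c_out
        self.head = nn.Conv2d(c, cfg.n_classes, k=1, rng=rng)

    def map_latent(self, z: np.ndarray, one_hot: np.ndarray):
        e = self.embed(Tensor(one_hot.astype(np.float32)))
        w = ag.concat([Tensor(z.astype(np.float32)), e], axis=1)
        for dense in self.mapping:
            w = ag.leaky_relu(dense(w), 0.2)
        return w

    def forward(self, z: np.ndarray, one_hot: np.ndarray, noises=None, rng=None):
        """Class-probability slices (B, n_classes, R, R) for latents ``z`` and
        one-hot pair labels; per-layer noise comes from ``noises`` or ``rng``."""
        B = z.shape[0]
        w = self.map_latent(z, one_hot)
        x = ag.add(self.const, Tensor(np.zeros((B, 1, 1, 1), dtype=np.float32)))
        for i, conv in enumerate(self.convs):
            x = conv(ag.upsample2d(x))
            if self.cfg.noise_injection:
                h = x.data.shape[2]
                if noises is not None:
                    noise = noises[i]
                else:
                    rng = rng or np.random.default_rng(0)
                    noise = rng.normal(0, 1, size=(B, 1, h, h))
                x = ag.add(x, ag.mul(self.noise_w[i], Tensor(noise.astype(np.float32))))
            x = ag.leaky_relu(x, 0.2)
            xn = nn.instance_norm(x)
            c_out = self.channel_plan[i][1]
            scale = ag.reshape(self.style_scale[i](w), (B, c_out, 1, 1))
            shift = ag.reshape(self.style_shift[i](w), (B, c_out, 1, 1))
            x = ag.add(ag.mul(xn, ag.add(scale, 1.0)), shift)
        return _softmax_channels(self.head(x))

    def sample_labels(self, z, one_hot, noises=None, rng=None) -> np.ndarray:
        """Label slices (B, R, R) decoded by per-pixel argmax."""
        probs = self.forward(z, one_hot, noises=noises, rng=rng)
        return probs.data.argmax(axis=1).astype(np.uint8)


class Discriminator(nn.Module):
    """Convolutional critic with projection conditioning on the pair label."""

    def __init__(self, cfg: GANConfig, rng):
        self.cfg = cfg
        n_down = int(np.log2(cfg.resolution // 4))
        c_in, c = cfg.n_classes, 16
        self.convs = []
        for _ in range(n_down):
            self.convs.append(nn.Conv2d(c_in, c, rng=rng))
            c_in, c = c, min(c * 2, 128)
        feat_dim = c_in * 4 * 4
        self.fc = nn.Dense(feat_dim, 64, rng=rng)
        self.out = nn.Dense(64, 1, rng=rng)
        self.embed = nn.Dense(cfg.n_pair_labels, 64, rng=rng)

    def forward(self, x, one_hot: np.ndarray):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        for conv in self.convs:
            x = ag.avgpool2d(ag.leaky_relu(conv(x), 0.2))
        B = x.data.shape[0]
        feat = ag.leaky_relu(self.fc(ag.reshape(x, (B, -1))), 0.2)
        score = self.out(feat)
        proj = ag.tsum(
            ag.mul(feat, self.embed(Tensor(one_hot.astype(np.float32)))), axis=1, keepdims=True
        )
        return ag.add(score, proj)


def build_gan(config: GANConfig | None = None, seed: int = 0):
    """Construct (generator, discriminator) from a config."""
    config = config or GANConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    return Generator(config, rng), Discriminator(config, rng)


# ---------------------------------------------------------------------------
# training


def one_hot_slices(slices: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(B, H, W) integer labels -> (B, n_classes, H, W) one-hot float32."""
    s = np.asarray(slices)
    out = np.zeros((s.shape[0], n_classes) + s.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = s == c
    return out


@dataclass
class GANTrainResult:
    best_state: dict
    best_fid: float
    best_iteration: int
    fid_trace: pd.DataFrame
    final_state: dict


def _eval_fid(gen: Generator, real_slices: np.ndarray, cfg: GANConfig, rng) -> float:
    n = min(cfg.fid_samples, max(2 * len(real_slices), 8))
    z = rng.normal(0, 1, size=(n, cfg.latent_dim))
    labels = np.eye(cfg.n_pair_labels, dtype=np.float32)[np.arange(n) % cfg.n_pair_labels]
    fake = gen.sample_labels(z, labels, rng=rng).astype(np.float64) / (cfg.n_classes - 1)
    real = real_slices.astype(np.float64) / (cfg.n_classes - 1)
    fa = feature_extractor(fake, pool_to=cfg.fid_pool)
    fb = feature_extractor(real, pool_to=cfg.fid_pool)
    return fid(fa, fb, covariance=cfg.covariance, extractor="downsample_pixels").value


def train_gan(
    models: tuple[Generator, Discriminator],
    records: list[SlicePairRecord],
    config: GANConfig,
) -> GANTrainResult:
    """Adversarial training on slice-pair records, in record order.

    Non-saturating logistic losses; the discriminator sees (slice, pair
    label) pairs — real slices one-hot encoded, fake slices as the
    generator's probability output. FID against the training slices is
    evaluated every ``fid_interval`` iterations and the returned checkpoint
    is the generator state at the minimum of the trace.
    """
    config.validate()
    if len(records) < 2:
        raise ValueError("need at least 2 slice-pair records")
    gen, disc = models
    rng = np.random.default_rng(config.seed)
    fid_rng = np.random.default_rng(config.seed + 1)

    n_lab = config.n_pair_labels
    real_slices = np.stack([r.slice_a for r in records])
    real_onehot = one_hot_slices(real_slices, config.n_classes)
    pair_idx = np.array([r.index % n_lab for r in records])
    pair_onehot = np.eye(n_lab, dtype=np.float32)[pair_idx]

    opt_g = nn.Adam(gen.parameters(), lr=config.lr_g, betas=(0.5, 0.999))
    opt_d = nn.Adam(disc.parameters(), lr=config.lr_d, betas=(0.5, 0.999))

    trace = []
    f0 = _eval_fid(gen, real_slices, config, np.random.default_rng(config.seed + 2))
    trace.append({"iteration": 0, "fid": f0})
    best_fid, best_iter, best_state = f0, 0, gen.copy_state()

    order = np.arange(len(records))  # unshuffled: stack order
    cursor = 0
    B = config.batch_size
    for it in range(1, config.iterations + 1):
        idx = order[[(cursor + k) % len(order) for k in range(B)]]
        cursor = (cursor + B) % len(order)
        real_x = real_onehot[idx]
        lab = pair_onehot[idx]

        # discriminator step
        z = rng.normal(0, 1, size=(B, config.latent_dim))
        fake = gen.forward(z, lab, rng=rng)
        fake_const = Tensor(fake.data.copy())
        opt_d.zero_grad()
        d_real = disc.forward(real_x, lab)
        d_fake = disc.forward(fake_const, lab)
        loss_d = ag.tmean(ag.add(ag.softplus(ag.neg(d_real)), ag.softplus(d_fake)))
        if not np.isfinite(loss_d.data):
            raise RuntimeError(f"discriminator loss diverged at iteration {it}")
        loss_d.backward()
        opt_d.step()

        # generator step
        z = rng.normal(0, 1, size=(B, config.latent_dim))
        opt_g.zero_grad()
        fake = gen.forward(z, lab, rng=rng)
        loss_g = ag.tmean(ag.softplus(ag.neg(disc.forward(fake, lab))))
        if not np.isfinite(loss_g.data):
            raise RuntimeError(f"generator loss diverged at iteration {it}")
        loss_g.backward()
        opt_g.step()

        if it % config.fid_interval == 0 or it == config.iterations:
            f = _eval_fid(gen, real_slices, config, np.random.default_rng(config.seed + 2))
            trace.append({"iteration": it, "fid": f})
            if f < best_fid:
                best_fid, best_iter, best_state = f, it, gen.copy_state()

    return GANTrainResult(
        best_state=best_state,
        best_fid=best_fid,
        best_iteration=best_iter,
        fid_trace=pd.DataFrame(trace),
        final_state=gen.copy_state(),
    )


# ---------------------------------------------------------------------------
# generation


def generate_slices(
    gen: Generator, n_seeds: int, seed: int = 0, label_policy: str = "cycle"
) -> SliceStack:
    """Sample ``n_seeds`` label slices; pair labels cycle in order by default."""
    if n_seeds < 2:
        raise ValueError("need n_seeds >= 2 to build a volume")
    cfg = gen.cfg
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, size=(n_seeds, cfg.latent_dim))
    if label_policy == "cycle":
        idx = np.arange(n_seeds) % cfg.n_pair_labels
    elif label_policy == "random":
        idx = rng.integers(0, cfg.n_pair_labels, size=n_seeds)
    else:
        raise ValueError(f"unknown label policy {label_policy!r}")
    one_hot = np.eye(cfg.n_pair_labels, dtype=np.float32)[idx]
    labels = gen.sample_labels(z, one_hot, rng=rng)
    return SliceStack(list(labels))


def generate_model_volume(
    gen: Generator,
    n_seeds: int,
    seed: int = 0,
    z_spacing_um: float = 0.4,
    xy_extent_um: float = 10.0,
    order_method: str = "greedy",
    mode: str = "per_class_mean",
    stats_class: int = 1,
    surface_estimator: str = "mesh",
) -> tuple[LabelVolume, pd.DataFrame]:
    """Sample slices, order them by Jaccard distance, assemble a volume and
    quantify it.

    The z-extent scales linearly with ``n_seeds`` (n_seeds x z_spacing µm);
    x/y voxel size is ``xy_extent_um / resolution``. Returns the assembled
    label volume and the shape-statistics table of ``stats_class`` objects
    (empty table if the class is absent).
    """
    stack = generate_slices(gen, n_seeds, seed=seed)
    ordering = order_slices(stack, method=order_method, mode=mode)
    vxy = xy_extent_um / gen.cfg.resolution
    volume = assemble_volume(stack, ordering, voxel_size_um=(z_spacing_um, vxy, vxy))
    comp, n = label_components(volume, class_id=stats_class)
    if n == 0:
        stats = pd.DataFrame()
    else:
        stats = shape_stats(comp, voxel_size_um=volume.voxel_size_um, surface_estimator=surface_estimator)
    return volume, stats


def save_checkpoint(path, module: nn.Module) -> None:
    np.savez(path, **module.state_dict())


def load_checkpoint(path, module: nn.Module) -> None:
    with np.load(path) as data:
        module.load_state_dict({k: data[k] for k in data.files})
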