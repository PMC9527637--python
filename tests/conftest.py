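"""Shared fixtures.

The trained-network fixtures are session-scoped: the same scaled-down
training runs back several behavioural tests, so each experiment executes
once per session.
"""
from __future__ import annotations

import numpy as np
import pytest

from cardiomorph.imio import build_slice_pair_records, extract_patches, make_split
from cardiomorph.phantom import PhantomConfig, generate_phantom, translate_slice_sequence
from cardiomorph.segnet import TrainConfig, UNetSpec, build_unet, predict, train
from cardiomorph.volumes import IntensityVolume, SliceStack
from cardiomorph import ganmod

# -- phantom configs scaled to CPU experiments ------------------------------

#: 32x128x128 voxels at 20 nm: enough texture for segmentation training.
SEG_PHANTOM = PhantomConfig(
    shape_voxels=(32, 128, 128),
    mito_count=10,
    mito_semiaxes_um=(0.15, 0.15, 0.25),
    seed=7,
)

#: 100 slices of 32x32 at 80 nm for the generative model (~100 records).
GAN_PHANTOM = PhantomConfig(
    shape_voxels=(100, 32, 32),
    voxel_size_um=(0.08, 0.08, 0.08),
    mito_count=12,
    mito_semiaxes_um=(0.25, 0.25, 0.35),
    myofibril_width_um=0.6,
    myofibril_fill_fraction=0.3,
    seed=3,
)

N_TRAIN_SLICES = 28  # held-out evaluation uses the remaining slices


def run_segmentation_experiment(seed: int, epochs: int = 45):
    """Train the tiny U-net on phantom patches and evaluate on held-out
    slices; returns (metrics dict, net, phantom volume)."""
    pv = generate_phantom(SEG_PHANTOM)
    train_vol = IntensityVolume(pv.intensity.data[:N_TRAIN_SLICES], pv.intensity.voxel_size_um)
    patches, footprints = extract_patches(train_vol, 64, 24, seed=seed, return_footprints=True)
    images = np.stack(patches)
    labels = np.stack(
        [pv.labels.data[f.slice_index, f.y : f.y + 64, f.x : f.x + 64] for f in footprints]
    ).astype(np.int64)
    split = make_split(list(range(24)), (16, 4, 4), n_folds=1, seed=seed)[0]
    net = build_unet(UNetSpec(input_size=64, base_channels=8), seed=seed)
    result = train(
        net, images, labels, split,
        TrainConfig(epochs=epochs, batch_size=4, learning_rate=3e-3, seed=seed),
    )
    net.load_state_dict(result.best_state)
    held = IntensityVolume(pv.intensity.data[N_TRAIN_SLICES:], pv.intensity.voxel_size_um)
    pred_vol, _ = predict(net, held, tile=64, overlap=16)
    truth = pv.labels.data[N_TRAIN_SLICES:]
    pred = pred_vol.data
    fg_p, fg_t = pred > 0, truth > 0
    metrics = {
        "fg_jaccard": np.logical_and(fg_p, fg_t).sum() / np.logical_or(fg_p, fg_t).sum(),
        "accuracy": (pred == truth).mean(),
        "history": result.history,
    }
    for c in (1, 2):
        inter = ((pred == c) & (truth == c)).sum()
        union = ((pred == c) | (truth == c)).sum()
        metrics[f"jaccard_class{c}"] = inter / union if union else np.nan
    majority = np.zeros_like(truth)
    metrics["majority_accuracy"] = (majority == truth).mean()
    return metrics, net, pv


@pytest.fixture(scope="session")
def seg_runs():
    """Segmentation experiments for three seeds (the learnability study)."""
    return {seed: run_segmentation_experiment(seed) for seed in (0, 1, 2)}


@pytest.fixture(scope="session")
def gan_run():
    """One 200-iteration GAN training run on phantom slice-pair records."""
    pv = generate_phantom(GAN_PHANTOM)
    stack = SliceStack(list(pv.labels.data))
    records = build_slice_pair_records(stack)
    cfg = ganmod.GANConfig(
        resolution=32, n_pair_labels=len(records), iterations=200, batch_size=4, seed=0
    )
    models = ganmod.build_gan(cfg, seed=0)
    result = ganmod.train_gan(models, records, cfg)
    return {"config": cfg, "models": models, "result": result, "records": records, "phantom": pv}


@pytest.fixture(scope="session")
def disc_gan_run():
    """GAN trained on a translated-disc sequence, where consecutive slices
    differ sharply — a clean testbed for pair-label conditioning."""
    yy, xx = np.mgrid[0:16, 0:16]
    disc = (((yy - 8) ** 2 + (xx - 4) ** 2) <= 9).astype(np.uint8)
    stack = translate_slice_sequence(disc, n=8, step_voxels=1)
    records = build_slice_pair_records(stack)
    cfg = ganmod.GANConfig(
        resolution=16,
        latent_dim=32,
        base_channels=32,
        n_pair_labels=len(records),
        iterations=150,
        batch_size=4,
        fid_interval=25,
        seed=1,
    )
    models = ganmod.build_gan(cfg, seed=1)
    result = ganmod.train_gan(models, records, cfg)
    return {"config": cfg, "models": models, "result": result, "records": records, "stack": stack}
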