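# cardiomorph

Segmentation, generative modelling and 3D morphometry of cardiomyocyte
ultrastructure in volume electron microscopy (FIB-SEM / SBF-SEM).

Volume-EM stacks of cardiac muscle show three structures whose geometry
matters for cardiac physiology: **mitochondria**, **myofibrils** and the thin
**Z-discs** that bound each ~2 µm sarcomere. Manually annotating hundreds of
low-contrast slices is the bottleneck of such studies. `cardiomorph`
implements a complete desk-scale workflow that goes from raw image stacks to
statistical 3D models:

1. **Semantic segmentation** (`cardiomorph.segnet`) — a modified U-net: four
   encoder and four decoder blocks around a densely connected bottleneck
   (nine blocks in total), 2×2 max-pooling with channel doubling, skip
   connections by concatenation, trainable linear units (TLUs) in the
   bottleneck, and a four-channel SoftMax output
   `p_n(x) = e^{a_n(x)} / Σ_{n'} e^{a_{n'}(x)}` over background,
   mitochondria, myofibrils and Z-discs. Training all three structures
   jointly sidesteps the extreme class imbalance (<1 % Z-disc pixels) that
   cripples binary Z-disc segmentation.
2. **Generative modelling** (`cardiomorph.ganmod`) — a conditional
   style-based GAN trained on segmented slices: synthesis starts from a
   learned constant tensor, a mapping network produces a style vector that
   modulates every block, noise is injected after each convolution, and a
   one-hot *slice-pair* label enters through an embedding so the model
   captures correlation between consecutive slices. Records are consumed in
   stack order (no shuffling) and convergence is monitored with the Fréchet
   inception distance (FID); the reported checkpoint is the FID minimizer.
3. **Volume assembly** (`cardiomorph.assembly`) — generated 2D slices are
   ordered by minimizing the total Jaccard distance
   `d(A,B) = 1 − |A∩B|/|A∪B|` between consecutive slices (exhaustive search
   for small stacks, greedy chain extension otherwise) and stacked into
   volumes of up to 10 µm × 10 µm × 10 µm.
4. **Morphometry** (`cardiomorph.morpho`) — per-object volume, surface area,
   SA:V, compactness `C = 36πV²/S³`, sphericity `ψ = C^{1/3}`, elongation
   `√(λ1/λ2)`, flatness `√(λ2/λ3)` and spareness; sliding-kernel mito/myo
   density maps (4 µm kernel, 0.4 µm stride); one-way ANOVA comparison of
   shape-metric distributions; mutual 3D Jaccard distances between volumes.
5. **Evaluation** (`cardiomorph.segmetrics`) — confusion-matrix metrics plus
   the foreground-restricted, border-thinned Rand and Information F-scores
   standard in EM segmentation.
6. **Synthetic phantoms** (`cardiomorph.phantom`) — seeded generators of
   intensity + ground-truth label volumes with the statistical structure of
   the real data (periodic sarcomere banding, sparse Z-disc plates,
   ellipsoidal mitochondria between myofibrils, low-contrast noise), so the
   entire pipeline runs and is tested without microscope data.

The neural networks run on a small numpy autograd core
(`cardiomorph.nn`) and train in minutes on one CPU at the package's
desk-scale defaults; every architectural element scales up by config.

## Worked example

```python
import numpy as np

from cardiomorph import phantom, segmetrics, ganmod, morpho
from cardiomorph.imio import build_slice_pair_records
from cardiomorph.volumes import SliceStack

# 1. a synthetic cardiomyocyte volume with ground-truth labels
cfg = phantom.PhantomConfig(
    shape_voxels=(60, 32, 32), voxel_size_um=(0.08, 0.08, 0.08),
    mito_count=8, mito_semiaxes_um=(0.25, 0.25, 0.35),
    myofibril_fill_fraction=0.3, myofibril_width_um=0.6, seed=42,
)
pv = phantom.generate_phantom(cfg)
print(f"Z-disc voxel fraction: {100 * pv.labels.class_fraction(3):.2f}%")

# 2. score an imperfect segmentation against the ground truth
noisy = phantom.degrade_labels(pv.labels, flip_rate=0.05, seed=0)
report = segmetrics.report(noisy.data, pv.labels.data)
print(f"mitochondria Jaccard:  {report.loc[1, 'jaccard']:.3f}")
print(f"V_rand (thinned):      {report.attrs['v_rand_thinned']:.3f}")

# 3. train the conditional style-based GAN on the label slices
records = build_slice_pair_records(SliceStack(list(pv.labels.data)))
gcfg = ganmod.GANConfig(resolution=32, n_pair_labels=len(records),
                        iterations=200, seed=0)
models = ganmod.build_gan(gcfg, seed=0)
result = ganmod.train_gan(models, records, gcfg)
print(f"FID at start / best:   {result.fid_trace.fid.iloc[0]:.2f} / {result.best_fid:.2f}")

# 4. generate a volume (Jaccard-ordered slices) and quantify it
gen = models[0]
gen.load_state_dict(result.best_state)
volume, stats = ganmod.generate_model_volume(gen, n_seeds=25, seed=1,
                                             z_spacing_um=0.4, xy_extent_um=10.0)
ez, ey, ex = volume.extent_um
print(f"generated volume:      {ex:.0f} x {ey:.0f} x {ez:.0f} um, "
      f"{len(stats)} mitochondrial objects")

# 5. do generated and real mitochondria have similar shape statistics?
comp, _ = morpho.label_components(pv.labels, class_id=1)
real = morpho.shape_stats(comp, pv.labels.voxel_size_um)
rep = morpho.compare_distributions(real["sphericity"], stats["sphericity"])
print(f"sphericity ANOVA:      F = {rep.f_means:.2f}, p = {rep.p_means:.3f}")
```

Output (~40 s on one CPU):

```
Z-disc voxel fraction: 0.78%
mitochondria Jaccard:  0.555
V_rand (thinned):      0.949
FID at start / best:   13.93 / 0.09
generated volume:      10 x 10 x 10 um, 3 mitochondrial objects
sphericity ANOVA:      F = 1.74, p = 0.220
```

Reading the numbers: the phantom reproduces the Z-disc rarity (<1 % of
voxels); flipping 5 % of voxels drops the mitochondria Jaccard to 0.55 while
the border-thinned Rand score stays high (boundary errors are forgiven);
200 GAN iterations reduce the FID from 13.9 to 0.09; 25 generated slices at
0.4 µm spacing assemble into a 10 × 10 × 10 µm model; and the sphericity
distributions of generated vs. ground-truth mitochondria are not
significantly different (p = 0.22).

The same workflow is scriptable from the shell via the `cardiomorph` CLI
(`phantom`, `patches`, `split`, `train-seg`, `segment`, `eval`, `assemble`,
`morpho`, `density`, `train-gan`, `generate`); run `cardiomorph --help`.

## Layout

```
src/cardiomorph/
  volumes.py     # IntensityVolume / LabelVolume / SliceStack containers
  phantom.py     # synthetic cardiomyocyte volumes + degradation utilities
  imio.py        # TIFF/HDF5 I/O, patches, K-fold splits, slice-pair records
  nn/            # numpy autograd core, layers, Adam
  segnet.py      # modified U-net: build / train / predict
  segmetrics.py  # confusion metrics, thinned V_rand / V_info
  ganmod.py      # conditional style-based GAN, FID, generation
  assembly.py    # Jaccard slice ordering and stack assembly
  morpho.py      # shape statistics, density maps, ANOVA, mutual Jaccard
  cli.py         # click-based command-line interface
docs/methods.md  # model and design notes
```
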