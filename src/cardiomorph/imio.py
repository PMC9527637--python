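"""Volume/table I/O, patch extraction, data splits and slice-pair records.

Formats: multi-page TIFF (voxel size carried in resolution tags + a JSON
sidecar) and HDF5 (voxel size as a dataset attribute). Coordinates are
0-based (z, y, x) with half-open extents throughout.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .volumes import IntensityVolume, LabelVolume, SliceStack

logger = logging.getLogger(__name__)

VOXEL_ATTR = "voxel_size_um"


class CapacityError(ValueError):
    """Requested more non-overlapping patches than can possibly fit."""


# ---------------------------------------------------------------------------
# volume I/O


def write_volume(path, volume: IntensityVolume | LabelVolume) -> None:
    """Write a volume to multi-page TIFF or HDF5 (by file suffix).

    TIFF stores x/y voxel size in the resolution tags and the full per-axis
    size in a ``<path>.json`` sidecar; HDF5 stores it as a dataset attribute.
    """
    path = Path(path)
    vs = volume.voxel_size_um
    if path.suffix.lower() in {".tif", ".tiff"}:
        # resolution tags are pixels per unit; unit = centimetre
        res = (1e4 / vs[2], 1e4 / vs[1])
        tifffile.imwrite(path, volume.data, resolution=res, resolutionunit="CENTIMETER")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({VOXEL_ATTR: list(vs)})
        )
    elif path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=volume.data)
            ds.attrs[VOXEL_ATTR] = np.asarray(vs)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path, kind: str = "intensity") -> IntensityVolume | LabelVolume:
    """Read a 3D volume from TIFF or HDF5.

    ``kind='labels'`` returns a :class:`LabelVolume` and requires integer
    data; round-tripping integer data through :func:`write_volume` is
    bit-identical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vs = (1.0, 1.0, 1.0)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            vs = tuple(json.loads(sidecar.read_text())[VOXEL_ATTR])
    elif path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            ds = f["volume"]
            data = ds[...]
            if VOXEL_ATTR in ds.attrs:
                vs = tuple(float(v) for v in np.asarray(ds.attrs[VOXEL_ATTR]))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if data.ndim == 2:
        data = data[np.newaxis]
    if kind == "labels":
        if not np.issubdtype(data.dtype, np.integer):
            raise TypeError(f"label volume requires integer data, got {data.dtype}")
        return LabelVolume(data, vs)
    return IntensityVolume(data, vs)


# ---------------------------------------------------------------------------
# patches


@dataclass(frozen=True)
class PatchFootprint:
    """Location of a 2D patch: slice index + top-left corner + size."""

    slice_index: int
    y: int
    x: int
    size: int

    def overlaps(self, other: "PatchFootprint") -> bool:
        if self.slice_index != other.slice_index:
            return False
        return (
            self.y < other.y + other.size
            and other.y < self.y + self.size
            and self.x < other.x + other.size
            and other.x < self.x + self.size
        )


def max_nonoverlapping_patches(shape_yx: tuple[int, int], patch_size: int) -> int:
    """Grid capacity: how many non-overlapping axis-aligned square patches of
    ``patch_size`` fit in one slice of extent (Y, X)."""
    return (shape_yx[0] // patch_size) * (shape_yx[1] // patch_size)


def extract_patches(
    volume: IntensityVolume | LabelVolume,
    patch_size: int,
    n: int,
    policy: str = "random_nonoverlap",
    seed: int = 0,
    return_footprints: bool = False,
):
    """Extract ``n`` random non-overlapping 2D patches from a volume.

    Patches are drawn from randomly offset grids, one offset per z-slice, so
    footprints never overlap in (slice, y, x). Raises :class:`CapacityError`
    when ``n`` exceeds the total grid capacity of the stack.
    """
    if policy != "random_nonoverlap":
        raise ValueError(f"unknown policy {policy!r}")
    data = volume.data
    nz, ny, nx = data.shape
    if patch_size > ny or patch_size > nx:
        raise CapacityError(f"patch_size {patch_size} exceeds slice extents ({ny}, {nx})")
    per_slice = max_nonoverlapping_patches((ny, nx), patch_size)
    if n > per_slice * nz:
        raise CapacityError(
            f"requested {n} non-overlapping patches but at most {per_slice * nz} fit "
            f"({per_slice} per slice x {nz} slices)"
        )
    rng = np.random.default_rng(seed)
    gy, gx = ny // patch_size, nx // patch_size
    cells = []
    for z in range(nz):
        oy = rng.integers(0, ny - gy * patch_size + 1)
        ox = rng.integers(0, nx - gx * patch_size + 1)
        for iy in range(gy):
            for ix in range(gx):
                cells.append(
                    PatchFootprint(z, int(oy + iy * patch_size), int(ox + ix * patch_size), patch_size)
                )
    chosen = rng.choice(len(cells), size=n, replace=False)
    footprints = [cells[i] for i in sorted(chosen)]
    patches = [
        data[f.slice_index, f.y : f.y + f.size, f.x : f.x + f.size].copy() for f in footprints
    ]
    if return_footprints:
        return patches, footprints
    return patches


# ---------------------------------------------------------------------------
# splits


@dataclass
class DatasetSplit:
    """One cross-validation fold: exact disjoint train/val/test id lists."""

    train: list
    val: list
    test: list
    fold_index: int
    n_folds: int
    seed: int

    def __post_init__(self):
        all_ids = self.train + self.val + self.test
        if len(set(map(str, all_ids))) != len(all_ids):
            raise ValueError("train/val/test must be pairwise disjoint")


def make_split(
    patch_ids,
    counts: tuple[int, int, int],
    n_folds: int = 1,
    seed: int = 0,
) -> list[DatasetSplit]:
    """K-fold splits with exact (train, val, test) counts per fold.

    A single seeded permutation is rotated by the validation-block size per
    fold, so validation sets are disjoint across folds whenever
    ``n_folds * val_count <= len(patch_ids)``.
    """
    patch_ids = list(patch_ids)
    n_train, n_val, n_test = counts
    if n_train + n_val + n_test != len(patch_ids):
        raise ValueError(
            f"counts {counts} sum to {n_train + n_val + n_test}, expected {len(patch_ids)}"
        )
    rng = np.random.default_rng(seed)
    perm = [patch_ids[i] for i in rng.permutation(len(patch_ids))]
    folds = []
    for k in range(n_folds):
        rot = perm[k * n_val % max(len(perm), 1) :] + perm[: k * n_val % max(len(perm), 1)]
        val = rot[:n_val]
        test = rot[n_val : n_val + n_test]
        train = rot[n_val + n_test :]
        folds.append(DatasetSplit(train, val, test, fold_index=k, n_folds=n_folds, seed=seed))
    return folds


# ---------------------------------------------------------------------------
# slice-pair records for GAN conditioning


@dataclass
class SlicePairRecord:
    """Two consecutive label slices plus a one-hot index of the pair."""

    slice_a: np.ndarray
    slice_b: np.ndarray
    pair_label: np.ndarray
    index: int

    def __post_init__(self):
        if np.count_nonzero(self.pair_label) != 1:
            raise ValueError("pair_label must be one-hot")


def build_slice_pair_records(
    stack: SliceStack, missing: set[int] | None = None
) -> list[SlicePairRecord]:
    """Encode a stack as consecutive-slice pair records, in stack order.

    The downstream generative model trains on these records *without
    shuffling*, so order is part of the contract. Pairs that would span a
    missing/unusable slice index are dropped with a warning.
    """
    if len(stack) < 2:
        raise ValueError(f"need a stack of at least 2 slices, got {len(stack)}")
    n_pairs = len(stack) - 1
    records = []
    for i in range(n_pairs):
        if missing and (i in missing or i + 1 in missing):
            warnings.warn(f"dropping pair {i}: spans a missing slice", stacklevel=2)
            continue
        one_hot = np.zeros(n_pairs, dtype=np.float32)
        one_hot[i] = 1.0
        records.append(SlicePairRecord(stack[i], stack[i + 1], one_hot, index=i))
    return records


def save_records(path, records: list[SlicePairRecord]) -> None:
    """Serialize slice-pair records to HDF5."""
    with h5py.File(path, "w") as f:
        for i, r in enumerate(records):
            g = f.create_group(f"record_{i:05d}")
            g.create_dataset("slice_a", data=r.slice_a)
            g.create_dataset("slice_b", data=r.slice_b)
            g.create_dataset("pair_label", data=r.pair_label)
            g.attrs["index"] = r.index


def load_records(path) -> list[SlicePairRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            records.append(
                SlicePairRecord(
                    g["slice_a"][...], g["slice_b"][...], g["pair_label"][...], int(g.attrs["index"])
                )
            )
    return records
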