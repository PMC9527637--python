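"""Core in-memory containers for 3D EM volumes.

Conventions: arrays are (z, y, x), 0-based, half-open extents. Voxel size is
per-axis in micrometres, same axis order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class ids for cardiomyocyte ultrastructure labels.
BACKGROUND, MITOCHONDRIA, MYOFIBRIL, ZDISC = 0, 1, 2, 3
CLASS_NAMES = {
    BACKGROUND: "background",
    MITOCHONDRIA: "mitochondria",
    MYOFIBRIL: "myofibril",
    ZDISC: "zdisc",
}
N_CLASSES = 4


def _as_voxel_size(voxel_size_um) -> tuple[float, float, float]:
    if np.isscalar(voxel_size_um):
        voxel_size_um = (voxel_size_um,) * 3
    vs = tuple(float(v) for v in voxel_size_um)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel size must be 3 positive reals, got {voxel_size_um!r}")
    return vs


@dataclass
class IntensityVolume:
    """3D grayscale stack with physical voxel size in µm (z, y, x)."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"intensity volume must be 3D, got ndim={self.data.ndim}")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent per axis (µm)."""
        return tuple(s * v for s, v in zip(self.data.shape, self.voxel_size_um))


@dataclass
class LabelVolume:
    """3D integer class map sharing geometry with an :class:`IntensityVolume`."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label volume requires integer dtype, got {self.data.dtype}")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.data.shape, self.voxel_size_um))

    def class_fraction(self, class_id: int) -> float:
        """Fraction of voxels assigned to ``class_id``."""
        return float(np.count_nonzero(self.data == class_id)) / self.data.size


@dataclass
class SliceStack:
    """Ordered sequence of 2D label slices, candidate for 3D assembly."""

    slices: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.slices = [np.asarray(s) for s in self.slices]
        if self.slices:
            shape = self.slices[0].shape
            for s in self.slices:
                if s.ndim != 2 or s.shape != shape:
                    raise ValueError("all slices must be 2D with identical shape")

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i):
        return self.slices[i]

    def __iter__(self):
        return iter(self.slices)

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices[0].shape
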