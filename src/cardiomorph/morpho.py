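"""3D quantification of segmented/generated volumes.

Per-object shape statistics (volume, surface area, SA:V, compactness,
sphericity, elongation, flatness, spareness), sliding-window
mitochondria/myofibril density maps, and distribution comparison by one-way
ANOVA plus a variance-ratio test.

Definitions (for an object with volume V, surface S and principal second
moments λ1 ≥ λ2 ≥ λ3 of its voxel coordinates, scaled to µm):

- compactness  C = 36 π V² / S³          (1 for a sphere)
- sphericity   ψ = C^{1/3}               (1 for a sphere)
- elongation   √(λ1/λ2)                  (≥ 1)
- flatness     √(λ2/λ3)                  (≥ 1)
- spareness    V / V_ellipsoid, the volume of the covariance-matched
  ellipsoid with semi-axes a_i = √(5 λ_i)
- SA:V         S / V (µm⁻¹)

Surface area defaults to the triangulated marching-cubes estimate; the
voxel-face count is available but biased high (≈1.5x for a ball) and wrecks
compactness through the S³ denominator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from .assembly import jaccard_distance
from .volumes import LabelVolume

MIN_RELIABLE_VOXELS = 4


def label_components(mask, class_id: int | None = None, connectivity: int = 26):
    """Connected components of a class mask.

    ``connectivity`` is 6 (faces) or 26 (faces+edges+corners); ids are
    assigned deterministically in scan order. Accepts a LabelVolume plus
    ``class_id``, or a boolean array directly.
    """
    if connectivity not in (6, 26):
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    data = np.asarray(getattr(mask, "data", mask))
    binary = data if data.dtype == bool else (data == class_id)
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labelled, n = ndimage.label(binary, structure=structure)
    return labelled, n


def _surface_area(component: np.ndarray, voxel_size, estimator: str) -> float:
    vz, vy, vx = voxel_size
    if estimator == "mesh":
        # anti-alias the binary mask before meshing: marching cubes on a raw
        # 0/1 field overestimates a ball's area by ~9% (staircase artefact);
        # a 0.8-voxel Gaussian brings it within a fraction of a percent
        padded = np.pad(component.astype(np.float64), 2)
        smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
        if smoothed.max() <= 0.5:  # tiny objects can be smoothed away
            smoothed = padded
        verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=(vz, vy, vx))
        return float(measure.mesh_surface_area(verts, faces))
    if estimator == "voxel_faces":
        area = 0.0
        face_areas = (vy * vx, vz * vx, vz * vy)
        for axis, fa in enumerate(face_areas):
            padded = np.pad(component, 1)
            diff = np.diff(padded.astype(np.int8), axis=axis)
            area += np.count_nonzero(diff) * fa
        return float(area)
    raise ValueError(f"unknown surface estimator {estimator!r}")


def shape_stats(
    component_map: np.ndarray,
    voxel_size_um=(1.0, 1.0, 1.0),
    surface_estimator: str = "mesh",
) -> pd.DataFrame:
    """Per-component shape statistics table.

    Principal moments come from the eigen-decomposition of the (physically
    scaled) voxel-coordinate covariance; components of fewer than 4 voxels
    are kept but flagged unreliable.
    """
    component_map = np.asarray(getattr(component_map, "data", component_map))
    ids = np.unique(component_map)
    ids = ids[ids != 0]
    if ids.size == 0:
        raise ValueError("component map contains no components")
    vz, vy, vx = voxel_size_um
    voxel_volume = vz * vy * vx
    rows = []
    objects = ndimage.find_objects(component_map)
    for cid in ids:
        sl = objects[int(cid) - 1]
        sub = component_map[sl] == cid
        n_vox = int(np.count_nonzero(sub))
        V = n_vox * voxel_volume
        S = _surface_area(sub, voxel_size_um, surface_estimator)
        coords = np.argwhere(sub).astype(float)
        coords *= np.array([vz, vy, vx])
        if n_vox > 1:
            cov = np.cov(coords.T, bias=True)
            lam = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
            lam = np.clip(lam, 0.0, None)
        else:
            lam = np.zeros(3)
        l1, l2, l3 = lam
        elongation = np.sqrt(l1 / l2) if l2 > 0 else np.nan
        flatness = np.sqrt(l2 / l3) if l3 > 0 else np.nan
        semi = np.sqrt(5.0 * lam)
        v_ell = 4.0 / 3.0 * np.pi * semi[0] * semi[1] * semi[2]
        compactness = 36.0 * np.pi * V**2 / S**3 if S > 0 else np.nan
        rows.append(
            {
                "component_id": int(cid),
                "n_voxels": n_vox,
                "volume_um3": V,
                "surface_um2": S,
                "sa_to_v": S / V,
                "compactness": compactness,
                "sphericity": compactness ** (1.0 / 3.0) if compactness == compactness else np.nan,
                "elongation": elongation,
                "flatness": flatness,
                "spareness": V / v_ell if v_ell > 0 else np.nan,
                "reliable": n_vox >= MIN_RELIABLE_VOXELS,
            }
        )
    return pd.DataFrame(rows).set_index("component_id")


SHAPE_METRICS = ("sa_to_v", "compactness", "sphericity", "elongation", "flatness", "spareness")


def shape_stats_from_measures(V: float, S: float) -> dict[str, float]:
    """Compactness/sphericity/SA:V from exact (continuous) V and S measures."""
    return {
        "compactness": 36.0 * np.pi * V**2 / S**3,
        "sphericity": (36.0 * np.pi * V**2 / S**3) ** (1.0 / 3.0),
        "sa_to_v": S / V,
    }


@dataclass
class DensityMap:
    """Sliding-window mito/myo voxel-count ratios on a stride grid.

    Cells whose window contains no myofibril voxels are NaN; their count is
    reported separately so histograms can state what was excluded.
    """

    values: np.ndarray
    kernel_um: tuple[float, float, float]
    stride_um: float
    n_undefined: int

    def defined_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def density_map(
    labels: LabelVolume,
    kernel_um=4.0,
    stride_um: float = 0.4,
    numerator_class: int = 1,
    denominator_class: int = 2,
) -> DensityMap:
    """Mito/myo density: ratio of class-1 to class-2 voxel counts in a
    sliding cubic window (default 4 µm kernel, 0.4 µm stride), evaluated only
    where the window lies fully inside the volume."""
    data = labels.data
    vs = np.asarray(labels.voxel_size_um)
    if np.isscalar(kernel_um):
        kernel_um = (float(kernel_um),) * 3
    k_vox = np.maximum(1, np.round(np.asarray(kernel_um) / vs)).astype(int)
    s_vox = np.maximum(1, np.round(stride_um / vs)).astype(int)
    if np.any(k_vox > data.shape):
        raise ValueError(f"kernel {tuple(k_vox)} voxels exceeds volume shape {data.shape}")

    def window_sums(mask):
        # summed-area table -> box sums at every voxel origin
        c = np.pad(mask.astype(np.int64), ((1, 0),) * 3).cumsum(0).cumsum(1).cumsum(2)
        kz, ky, kx = k_vox
        nz, ny, nx = data.shape
        oz, oy, ox = nz - kz + 1, ny - ky + 1, nx - kx + 1
        return (
            c[kz : kz + oz, ky : ky + oy, kx : kx + ox]
            - c[:oz, ky : ky + oy, kx : kx + ox]
            - c[kz : kz + oz, :oy, kx : kx + ox]
            - c[kz : kz + oz, ky : ky + oy, :ox]
            + c[:oz, :oy, kx : kx + ox]
            + c[:oz, ky : ky + oy, :ox]
            + c[kz : kz + oz, :oy, :ox]
            - c[:oz, :oy, :ox]
        )

    num = window_sums(data == numerator_class)[:: s_vox[0], :: s_vox[1], :: s_vox[2]]
    den = window_sums(data == denominator_class)[:: s_vox[0], :: s_vox[1], :: s_vox[2]]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return DensityMap(
        values=values,
        kernel_um=tuple(float(k) for k in np.atleast_1d(kernel_um)),
        stride_um=float(stride_um),
        n_undefined=int(np.count_nonzero(den == 0)),
    )


@dataclass
class ComparisonReport:
    """One-way ANOVA on means plus an F-ratio test on variances."""

    f_means: float
    p_means: float
    f_var: float
    p_var: float
    effect_size: float  # eta squared
    n_a: int
    n_b: int
    degenerate: bool = False


def compare_distributions(sample_a, sample_b) -> ComparisonReport:
    """Compare two real-valued samples: equality of means (one-way ANOVA) and
    of variances (two-sided F-ratio test)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite values per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        same = np.isclose(a.mean(), b.mean())
        warnings.warn("both samples have zero variance; comparison degenerate", stacklevel=2)
        return ComparisonReport(
            f_means=0.0 if same else np.inf,
            p_means=1.0 if same else 0.0,
            f_var=np.nan,
            p_var=np.nan,
            effect_size=0.0 if same else 1.0,
            n_a=len(a),
            n_b=len(b),
            degenerate=True,
        )
    f_means, p_means = stats.f_oneway(a, b)
    grand = np.concatenate([a, b]).mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_total = ((np.concatenate([a, b]) - grand) ** 2).sum()
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if min(va, vb) == 0:
        f_var, p_var = np.inf, 0.0
    else:
        f_var = va / vb
        dfa, dfb = len(a) - 1, len(b) - 1
        p_one = stats.f.sf(f_var, dfa, dfb) if f_var >= 1 else stats.f.cdf(f_var, dfa, dfb)
        p_var = min(1.0, 2.0 * p_one)
    return ComparisonReport(
        f_means=float(f_means),
        p_means=float(p_means),
        f_var=float(f_var),
        p_var=float(p_var),
        effect_size=float(eta2),
        n_a=len(a),
        n_b=len(b),
    )


def mutual_volume_jaccard(volumes: list, mode: str = "foreground") -> np.ndarray:
    """Symmetric matrix of pairwise 3D Jaccard distances between volumes."""
    shapes = {np.asarray(getattr(v, "data", v)).shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"volumes must share a shape, got {shapes}")
    n = len(volumes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(volumes[i], volumes[j], mode=mode)
    return d
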