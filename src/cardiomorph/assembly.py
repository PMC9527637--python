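"""Slice ordering and 3D stack assembly.

Generated 2D slices carry no intrinsic z-order; they are arranged into a
stack by minimizing the total Jaccard distance between consecutive slices —
exactly (exhaustive permutation search) for small stacks, greedily
(chain extension from the closest pair) for larger ones. The objective is an
open path: a stack has two ends, so every ordering is equivalent to its
reversal and the canonical representative starts with the smaller end index.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .volumes import LabelVolume, SliceStack

EXHAUSTIVE_LIMIT = 10


def jaccard_distance(a, b, mode: str = "foreground") -> float:
    """Jaccard distance between two label arrays (2D slices or 3D volumes).

    ``foreground``: 1 - |A∩B|/|A∪B| over the nonzero masks.
    ``per_class_mean``: unweighted mean of per-class distances over the
    classes present in either array. Two empty arrays are at distance 0.
    """
    a = np.asarray(getattr(a, "data", a))
    b = np.asarray(getattr(b, "data", b))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mode == "foreground":
        fa, fb = a != 0, b != 0
        union = np.count_nonzero(fa | fb)
        if union == 0:
            return 0.0
        return 1.0 - np.count_nonzero(fa & fb) / union
    if mode == "per_class_mean":
        classes = np.union1d(np.unique(a), np.unique(b))
        classes = classes[classes != 0]
        if classes.size == 0:
            return 0.0
        dists = []
        for c in classes:
            ca, cb = a == c, b == c
            union = np.count_nonzero(ca | cb)
            dists.append(1.0 - np.count_nonzero(ca & cb) / union if union else 0.0)
        return float(np.mean(dists))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class OrderingResult:
    """A slice permutation with its total consecutive-distance cost."""

    permutation: list[int]
    total_cost: float
    method: str

    def __post_init__(self):
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError("permutation must be a bijection on slice indices")
        if self.total_cost < -1e-12:
            raise ValueError("total cost must be non-negative")


def pairwise_distances(slices: SliceStack, mode: str = "per_class_mean") -> np.ndarray:
    n = len(slices)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(slices[i], slices[j], mode=mode)
    return d


def _path_cost(d: np.ndarray, perm) -> float:
    return float(sum(d[perm[i], perm[i + 1]] for i in range(len(perm) - 1)))


def _canonical(perm: tuple) -> tuple:
    rev = perm[::-1]
    return min(perm, rev)


def order_slices(
    slices: SliceStack, method: str = "greedy", mode: str = "per_class_mean"
) -> OrderingResult:
    """Order slices to minimize total consecutive Jaccard distance.

    ``exhaustive`` scans all permutations (n <= 10) and returns the global
    minimizer, ties broken by the lexicographically smallest permutation;
    ``greedy`` seeds with the closest pair and repeatedly appends the nearest
    unused slice to whichever end is closer.
    """
    n = len(slices)
    if n < 2:
        raise ValueError("need at least 2 slices to order")
    d = pairwise_distances(slices, mode=mode)
    if method == "exhaustive":
        if n > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive ordering is limited to n <= {EXHAUSTIVE_LIMIT} "
                f"(got {n}); use method='greedy'"
            )
        best_perm, best_cost = None, np.inf
        for perm in permutations(range(n)):
            perm = _canonical(perm)
            cost = _path_cost(d, perm)
            if cost < best_cost - 1e-12 or (
                abs(cost - best_cost) <= 1e-12 and (best_perm is None or perm < best_perm)
            ):
                best_perm, best_cost = perm, cost
        return OrderingResult(list(best_perm), best_cost, "exhaustive")
    if method == "greedy":
        if n == 2:
            return OrderingResult([0, 1], float(d[0, 1]), "greedy")
        iu = np.triu_indices(n, k=1)
        k = int(np.argmin(d[iu]))
        left, right = int(iu[0][k]), int(iu[1][k])
        chain = [left, right]
        used = {left, right}
        while len(chain) < n:
            rest = [i for i in range(n) if i not in used]
            dl = [d[chain[0], i] for i in rest]
            dr = [d[chain[-1], i] for i in rest]
            if min(dl) <= min(dr):
                pick = rest[int(np.argmin(dl))]
                chain.insert(0, pick)
            else:
                pick = rest[int(np.argmin(dr))]
                chain.append(pick)
            used.add(pick)
        perm = list(_canonical(tuple(chain)))
        return OrderingResult(perm, _path_cost(d, perm), "greedy")
    raise ValueError(f"unknown method {method!r}")


def assemble_volume(
    slices: SliceStack,
    ordering: OrderingResult,
    voxel_size_um=(0.4, 0.02, 0.02),
) -> LabelVolume:
    """Stack slices in permutation order into a 3D label volume.

    ``voxel_size_um`` is (z, y, x); z is the inter-slice spacing, so the
    reported physical extent is ``n_slices * z_spacing`` deep.
    """
    if sorted(ordering.permutation) != list(range(len(slices))):
        raise ValueError("ordering does not match the slice stack")
    data = np.stack([np.asarray(slices[i]) for i in ordering.permutation])
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint8)
    return LabelVolume(data, voxel_size_um)
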