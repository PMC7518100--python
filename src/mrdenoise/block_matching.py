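"""Nonlocal cube matching and aggregation for 3D volumes.

Reference cubes of edge ``p`` are placed on a regular grid; for each one the
``m`` most similar cubes (squared Euclidean distance, reference included and
always first) are collected from an ``L x L x L`` search window and stacked
along a fourth axis.  After per-group denoising the cubes are averaged back
into the volume with uniform weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Volume3D",
    "CubeGroup",
    "reference_positions",
    "match_cubes",
    "aggregate",
    "VolumeAccumulator",
]


@dataclass
class Volume3D:
    """A 3D nonnegative intensity array plus its nominal dynamic range."""

    data: np.ndarray
    max_intensity: float = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume entries must be finite")
        if self.max_intensity is None:
            self.max_intensity = float(self.data.max()) if self.data.size else 0.0


def _vol_data(vol) -> np.ndarray:
    if isinstance(vol, Volume3D):
        return vol.data
    arr = np.asarray(vol, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"volume must be 3-D, got ndim={arr.ndim}")
    return arr


@dataclass
class CubeGroup:
    """A stack of matched cubes: ``tensor`` has shape (p, p, p, m_eff) and
    ``corners[k]`` is the 0-based corner of cube k (occupying [c, c+p) per
    axis).  The reference cube sits at stack index ``ref_index`` (always 0).
    """

    tensor: np.ndarray
    corners: np.ndarray
    ref_index: int = 0

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        self.corners = np.asarray(self.corners, dtype=np.intp)
        if self.tensor.ndim != 4:
            raise ValueError("group tensor must be 4-way")
        if self.corners.shape != (self.tensor.shape[3], 3):
            raise ValueError("corners inconsistent with stack size")


def reference_positions(shape, p: int, stride: int):
    """Regular grid of reference-cube corners with the last position per
    axis snapped to ``dim - p`` so the whole volume is covered."""
    shape = tuple(int(s) for s in shape)
    p, stride = int(p), int(stride)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    axes = []
    for dim in shape:
        if p > dim:
            raise ValueError(f"cube edge {p} exceeds volume dimension {dim}")
        pos = list(range(0, dim - p + 1, stride))
        if pos[-1] != dim - p:
            pos.append(dim - p)
        axes.append(pos)
    return [
        (x, y, z) for x in axes[0] for y in axes[1] for z in axes[2]
    ]


def match_cubes(vol, ref_corner, p: int, m: int, L: int) -> CubeGroup:
    """Collect the ``m`` cubes most similar to the reference inside an
    ``L x L x L`` window (clipped at volume borders, no padding).

    Distance is the sum of squared voxel differences.  The reference is
    always first; ties among other candidates are broken by lexicographic
    corner order.  Fewer than ``m`` in-window candidates means all are used.
    """
    data = _vol_data(vol)
    p, m, L = int(p), int(m), int(L)
    if L % 2 == 0:
        raise ValueError(f"search window edge L must be odd, got {L}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    ref = tuple(int(c) for c in ref_corner)
    for c, dim in zip(ref, data.shape):
        if c < 0 or c + p > dim:
            raise ValueError(f"reference cube at {ref} not inside volume")
    half = (L - 1) // 2
    lo = [max(0, c - half) for c in ref]
    hi = [min(dim - p, c + half) for c, dim in zip(ref, data.shape)]
    region = data[lo[0] : hi[0] + p, lo[1] : hi[1] + p, lo[2] : hi[2] + p]
    wins = sliding_window_view(region, (p, p, p))
    ref_cube = data[ref[0] : ref[0] + p, ref[1] : ref[1] + p, ref[2] : ref[2] + p]
    dist = ((wins - ref_cube) ** 2).sum(axis=(3, 4, 5)).ravel()
    # candidates flattened in C order = lexicographic corner order; stable
    # argsort then preserves that order among ties
    ref_flat = np.ravel_multi_index(
        tuple(r - l for r, l in zip(ref, lo)), wins.shape[:3]
    )
    dist[ref_flat] = -1.0  # force the reference to the front
    order = np.argsort(dist, kind="stable")[:m]
    corners = np.stack(np.unravel_index(order, wins.shape[:3]), axis=1)
    corners += np.asarray(lo, dtype=corners.dtype)
    tensor = np.moveaxis(
        wins.reshape(-1, p, p, p)[order], 0, -1
    )
    return CubeGroup(tensor=np.ascontiguousarray(tensor), corners=corners)


class VolumeAccumulator:
    """Streaming numerator/denominator accumulator for cube aggregation."""

    def __init__(self, shape):
        self.num = np.zeros(shape, dtype=np.float64)
        self.den = np.zeros(shape, dtype=np.float64)

    def add(self, tensor: np.ndarray, corners: np.ndarray) -> None:
        p = tensor.shape[0]
        for k in range(tensor.shape[3]):
            x, y, z = corners[k]
            self.num[x : x + p, y : y + p, z : z + p] += tensor[..., k]
            self.den[x : x + p, y : y + p, z : z + p] += 1.0

    def finish(self) -> np.ndarray:
        if np.any(self.den == 0):
            raise RuntimeError(
                "voxels with zero cube coverage: stride/reference grid "
                "contract is broken"
            )
        return self.num / self.den


def aggregate(groups, shape) -> np.ndarray:
    """Average all cube contributions back into a volume of ``shape``
    (uniform weights).  Raises if any voxel receives no contribution."""
    acc = VolumeAccumulator(tuple(int(s) for s in shape))
    for g in groups:
        p = g.tensor.shape[0]
        if np.any(g.corners < 0) or np.any(g.corners + p > np.asarray(acc.num.shape)):
            raise ValueError("cube outside volume")
        acc.add(g.tensor, g.corners)
    return acc.finish()
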