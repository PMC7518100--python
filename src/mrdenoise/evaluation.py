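"""Quality metrics and the synthetic piecewise-smooth phantom generator.

``ssim_paper`` is the global single-window similarity index using the
product of the two standard deviations in the cross term; ``ssim_standard``
is the conventional windowed SSIM from scikit-image, kept for sanity
comparisons (the global form cannot detect structure scrambling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity

from .block_matching import Volume3D, _vol_data

__all__ = [
    "MetricParams",
    "PhantomSpec",
    "psnr",
    "ssim_paper",
    "ssim_standard",
    "make_phantom",
]


@dataclass
class MetricParams:
    max_intensity: float
    c1: float = None
    c2: float = None

    def __post_init__(self):
        if self.c1 is None:
            self.c1 = (0.01 * self.max_intensity) ** 2
        if self.c2 is None:
            self.c2 = (0.03 * self.max_intensity) ** 2
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("c1 and c2 must be positive")


def _pair(ref, test):
    a, b = _vol_data(ref), _vol_data(test)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(ref, test, max_intensity: float) -> float:
    """Peak signal-to-noise ratio ``10*log10(MAX^2 / MSE)`` in dB.
    Identical inputs return ``inf``."""
    a, b = _pair(ref, test)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_intensity**2 / mse)


def ssim_paper(ref, test, params: MetricParams) -> float:
    """Global similarity index over the whole volume (single mean/std per
    image, std product in the cross term).  Always <= 1; equals 1 iff the
    means and stds match."""
    a, b = _pair(ref, test)
    mu_a, mu_b = float(a.mean()), float(b.mean())
    sd_a, sd_b = float(a.std()), float(b.std())
    num = (2 * mu_a * mu_b + params.c1) * (2 * sd_a * sd_b + params.c2)
    den = (mu_a**2 + mu_b**2 + params.c1) * (sd_a**2 + sd_b**2 + params.c2)
    return num / den


def ssim_standard(ref, test, max_intensity: float) -> float:
    """Conventional windowed SSIM (scikit-image) for cross-checking."""
    a, b = _pair(ref, test)
    return float(structural_similarity(a, b, data_range=max_intensity))


@dataclass
class PhantomSpec:
    """Parameters of the synthetic piecewise-smooth volume."""

    shape: tuple = (64, 64, 64)
    n_ellipsoids: int = 6
    intensity_levels: tuple = (40.0, 80.0, 120.0, 160.0, 200.0, 255.0)
    smoothing_width: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 16 for s in self.shape):
            raise ValueError("phantom shape must be at least 16 per axis")
        levels = np.asarray(self.intensity_levels, dtype=np.float64)
        if np.any(levels < 0):
            raise ValueError("intensity levels must be nonnegative")
        self.intensity_levels = tuple(float(v) for v in levels)


def make_phantom(spec: PhantomSpec) -> Volume3D:
    """Deterministic-for-seed phantom: overlapping ellipsoids over a dark
    background, a few 1-2 voxel sheets for thin structure, and optional
    Gaussian edge smoothing.

    With ``smoothing_width == 0`` every voxel takes one of the listed levels
    or the zero background, so at most ``len(levels) + 1`` distinct values.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    levels = spec.intensity_levels
    data = np.zeros(shape, dtype=np.float64)
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    for i in range(spec.n_ellipsoids):
        center = [rng.uniform(0.2 * s, 0.8 * s) for s in shape]
        axes = [rng.uniform(0.1 * s, 0.35 * s) for s in shape]
        mask = (
            sum(((c - mu) / ax) ** 2 for c, mu, ax in zip(coords, center, axes)) <= 1.0
        )
        data[mask] = levels[i % len(levels)]
    # thin sheets (1-2 voxels) to exercise edge preservation
    for j in range(2):
        axis = int(rng.integers(0, 3))
        idx = int(rng.integers(shape[axis] // 4, 3 * shape[axis] // 4))
        thickness = 1 + j % 2
        sl = [slice(None)] * 3
        sl[axis] = slice(idx, idx + thickness)
        data[tuple(sl)] = levels[(j + 1) % len(levels)]
    if spec.smoothing_width > 0:
        data = gaussian_filter(data, spec.smoothing_width)
    np.clip(data, 0.0, max(levels), out=data)
    return Volume3D(data, max_intensity=max(levels))
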