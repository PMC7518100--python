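"""End-to-end denoising loop.

The stabilized volume is denoised in T outer passes.  Each pass mixes the
current estimate back toward the stabilized input (iterate feedback weight
beta), shrinks the working noise level (feedback weight gamma), and runs one
sweep of cube matching + per-group truncated-HOSVD denoising + aggregation.
The result is mapped back through the exact unbiased inverse stabilizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .block_matching import (
    Volume3D,
    VolumeAccumulator,
    _vol_data,
    match_cubes,
    reference_positions,
)
from .rician import NoiseModel, build_stabilizer, update_sigma
from .shrinkage import ShrinkageParams, estimate_truncation
from .tensor_core import reconstruct

__all__ = [
    "DenoiseConfig",
    "DenoiseResult",
    "default_params",
    "compute_threshold",
    "denoise_stabilized",
    "denoise_volume",
]

# cube edge / group size schedule, indexed by noise level (% of max intensity)
_LEVEL_GRID = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0)
_P_GRID = (3, 3, 4, 4, 5, 5, 5, 5)
_M_GRID = (50, 75, 75, 75, 90, 90, 90, 90)

_MIN_SIGMA = 1e-6  # keeps the shrinkage threshold strictly positive


def default_params(noise_level_percent: float):
    """Cube edge ``p`` and group size ``m`` for a noise level given as % of
    the maximum intensity; nearest grid level, ties toward the higher one."""
    level = float(noise_level_percent)
    if not level > 0:
        raise ValueError(f"noise level must be positive, got {level}")
    if level > 20:
        raise ValueError(f"noise level {level}% outside supported range (<= 20)")
    diffs = np.abs(np.asarray(_LEVEL_GRID) - level)
    # argmax over reversed minima -> highest level among ties
    candidates = np.flatnonzero(diffs == diffs.min())
    idx = int(candidates[-1])
    return _P_GRID[idx], _M_GRID[idx]


def compute_threshold(
    sigma_vst: float, p: int, m: int, rule: str = "literal_tau"
) -> ShrinkageParams:
    """Shrinkage parameters from the universal-threshold constant
    ``tau = 2*log(p^3 m)``.

    ``literal_tau``: lam = tau, a = 0.5/tau (default).  With the stabilized
    noise at unit variance, tau tracks the largest noise singular value of
    the mode-4 unfolding (sigma * (sqrt(m) + sqrt(p^3)) within a few
    percent for the whole parameter schedule), which is what makes the rank
    estimate discard noise-only directions.
    ``universal_sigma``: lam = sigma_vst * sqrt(tau), a = 0.5/lam; the
    per-coefficient universal threshold, far below the singular-value noise
    edge of the unfoldings, so it truncates almost nothing — kept as a
    config option only.
    Either way ``a * lam = 0.5 < 1`` so the objective stays strictly convex.
    """
    if not (sigma_vst > 0 and p > 0 and m > 0):
        raise ValueError("sigma_vst, p, m must be positive")
    tau = 2.0 * math.log(p**3 * m)
    if rule == "universal_sigma":
        lam = sigma_vst * math.sqrt(tau)
    elif rule == "literal_tau":
        lam = tau
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return ShrinkageParams(lam=lam, a=0.5 / lam, tau=tau)


@dataclass
class DenoiseConfig:
    """Knobs of the outer loop and the matching stage."""

    p: int = 4
    m: int = 75
    L: int = 13
    stride: int = 3
    beta: float = 0.65
    gamma: float = 0.2
    T: int = 2
    threshold_rule: str = "literal_tau"
    sigma_schedule: str = "delayed"
    seed: int = 0

    def __post_init__(self):
        if self.p < 2:
            raise ValueError(f"p must be >= 2, got {self.p}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.L % 2 == 0 or self.L < self.p:
            raise ValueError(f"L must be odd and >= p, got L={self.L}, p={self.p}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not 0 <= self.gamma <= 1:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.threshold_rule not in ("universal_sigma", "literal_tau"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.sigma_schedule not in ("literal", "delayed"):
            raise ValueError(f"unknown sigma schedule {self.sigma_schedule!r}")

    @classmethod
    def for_noise_level(cls, noise_level_percent: float, **overrides):
        p, m = default_params(noise_level_percent)
        overrides.setdefault("p", p)
        overrides.setdefault("m", m)
        return cls(**overrides)


@dataclass
class DenoiseResult:
    volume: Volume3D
    diagnostics: list = field(default_factory=list)


def denoise_stabilized(vol, sigma_vst: float, cfg: DenoiseConfig):
    """One sweep over all reference positions: match, denoise each group by
    truncated HOSVD, aggregate with uniform weights.

    Returns ``(denoised array, diagnostics dict)`` with the group count and
    the mean estimated rank per mode.
    """
    data = _vol_data(vol)
    sigma = max(float(sigma_vst), _MIN_SIGMA)
    params = compute_threshold(sigma, cfg.p, cfg.m, cfg.threshold_rule)
    positions = reference_positions(data.shape, cfg.p, cfg.stride)
    acc = VolumeAccumulator(data.shape)
    rank_sums = np.zeros(4)
    for corner in positions:
        group = match_cubes(data, corner, cfg.p, cfg.m, cfg.L)
        factors = estimate_truncation(group.tensor, params)
        acc.add(reconstruct(factors), group.corners)
        rank_sums += factors.ranks
    diag = {
        "sigma_vst": sigma,
        "lam": params.lam,
        "n_groups": len(positions),
        "mean_ranks": tuple(rank_sums / len(positions)),
    }
    return acc.finish(), diag


def denoise_volume(noisy, sigma_n: float, cfg: DenoiseConfig) -> DenoiseResult:
    """Full pipeline: forward VST, T regularized denoising passes with noise
    feedback, inverse VST, clamp to nonnegative intensities."""
    if not sigma_n > 0:
        raise ValueError(f"sigma_n must be positive, got {sigma_n}")
    data = _vol_data(noisy)
    model = NoiseModel(sigma_n=float(sigma_n), sigma_vst=1.0)
    table = build_stabilizer(model.sigma_n, target=model.sigma_vst)
    y_stab = table.forward(data)
    x = y_stab.copy()
    sigma = model.sigma_vst
    diagnostics = []
    for t in range(1, cfg.T + 1):
        y_t = x + cfg.beta * (y_stab - x)
        if cfg.sigma_schedule == "literal" or t > 1:
            sigma = update_sigma(sigma, y_stab, y_t, cfg.gamma)
        sigma = max(sigma, _MIN_SIGMA)
        x, diag = denoise_stabilized(y_t, sigma, cfg)
        diag["iteration"] = t
        diagnostics.append(diag)
    out = np.maximum(table.inverse(x), 0.0)
    max_int = noisy.max_intensity if isinstance(noisy, Volume3D) else float(out.max())
    return DenoiseResult(
        volume=Volume3D(out, max_intensity=max_int), diagnostics=diagnostics
    )
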