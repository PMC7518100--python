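"""Nonconvex spectral shrinkage and adaptive multilinear rank truncation.

The scalar threshold operator is the proximal map of the parameterized
logarithmic penalty ``lam * (1/a) * log(1 + a*x)``, which stays strictly
convex as part of the quadratic objective whenever ``0 <= a < 1/lam``.
Group denoising keeps, per mode, the leading singular vectors whose shrunk
singular values survive the threshold, and reconstructs by orthogonal
projection onto the resulting multilinear subspace.  Only rank truncation is
applied: the shrunk values drive rank selection and are never substituted
into the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor_core import (
    HOSVDFactors,
    _VALID_MODES,
    _as_tensor4,
    _fix_signs,
    mode_product,
    reconstruct,
    unfold,
)

__all__ = [
    "ShrinkageParams",
    "log_prox",
    "soft_threshold_spectrum",
    "shrink_spectrum",
    "estimate_truncation",
    "denoise_group",
]


@dataclass(frozen=True)
class ShrinkageParams:
    """Threshold ``lam``, nonconvexity parameter ``a`` and the universal
    threshold constant ``tau = 2*log(p^3 m)`` they were derived from."""

    lam: float
    a: float
    tau: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not self.a < 1.0 / self.lam:
            raise ValueError(
                f"convexity requires a < 1/lam; got a={self.a}, "
                f"1/lam={1.0 / self.lam}"
            )
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


def log_prox(y, lam: float, a: float):
    """Closed-form proximal operator of the log penalty.

    Returns 0 where ``|y| < lam``; elsewhere
    ``sign(y) * (|y|/2 - 1/(2a) + sqrt((|y|/2 + 1/(2a))^2 - lam/a))``.
    Accepts scalars or arrays.
    """
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if not a > 0:
        raise ValueError(f"a must be positive, got {a}")
    if not a < 1.0 / lam:
        raise ValueError(f"convexity violated: a={a} >= 1/lam={1.0 / lam}")
    y = np.asarray(y, dtype=np.float64)
    ay = np.abs(y)
    # radicand equals (lam/2 - 1/(2a))^2 at |y| = lam, so it is nonnegative
    # on the active branch; clip guards float round-off only
    rad = np.clip((ay / 2 + 0.5 / a) ** 2 - lam / a, 0.0, None)
    shrunk = ay / 2 - 0.5 / a + np.sqrt(rad)
    out = np.where(ay < lam, 0.0, np.sign(y) * np.maximum(shrunk, 0.0))
    return float(out) if out.ndim == 0 else out


def soft_threshold_spectrum(delta, lam: float):
    """Convex-relaxation baseline: ``max(delta - lam, 0)`` element-wise.
    Also the a -> 0+ limit of :func:`log_prox`."""
    delta = np.asarray(delta, dtype=np.float64)
    if not np.all(np.isfinite(delta)):
        raise ValueError("spectrum entries must be finite")
    return np.maximum(delta - lam, 0.0)


def shrink_spectrum(delta, params: ShrinkageParams):
    """Apply :func:`log_prox` to a nonincreasing spectrum and count the
    surviving entries.

    Returns ``(shrunk, rank)`` where ``rank`` is the number of strictly
    positive shrunk values, floored at 1 so a group never vanishes entirely
    (the leading singular vector carries the group mean).
    """
    delta = np.asarray(delta, dtype=np.float64)
    if delta.ndim != 1:
        raise ValueError("spectrum must be a vector")
    if np.any(delta < 0):
        raise ValueError("spectrum entries must be nonnegative")
    if np.any(np.diff(delta) > 0):
        raise ValueError("spectrum must be nonincreasing")
    shrunk = log_prox(delta, params.lam, params.a)
    rank = max(int(np.count_nonzero(shrunk > 0)), 1)
    return shrunk, rank


def estimate_truncation(group, params: ShrinkageParams) -> HOSVDFactors:
    """Truncated HOSVD of a cube group with per-mode adaptive ranks.

    For each mode the rank is the number of singular values surviving the
    log-penalty threshold; the factor keeps the first ``r_n`` left singular
    vectors.  Spectra are stored untruncated for diagnostics.
    """
    arr = _as_tensor4(group)
    factors, spectra, ranks = [], [], []
    for mode in _VALID_MODES:
        try:
            u, s, _ = np.linalg.svd(unfold(arr, mode), full_matrices=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"SVD failed on mode {mode}") from exc
        _, rank = shrink_spectrum(s, params)
        factors.append(_fix_signs(u)[:, :rank])
        spectra.append(s)
        ranks.append(rank)
    core = arr
    for mode, u in zip(_VALID_MODES, factors):
        core = mode_product(core, u.T, mode)
    return HOSVDFactors(core=core, factors=factors, spectra=spectra, ranks=tuple(ranks))


def denoise_group(group, params: ShrinkageParams) -> np.ndarray:
    """Project a cube group onto its truncated multilinear subspace."""
    return reconstruct(estimate_truncation(group, params))
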