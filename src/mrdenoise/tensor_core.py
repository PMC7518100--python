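"""Tensor algebra primitives for fourth-order tensors.

Provides mode-n unfolding/folding, the n-mode matrix product, and the full
(untruncated) higher-order SVD.  Modes are labelled 1..4 in the public API;
indexing is 0-based internally.

Unfolding convention: in the mode-n unfolding the row index is the mode-n
index and the columns enumerate the remaining indices with the
lowest-numbered remaining index varying fastest.  Any consistent convention
yields the same singular values and reconstructions; this one is fixed so
that factor matrices are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HOSVDFactors",
    "unfold",
    "fold",
    "mode_product",
    "hosvd",
    "reconstruct",
]

_VALID_MODES = (1, 2, 3, 4)


def _check_mode(mode: int) -> int:
    if mode not in _VALID_MODES:
        raise ValueError(f"mode must be one of {_VALID_MODES}, got {mode!r}")
    return mode - 1


def _as_tensor4(t) -> np.ndarray:
    arr = np.asarray(t, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError(f"expected a 4-way array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("tensor entries must be finite")
    return arr


def unfold(t, mode: int) -> np.ndarray:
    """Mode-n matricization of a fourth-order tensor.

    Returns a matrix of shape ``(J_mode, prod of remaining dims)``.  Columns
    enumerate mode-n fibers with the lowest-numbered remaining index varying
    fastest.
    """
    ax = _check_mode(mode)
    arr = _as_tensor4(t)
    return np.moveaxis(arr, ax, 0).reshape(arr.shape[ax], -1, order="F")


def fold(m, mode: int, shape) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the tensor of ``shape`` from its
    mode-n unfolding."""
    ax = _check_mode(mode)
    shape = tuple(int(s) for s in shape)
    if len(shape) != 4:
        raise ValueError(f"shape must have 4 entries, got {shape}")
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("mode matrix must be 2-D")
    rest = tuple(s for i, s in enumerate(shape) if i != ax)
    if m.shape[0] != shape[ax] or m.shape[1] != int(np.prod(rest)):
        raise ValueError(
            f"matrix shape {m.shape} inconsistent with tensor shape {shape} "
            f"at mode {mode}"
        )
    arr = m.reshape((shape[ax],) + rest, order="F")
    return np.moveaxis(arr, 0, ax)


def mode_product(t, v, mode: int) -> np.ndarray:
    """n-mode product: multiply ``t`` along ``mode`` by the matrix ``v``
    (shape K x J_mode); the mode dimension is replaced by K."""
    ax = _check_mode(mode)
    arr = _as_tensor4(t)
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError("v must be a matrix")
    if v.shape[1] != arr.shape[ax]:
        raise ValueError(
            f"matrix has {v.shape[1]} columns but tensor mode {mode} has "
            f"size {arr.shape[ax]}"
        )
    new_shape = list(arr.shape)
    new_shape[ax] = v.shape[0]
    return fold(v @ unfold(arr, mode), mode, new_shape)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive (ties
    broken by lowest index, which is what argmax returns)."""
    u = u.copy()
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


@dataclass
class HOSVDFactors:
    """Tucker factorization of a fourth-order tensor.

    ``core`` has shape ``ranks``; ``factors[n]`` is column-orthonormal of
    shape ``(J_n, ranks[n])``; ``spectra[n]`` holds the full (untruncated)
    singular values of the mode-(n+1) unfolding, nonincreasing.
    """

    core: np.ndarray
    factors: list = field(default_factory=list)
    spectra: list = field(default_factory=list)
    ranks: tuple = ()

    def __post_init__(self):
        self.ranks = tuple(int(r) for r in self.ranks)
        for n, (u, r) in enumerate(zip(self.factors, self.ranks)):
            if u.shape[1] != r or self.core.shape[n] != r:
                raise ValueError("ranks inconsistent with factors/core")
            if r < 1 or r > u.shape[0]:
                raise ValueError(f"rank {r} out of range for mode {n + 1}")


def hosvd(t) -> HOSVDFactors:
    """Full higher-order SVD: per-mode left singular vectors plus the core
    ``S = t x1 U1' x2 U2' x3 U3' x4 U4'``.

    The full-rank reconstruction reproduces ``t`` and the core preserves the
    Frobenius norm (orthogonal invariance).
    """
    arr = _as_tensor4(t)
    factors, spectra = [], []
    for mode in _VALID_MODES:
        u, s, _ = np.linalg.svd(unfold(arr, mode), full_matrices=False)
        factors.append(_fix_signs(u))
        spectra.append(s)
    core = arr
    for mode, u in zip(_VALID_MODES, factors):
        core = mode_product(core, u.T, mode)
    return HOSVDFactors(
        core=core,
        factors=factors,
        spectra=spectra,
        ranks=tuple(u.shape[1] for u in factors),
    )


def reconstruct(f: HOSVDFactors) -> np.ndarray:
    """Rebuild the tensor ``core x1 U1 x2 U2 x3 U3 x4 U4``."""
    out = f.core
    for mode, u in zip(_VALID_MODES, f.factors):
        out = mode_product(out, u, mode)
    return out
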