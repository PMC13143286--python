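"""Traceless-symmetric rank-p tensors in two dimensions.

A symmetric, fully traceless tensor of rank ``p`` in 2D has exactly two
independent components.  The package stores such objects as a single complex
scalar ``t`` per point, with the explicit tensor recovered as

    T = Re( conj(t) * u^{(x) p} ),      u = e_x + i e_y,

so that ``T[x,...,x] = Re t`` and ``T[x,...,x,y] = Im t`` and the Euclidean
norm is ``|T|^2 = 2^{p-1} |t|^2``.  The hexatic order tensor is
``Q6 = 4 |Psi6| [[n^{(x)6}]]`` whose complex representation is ``psi / 8``
(this normalisation is pinned by ``|Q6|^2 = |Psi6|^2 / 2``).

The explicit-array routines here (``sym``, ``project_traceless_symmetric``,
``contract_full`` ...) are deliberately brute force: they are the oracle that
fixes every contraction constant used by the fast complex-representation
paths elsewhere.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

__all__ = [
    "RankPTensor",
    "sym",
    "project_traceless_symmetric",
    "complex_to_tensor",
    "tensor_to_complex",
    "contract_full",
    "psi_to_Q6",
]


class RankPTensor:
    """Explicit rank-p tensor over 2D, with optional leading batch axes.

    ``components`` has shape ``batch + (2,) * p``.
    """

    def __init__(self, components: np.ndarray, p: int):
        components = np.asarray(components, dtype=float)
        if components.shape[-p:] != (2,) * p:
            raise ValueError(f"trailing axes must be {(2,) * p}")
        self.components = components
        self.p = p

    @property
    def batch_shape(self):
        return self.components.shape[: self.components.ndim - self.p]

    def __add__(self, other):
        return RankPTensor(self.components + other.components, self.p)

    def __sub__(self, other):
        return RankPTensor(self.components - other.components, self.p)

    def __mul__(self, a):
        return RankPTensor(self.components * a, self.p)

    __rmul__ = __mul__


def _tensor_axes(arr: np.ndarray, p: int) -> tuple[int, ...]:
    return tuple(range(arr.ndim - p, arr.ndim))


def sym(arr: np.ndarray, p: int) -> np.ndarray:
    """Symmetrise the trailing ``p`` axes by averaging over permutations."""
    axes = _tensor_axes(arr, p)
    lead = tuple(range(arr.ndim - p))
    out = np.zeros_like(arr)
    for perm in itertools.permutations(range(p)):
        out += np.transpose(arr, lead + tuple(axes[i] for i in perm))
    return out / math.factorial(p)


def _basis(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal basis (E1, E2) of the traceless-symmetric subspace."""
    u = np.array([1.0 + 0j, 0.0 + 1j])
    up = u
    for _ in range(p - 1):
        up = np.multiply.outer(up, u)
    return up.real.copy(), up.imag.copy()


def project_traceless_symmetric(t: RankPTensor) -> RankPTensor:
    """Orthogonal projection onto the traceless-symmetric subspace.

    This is the ``[[...]]`` operator of the hydrodynamic theory: linear,
    idempotent, and its image is two-dimensional per point for any p >= 2.
    """
    if t.p not in (2, 6):
        raise ValueError(f"unsupported tensor rank p={t.p}; expected 2 or 6")
    e1, e2 = _basis(t.p)
    norm = 2.0 ** (t.p - 1)
    axes = _tensor_axes(t.components, t.p)
    c1 = np.tensordot(t.components, e1, axes=(axes, tuple(range(t.p)))) / norm
    c2 = np.tensordot(t.components, e2, axes=(axes, tuple(range(t.p)))) / norm
    out = (np.multiply.outer(c1, e1) + np.multiply.outer(c2, e2))
    return RankPTensor(out, t.p)


def tensor_to_complex(t: RankPTensor) -> np.ndarray:
    """Complex representation of a traceless-symmetric tensor (or of the
    traceless-symmetric part of a general one)."""
    e1, e2 = _basis(t.p)
    norm = 2.0 ** (t.p - 1)
    axes = _tensor_axes(t.components, t.p)
    c1 = np.tensordot(t.components, e1, axes=(axes, tuple(range(t.p)))) / norm
    c2 = np.tensordot(t.components, e2, axes=(axes, tuple(range(t.p)))) / norm
    return c1 + 1j * c2


def complex_to_tensor(t: np.ndarray, p: int) -> RankPTensor:
    """Explicit tensor for complex representation ``t`` (batch allowed)."""
    e1, e2 = _basis(p)
    t = np.asarray(t)
    out = np.multiply.outer(t.real, e1) + np.multiply.outer(t.imag, e2)
    return RankPTensor(out, p)


def contract_full(a: RankPTensor, b: RankPTensor) -> np.ndarray:
    """Full contraction over all tensor indices (batchwise)."""
    if a.p != b.p:
        raise ValueError("rank mismatch")
    axes = _tensor_axes(a.components, a.p)
    bxes = _tensor_axes(b.components, b.p)
    if a.batch_shape != b.batch_shape:
        raise ValueError("batch shape mismatch")
    prod = a.components * b.components
    return prod.sum(axis=tuple(axes))


def psi_to_Q6(psi: np.ndarray) -> RankPTensor:
    """Hexatic order tensor ``Q6 = 4 |Psi6| [[n^{(x)6}]]`` as an explicit
    rank-6 tensor field (batch axes = field axes).

    The complex representation of the result is exactly ``psi / 8``; the
    inverse map ``8 * tensor_to_complex`` recovers ``(|Psi6|, 6 theta)``.
    """
    return complex_to_tensor(np.asarray(psi, dtype=complex) / 8.0, 6)
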