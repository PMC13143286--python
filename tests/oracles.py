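"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's complex-representation fast paths:
tensors are explicit numpy arrays, the traceless-symmetric projection is an
orthogonal projection onto an explicitly constructed constraint-satisfying
subspace, and contractions are plain tensordots.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def symmetrize(t: np.ndarray) -> np.ndarray:
    p = t.ndim
    out = np.zeros_like(t)
    for perm in itertools.permutations(range(p)):
        out += np.transpose(t, perm)
    return out / math.factorial(p)


def _ts_subspace_basis(p: int) -> np.ndarray:
    """Orthonormal basis (rows) of the symmetric fully-traceless subspace,
    built by projecting symmetrized coordinate tensors onto the null space
    of all trace constraints and Gram-Schmidt orthogonalising."""
    sym_basis = []
    seen = set()
    for idx in itertools.product((0, 1), repeat=p):
        key = tuple(sorted(idx))
        if key in seen:
            continue
        seen.add(key)
        e = np.zeros((2,) * p)
        e[idx] = 1.0
        sym_basis.append(symmetrize(e).ravel())
    cons = []
    for i, j in itertools.combinations(range(p), 2):
        for rest in itertools.product((0, 1), repeat=p - 2):
            row = np.zeros((2,) * p)
            for k in (0, 1):
                idx = list(rest)
                idx.insert(min(i, j), k)
                idx.insert(max(i, j), k)
                row[tuple(idx)] += 1.0
            cons.append(row.ravel())
    A = np.asarray(cons).T
    u, sv, _ = np.linalg.svd(A, full_matrices=False)
    q = u[:, sv > 1e-10 * sv.max()]
    basis = []
    for b in sym_basis:
        v = b - q @ (q.T @ b)
        for u in basis:
            v = v - u * (u @ v)
        n = np.linalg.norm(v)
        if n > 1e-10:
            basis.append(v / n)
    return np.asarray(basis)


def project_ts_oracle(t: np.ndarray) -> np.ndarray:
    """Orthogonal projection of an explicit tensor onto the traceless
    symmetric subspace (the nearest such tensor in Frobenius norm)."""
    p = t.ndim
    B = _ts_subspace_basis(p)
    flat = t.ravel()
    return (B.T @ (B @ flat)).reshape((2,) * p)


def contract_keep_one(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """(t1 . t2)_{ij} = t1[i, k1..k5] t2[k1..k5, j]: contract all but one
    index of each rank-p factor."""
    p = t1.ndim
    return np.tensordot(t1, t2, axes=(tuple(range(1, p)), tuple(range(p - 1))))


def contract_full(t1: np.ndarray, t2: np.ndarray) -> float:
    return float((t1 * t2).sum())
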