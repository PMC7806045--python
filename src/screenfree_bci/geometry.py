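"""Riemannian geometry of symmetric positive-definite (SPD) matrices.

Window covariances of EEG epochs live in the SPD cone.  Under the
affine-invariant Riemannian metric (AIRM) the cone is a complete manifold
on which distances are invariant to congruence transforms ``C -> A C A^T``
-- exactly the invariance one wants for covariances of linearly mixed
signals.  This module provides the primitives the decoding pipelines are
built from: matrix square roots and logarithms via eigendecomposition, the
AIRM distance, log/exp maps, the Fréchet (geometric) mean by fixed-point
tangent averaging, parallel transport to the identity, and the isometric
vectorization of tangent-space matrices.

All functions validate SPD-ness explicitly: shrinkage upstream guarantees
positive definiteness, so a degenerate matrix reaching this layer signals a
pipeline bug rather than something to clip silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TangentVector",
    "validate_spd",
    "spd_sqrt_invsqrt",
    "spd_logm",
    "spd_expm",
    "airm_distance",
    "frechet_mean",
    "log_map",
    "exp_map",
    "transport_to_identity",
    "tangent_vectorize",
    "tangent_unvectorize",
]

# eigenvalues below RCOND * lambda_max are treated as numerically zero
_RCOND = 1e-12
_SYM_RTOL = 1e-10


@dataclass(frozen=True)
class TangentVector:
    """A tangent-space element in matrix and vector form.

    ``vector_form`` uses the isometric (sqrt-2-weighted) vectorization, so
    its Euclidean norm equals the Frobenius norm of ``matrix_form``.
    """

    matrix_form: np.ndarray
    vector_form: np.ndarray


def _check_symmetric(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name} must be square, got shape {C.shape}")
    scale = max(np.abs(C).max(), 1.0)
    if not np.allclose(C, C.T, rtol=0.0, atol=_SYM_RTOL * scale):
        raise ValueError(f"{name} is not symmetric within tolerance")
    return 0.5 * (C + C.T)


def validate_spd(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate symmetry and positive definiteness; return symmetrized copy."""
    C = _check_symmetric(C, name)
    eigvals = np.linalg.eigvalsh(C)
    if eigvals[0] <= _RCOND * max(eigvals[-1], 0.0) or eigvals[0] <= 0.0:
        raise ValueError(
            f"{name} is not positive definite (smallest eigenvalue "
            f"{eigvals[0]:.3e}); apply shrinkage upstream"
        )
    return C


def _eig_fun(C: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, Q = np.linalg.eigh(C)
    return (Q * fun(w)) @ Q.T


def spd_sqrt_invsqrt(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(C^{1/2}, C^{-1/2})`` of an SPD matrix via eigendecomposition."""
    C = validate_spd(C, "C")
    w, Q = np.linalg.eigh(C)
    sqrt_w = np.sqrt(w)
    return (Q * sqrt_w) @ Q.T, (Q / sqrt_w) @ Q.T


def spd_logm(C: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric output)."""
    return _eig_fun(validate_spd(C, "C"), np.log)


def spd_expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD output)."""
    return _eig_fun(_check_symmetric(S, "S"), np.exp)


def airm_distance(C1: np.ndarray, C2: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    ``d(C1, C2) = || logm(C1^{-1/2} C2 C1^{-1/2}) ||_F``.
    """
    C1 = validate_spd(C1, "C1")
    C2 = validate_spd(C2, "C2")
    if C1.shape != C2.shape:
        raise ValueError(f"side mismatch: {C1.shape} vs {C2.shape}")
    _, inv_sqrt = spd_sqrt_invsqrt(C1)
    middle = inv_sqrt @ C2 @ inv_sqrt
    w = np.linalg.eigvalsh(0.5 * (middle + middle.T))
    return float(np.linalg.norm(np.log(w)))


def log_map(C: np.ndarray, Cref: np.ndarray) -> TangentVector:
    """Map an SPD matrix into the tangent space at ``Cref``.

    Returns ``logm(Cref^{-1/2} C Cref^{-1/2})`` in matrix and vector form.
    """
    C = validate_spd(C, "C")
    _, inv_sqrt = spd_sqrt_invsqrt(Cref)
    if C.shape != Cref.shape:
        raise ValueError(f"side mismatch: {C.shape} vs {np.shape(Cref)}")
    middle = inv_sqrt @ C @ inv_sqrt
    S = _eig_fun(0.5 * (middle + middle.T), np.log)
    return TangentVector(matrix_form=S, vector_form=tangent_vectorize(S))


def exp_map(S: np.ndarray | TangentVector, Cref: np.ndarray) -> np.ndarray:
    """Inverse of :func:`log_map` at the same reference point."""
    if isinstance(S, TangentVector):
        S = S.matrix_form
    S = _check_symmetric(S, "S")
    sqrt, _ = spd_sqrt_invsqrt(Cref)
    return sqrt @ spd_expm(S) @ sqrt


def frechet_mean(
    Cs, tol: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """Fréchet mean of SPD matrices under the AIRM.

    Fixed-point iteration: map to the tangent space at the current
    estimate, average, map back (step size 1) until the Frobenius norm of
    the mean tangent falls below ``tol``.  Initialized at the arithmetic
    mean.  On non-convergence a warning reports the final residual and the
    last iterate is returned.
    """
    Cs = [validate_spd(C, f"Cs[{i}]") for i, C in enumerate(Cs)]
    if len(Cs) == 0:
        raise ValueError("frechet_mean requires a non-empty list")
    sides = {C.shape[0] for C in Cs}
    if len(sides) != 1:
        raise ValueError(f"inconsistent matrix sides: {sorted(sides)}")
    stack = np.stack(Cs)
    M = stack.mean(axis=0)
    for _ in range(max_iter):
        sqrt, inv_sqrt = spd_sqrt_invsqrt(M)
        whitened = np.einsum("ij,kjl,lm->kim", inv_sqrt, stack, inv_sqrt)
        whitened = 0.5 * (whitened + whitened.transpose(0, 2, 1))
        w, Q = np.linalg.eigh(whitened)
        logs = np.einsum("kij,kj,klj->kil", Q, np.log(w), Q)
        mean_tangent = logs.mean(axis=0)
        residual = np.linalg.norm(mean_tangent)
        if residual < tol:
            return M
        M = sqrt @ spd_expm(mean_tangent) @ sqrt
        M = 0.5 * (M + M.T)
    warnings.warn(
        f"Fréchet mean did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})",
        RuntimeWarning,
        stacklevel=2,
    )
    return M


def transport_to_identity(Cs, Cm: np.ndarray) -> list[np.ndarray]:
    """Parallel-transport SPD matrices along the geodesic from ``Cm`` to I.

    Each ``C`` is replaced by ``Cm^{-1/2} C Cm^{-1/2}``.  If ``Cm`` is the
    Fréchet mean of the set, the transported set has Fréchet mean I.  The
    congruence preserves all pairwise AIRM distances.
    """
    _, inv_sqrt = spd_sqrt_invsqrt(Cm)
    out = []
    for i, C in enumerate(Cs):
        C = validate_spd(C, f"Cs[{i}]")
        if C.shape != inv_sqrt.shape:
            raise ValueError(f"side mismatch at index {i}")
        T = inv_sqrt @ C @ inv_sqrt
        out.append(0.5 * (T + T.T))
    return out


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def tangent_vectorize(S: np.ndarray) -> np.ndarray:
    """Isometric vectorization of a symmetric matrix.

    Ordering is fixed for serialization stability: the n diagonal entries
    first, then the upper triangle row-major, each off-diagonal scaled by
    sqrt(2) so that the Euclidean norm of the vector equals the Frobenius
    norm of the matrix.
    """
    S = _check_symmetric(S, "S")
    iu, ju = _triu_indices(S.shape[0])
    return np.concatenate([np.diag(S), np.sqrt(2.0) * S[iu, ju]])


def tangent_unvectorize(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_vectorize`."""
    v = np.asarray(v, dtype=float)
    m = v.shape[0]
    n = int(round((np.sqrt(8 * m + 1) - 1) / 2))
    if n * (n + 1) // 2 != m:
        raise ValueError(f"vector length {m} is not n(n+1)/2 for integer n")
    S = np.diag(v[:n]).astype(float)
    iu, ju = _triu_indices(n)
    off = v[n:] / np.sqrt(2.0)
    S[iu, ju] = off
    S[ju, iu] = off
    return S
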