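"""Numerically stable least-squares solvers.

The force model is fitted by minimising ||Ax - b||^2. For a full-column-rank
design the solution is obtained from the economy QR factorisation (a
triangular solve; the normal-equation product (A^T A)^{-1} is never formed,
because its condition number is the *square* of the design's). For a
rank-deficient design the minimum-norm solution is returned via the SVD
pseudo-inverse, taking reciprocals only of singular values above the
conventional tolerance ``max(N, m) * sigma_max * eps``.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

from .signals import DataError

__all__ = ["solve_least_squares", "lstsq_info", "condition_number", "svd_rank"]


def _check_system(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2 or A.size == 0 or b.size == 0:
        raise DataError("empty least-squares system")
    if A.shape[0] != b.shape[0]:
        raise DataError(f"A has {A.shape[0]} rows but b has {b.shape[0]} entries")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise DataError("least-squares system contains non-finite entries")
    return A, b


def svd_rank(s: np.ndarray, shape: tuple[int, int]) -> tuple[int, float]:
    """Numerical rank from singular values with the conventional
    pseudo-inverse tolerance; returns (rank, tolerance)."""
    if s.size == 0:
        return 0, 0.0
    tol = max(shape) * s[0] * np.finfo(float).eps
    return int(np.sum(s > tol)), tol


def lstsq_info(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, str, float]:
    """Solve min ||Ax - b||^2; return (x, solver_path, condition_number).

    solver_path is "normal-solve" (QR route, full column rank) or
    "pseudo-inverse" (SVD minimum-norm route, rank deficient).
    """
    A, b = _check_system(A, b)
    U, s, Vt = sla.svd(A, full_matrices=False)
    rank, _ = svd_rank(s, A.shape)
    m = A.shape[1]
    cond = float(s[0] / s[-1]) if (rank == m and s[-1] > 0) else float("inf")
    if rank == m:
        # Full column rank: economy QR + triangular back-substitution.
        Q, R = sla.qr(A, mode="economic")
        x = sla.solve_triangular(R, Q.T @ b)
        return x, "normal-solve", cond
    # Rank-deficient: minimum-norm solution from the SVD already computed.
    s_inv = np.zeros_like(s)
    nz = s > (max(A.shape) * s[0] * np.finfo(float).eps if s.size else 0.0)
    s_inv[nz] = 1.0 / s[nz]
    x = Vt.T @ (s_inv * (U.T @ b))
    return x, "pseudo-inverse", cond


def solve_least_squares(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least-squares solution of Ax = b (minimum-norm when rank deficient)."""
    x, _, _ = lstsq_info(A, b)
    return x


def condition_number(A: np.ndarray) -> float:
    """Ratio of the largest to the smallest singular value of A.

    Equals sqrt(lambda_max / lambda_min) of A^T A — the reason the solvers
    above work on A directly rather than on the normal equations. Infinite
    for rank-deficient matrices.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise DataError("condition number of an empty matrix is undefined")
    s = sla.svdvals(A)
    rank, _ = svd_rank(s, A.shape)
    if rank < min(A.shape) or s[-1] == 0:
        return float("inf")
    return float(s[0] / s[-1])
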