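"""Unconstrained parameterizations used by the samplers.

Correlation matrices are parameterized through canonical partial
correlations (CPCs): an unconstrained vector ``x`` maps through
``z = tanh(x)`` to CPCs in (-1, 1), which build a Cholesky factor ``L``
of a correlation matrix row by row.  Under an LKJ(eta) prior the CPCs
are independent with density proportional to ``(1 - z^2)^(b - 1)``,
``b = eta + (d - 1 - lag) / 2`` where ``lag = i - j`` for the entry in
row i, column j (0-based, i > j) -- the C-vine construction of
Lewandowski, Kurowicka & Joe.  All gradients here are hand-coded and
checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_cpc",
    "chol_from_cpc",
    "chol_from_cpc_backward",
    "lkj_cpc_exponents",
    "corr_from_cpc",
]


def n_cpc(dim: int) -> int:
    """Number of partial-correlation parameters for a dim x dim matrix."""
    return dim * (dim - 1) // 2


def lkj_cpc_exponents(dim: int, eta: float = 1.0) -> np.ndarray:
    """Beta-type exponents b for each CPC under LKJ(eta).

    Order matches :func:`chol_from_cpc`: row-major over (i, j), i > j.
    """
    b = np.empty(n_cpc(dim))
    k = 0
    for i in range(1, dim):
        for j in range(i):
            b[k] = eta + (dim - 1 - (i - j)) / 2.0
            k += 1
    return b


def chol_from_cpc(z: np.ndarray, dim: int) -> np.ndarray:
    """Build the Cholesky factor of a correlation matrix from CPCs.

    Row construction: L[i, j] = z_ij * sqrt(1 - sum_{k<j} L[i, k]^2),
    diagonal completes each row to unit norm.  Rows are independent.
    """
    if dim == 2:  # closed form for the ubiquitous 2x2 block
        z0 = float(z[0])
        return np.array([[1.0, 0.0], [z0, np.sqrt(1.0 - z0 * z0)]])
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, dim):
        s = 0.0  # accumulated squared norm of row i
        for j in range(i):
            L[i, j] = z[k] * np.sqrt(1.0 - s)
            s += L[i, j] ** 2
            k += 1
        L[i, i] = np.sqrt(max(1.0 - s, 0.0))
    return L


def chol_from_cpc_backward(z: np.ndarray, dim: int, dL: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`chol_from_cpc`: gradient w.r.t. the CPC vector.

    ``dL`` is the gradient of the objective w.r.t. every entry of L
    (lower triangle including the diagonal).
    """
    if dim == 2:
        z0 = float(z[0])
        w = np.sqrt(1.0 - z0 * z0)
        # L = [[1, 0], [z, w]]: dL[1,0] direct, dL[1,1] via dw/dz = -z/w
        return np.array([dL[1, 0] - dL[1, 1] * z0 / w])
    dz = np.zeros_like(z)
    # Recompute forward per row, then reverse through the recurrence.
    offs = np.concatenate(([0], np.cumsum(np.arange(dim))))  # row k offsets
    for i in range(1, dim):
        k0 = offs[i]
        zi = z[k0 : k0 + i]
        Li = np.zeros(i + 1)
        svals = np.zeros(i + 1)  # s before processing column j
        s = 0.0
        for j in range(i):
            svals[j] = s
            Li[j] = zi[j] * np.sqrt(1.0 - s)
            s += Li[j] ** 2
        svals[i] = s
        Li[i] = np.sqrt(max(1.0 - s, 0.0))
        # reverse pass: ds accumulates gradient w.r.t. the running s
        ds = 0.0
        if Li[i] > 0.0:
            ds += dL[i, i] * (-0.5 / Li[i])
        for j in range(i - 1, -1, -1):
            dLij = dL[i, j] + ds * 2.0 * Li[j]
            root = np.sqrt(1.0 - svals[j])
            dz[k0 + j] = dLij * root
            ds += dLij * zi[j] * (-0.5 / root) if root > 0.0 else 0.0
    return dz


def corr_from_cpc(z: np.ndarray, dim: int) -> np.ndarray:
    """Full correlation matrix R = L L^T from CPCs."""
    L = chol_from_cpc(z, dim)
    return L @ L.T
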