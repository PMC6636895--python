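"""Proximal and projection operators for the ADMM solver.

The one nonstandard operator here is :func:`prox_stacked_nuclear_psd`: the
proximal operator of the stacked nuclear norm ``t ||L||_*`` subject to the top
p x p block of L being symmetric PSD.  It has no closed form; it is computed by
a Dykstra-style proximal scheme alternating singular-value soft-thresholding
with PSD projection of the top block, with the usual correction terms.  In
practice a handful of inner iterations suffice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProxResult",
    "prox_l1",
    "svd_soft_threshold",
    "prox_stacked_nuclear_psd",
    "project_psd",
]


@dataclass
class ProxResult:
    value: np.ndarray
    inner_iterations: int
    inner_residual: float
    converged: bool = True


def prox_l1(M: np.ndarray, t, mask: np.ndarray | None = None) -> np.ndarray:
    """Elementwise soft-thresholding sign(M) max(|M|-t, 0).

    ``t`` may be a scalar or an array broadcastable to M.  ``mask`` (binary,
    optional) marks entries that are NOT penalized; they pass through.
    """
    M = np.asarray(M, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("threshold t must be nonnegative")
    if mask is not None:
        t = np.where(np.asarray(mask, dtype=bool), 0.0, t)
    return np.sign(M) * np.maximum(np.abs(M) - t, 0.0)


def svd_soft_threshold(M: np.ndarray, t: float) -> np.ndarray:
    """Singular-value soft-thresholding: prox of t ||.||_* (unconstrained)."""
    if t < 0:
        raise ValueError("threshold t must be nonnegative")
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return M.copy()
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    return (u * s) @ vt


def project_psd(M: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Nearest (Frobenius) symmetric matrix with eigenvalues >= floor."""
    M = 0.5 * (M + M.T)
    if M.size == 0:
        return M
    w, v = np.linalg.eigh(M)
    if w[0] >= floor:
        return M
    return (v * np.maximum(w, floor)) @ v.T


def prox_stacked_nuclear_psd(
    M: np.ndarray,
    t: float,
    p: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProxResult:
    """argmin_L 0.5||L - M||_F^2 + t ||L||_*  s.t. the top p x p block of L is
    symmetric PSD.

    Dykstra-like proximal algorithm for the sum of the nuclear-norm prox and
    the PSD-block projection (both firmly nonexpansive); the two auxiliary
    correction terms make the alternation converge to the prox of the sum
    rather than to a naive alternation fixed point.
    """
    if t < 0:
        raise ValueError("threshold t must be nonnegative")
    M = np.asarray(M, dtype=float).copy()
    if p:
        M[:p] = 0.5 * (M[:p] + M[:p].T)  # symmetrize top block on entry

    def proj_block(A):
        if p == 0:
            return A
        out = A.copy()
        out[:p] = project_psd(A[:p])
        return out

    x = M.copy()
    pcorr = np.zeros_like(M)
    qcorr = np.zeros_like(M)
    scale = max(1.0, float(np.linalg.norm(M)))
    res = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        y = svd_soft_threshold(x + pcorr, t)
        pcorr = x + pcorr - y
        x = proj_block(y + qcorr)
        qcorr = y + qcorr - x
        res = float(np.linalg.norm(x - y)) / scale
        if res <= tol:
            break
    return ProxResult(
        value=x, inner_iterations=it, inner_residual=res, converged=res <= tol
    )
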