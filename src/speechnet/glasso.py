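"""Graphical lasso: L1-penalized sparse precision-matrix estimation.

Solves

    minimize_K  -log det K + tr(S K) + lambda * sum_{i != j} |K_ij|

over positive-definite K, with the diagonal unpenalized (the convention of
the psychometric-network literature, which also makes the p = 2 solution an
exact soft-threshold of the off-diagonal correlation). The solver is ADMM
with an eigendecomposition-based proximal step; kernels are numba-compiled
because permutation and bootstrap procedures re-estimate the model tens of
thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso_fit", "glasso_path", "GlassoNonConvergence"]


class GlassoNonConvergence(RuntimeError):
    pass


@njit(cache=True)
def _soft_offdiag(T, thr, out):
    p = T.shape[0]
    for i in range(p):
        for j in range(p):
            if i == j:
                out[i, j] = T[i, j]
            else:
                v = T[i, j]
                if v > thr:
                    out[i, j] = v - thr
                elif v < -thr:
                    out[i, j] = v + thr
                else:
                    out[i, j] = 0.0


@njit(cache=True)
def _admm(S, lam, rho, tol, max_iter, Z, U):
    """ADMM iterations; Z and U are warm-start state, updated in place.

    The penalty parameter rho is adapted by residual balancing (with the
    scaled dual U rescaled accordingly), which keeps convergence fast on
    ill-conditioned inputs such as eigenvalue-clipped rank-deficient
    correlation matrices.

    Returns (Z, U, K, iterations, converged, rho). Z carries exact zeros.
    """
    p = S.shape[0]
    K = np.empty((p, p))
    Znew = np.empty((p, p))
    it = 0
    converged = False
    for it in range(max_iter):
        A = rho * (Z - U) - S
        A = 0.5 * (A + A.T)
        w, V = np.linalg.eigh(A)
        d = (w + np.sqrt(w * w + 4.0 * rho)) / (2.0 * rho)
        K = (V * d) @ V.T
        _soft_offdiag(K + U, lam / rho, Znew)
        # residuals (Frobenius, normalized by p)
        pr = 0.0
        dr = 0.0
        for i in range(p):
            for j in range(p):
                pr += (K[i, j] - Znew[i, j]) ** 2
                dr += (Znew[i, j] - Z[i, j]) ** 2
        pr = np.sqrt(pr) / p
        dr = rho * np.sqrt(dr) / p
        for i in range(p):
            for j in range(p):
                Z[i, j] = Znew[i, j]
                U[i, j] = U[i, j] + K[i, j] - Z[i, j]
        if pr < tol and dr < tol:
            converged = True
            break
        if (it + 1) % 10 == 0:
            if pr > 10.0 * dr and rho < 1e6:
                rho *= 2.0
                for i in range(p):
                    for j in range(p):
                        U[i, j] *= 0.5
            elif dr > 10.0 * pr and rho > 1e-6:
                rho *= 0.5
                for i in range(p):
                    for j in range(p):
                        U[i, j] *= 2.0
    return Z, U, K, it + 1, converged, rho


@njit(cache=True)
def _path_kernel(S, n, gamma, lambdas, rho, tol, max_iter):
    """EBIC over a descending lambda path with warm starts.

    Returns (precisions, ebics, edge_counts, logliks, converged_flags).
    EBIC_gamma = -2*l(K) + E*log(n) + 4*gamma*E*log(p) with
    l(K) = (n/2)(log det K - tr(S K)) and E the nonzero off-diagonal pairs.
    """
    p = S.shape[0]
    L = lambdas.size
    Zs = np.empty((L, p, p))
    ebics = np.empty(L)
    edges = np.zeros(L, dtype=np.int64)
    lls = np.empty(L)
    ok = np.zeros(L, dtype=np.bool_)
    Z = np.eye(p)
    U = np.zeros((p, p))
    for li in range(L):
        Z, U, K, _, conv, rho = _admm(S, lambdas[li], rho, tol, max_iter, Z, U)
        ok[li] = conv
        Zs[li] = 0.5 * (Z + Z.T)
        E = 0
        for i in range(p):
            for j in range(i + 1, p):
                if Zs[li, i, j] != 0.0:
                    E += 1
        edges[li] = E
        w = np.linalg.eigvalsh(Zs[li])
        if w[0] <= 0.0:
            # soft-threshold step left a non-PD iterate; use K's spectrum
            w = np.linalg.eigvalsh(K)
        logdet = 0.0
        for i in range(p):
            logdet += np.log(w[i])
        tr = 0.0
        for i in range(p):
            for j in range(p):
                tr += S[i, j] * Zs[li, j, i]
        ll = 0.5 * n * (logdet - tr)
        lls[li] = ll
        ebics[li] = -2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p)
    return Zs, ebics, edges, lls, ok


def _duality_gap(S, Z, lam):
    return float(np.trace(S @ Z) + lam * np.sum(np.abs(Z - np.diag(np.diag(Z))))
                 - S.shape[0])


def glasso_fit(S: np.ndarray, lam: float, rho: float = 1.0, tol: float = 1e-8,
               max_iter: int = 10000) -> np.ndarray:
    """Single graphical-lasso fit; returns the sparse precision matrix.

    ``lam = 0`` returns ``inv(S)`` exactly; ``lam`` at or above the largest
    absolute off-diagonal of S gives a diagonal precision (empty graph).
    Raises :class:`GlassoNonConvergence` with the duality gap if the
    iteration budget is exhausted.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return np.linalg.inv(S)
    Z = np.eye(S.shape[0])
    U = np.zeros_like(S)
    Z, U, K, n_iter, conv, rho = _admm(S, lam, rho, tol, max_iter, Z, U)
    if not conv:
        raise GlassoNonConvergence(
            f"glasso did not converge in {max_iter} ADMM iterations "
            f"(duality gap {_duality_gap(S, 0.5 * (Z + Z.T), lam):.3e})")
    return 0.5 * (Z + Z.T)


def glasso_path(S: np.ndarray, n: int, gamma: float, lambdas: np.ndarray,
                rho: float = 1.0, tol: float = 1e-7, max_iter: int = 5000):
    """Warm-started fits along a descending lambda path with EBIC scores."""
    lambdas = np.asarray(lambdas, dtype=float)
    Zs, ebics, edges, lls, ok = _path_kernel(
        np.ascontiguousarray(S, dtype=float), float(n), float(gamma),
        lambdas, rho, tol, max_iter)
    if not ok.all():
        bad = int(np.flatnonzero(~ok)[0])
        raise GlassoNonConvergence(
            f"glasso path failed to converge at lambda={lambdas[bad]:.4g} "
            f"(gap {_duality_gap(S, Zs[bad], lambdas[bad]):.3e})")
    return Zs, ebics, edges, lls
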