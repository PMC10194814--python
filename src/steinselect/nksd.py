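"""Normalized kernelized Stein discrepancy (NKSD): estimators and oracles.

The NKSD between a data density ``p`` and a model density ``q`` is the
standard kernelized Stein discrepancy divided by ``E[k(X, Y)]`` under ``p``,
which makes the value comparable across data spaces of different dimension.
It is estimated by the ratio of two U-statistics over the ``i != j`` pairs,

    NKSD_hat = sum_{i != j} u(X_i, X_j) / sum_{i != j} k(X_i, X_j),

with the Stein u-function

    u(x, y) = s_q(x)' s_q(y) k(x, y) + s_q(x)' grad_y k + s_q(y)' grad_x k
              + tr(grad_x grad_y' k),

where ``s_q(x) = grad_x log q(x)`` is the Stein score of the model.  Additive
constants in ``log q`` drop out of ``s_q``, so unnormalized (energy-based)
models are handled exactly like normalized ones.

Score functions here are batch callables: ``score(X) -> S`` maps an ``(n, d)``
array of points to the ``(n, d)`` array of score vectors.

For models whose score is affine in the observation, ``s(x) = W x + m``
(Gaussian location families, probabilistic PCA), :class:`LinearScoreMoments`
precomputes the pairwise kernel sums once in O(N^2 d) so that each subsequent
NKSD evaluation costs only O(d^3).  This is what makes minimum-NKSD fitting
and leave-one-out scans fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kernels import KernelSpec, _block_views, _profile, _require_resolved, _sqdist

__all__ = [
    "NKSDEstimate",
    "stein_u_term",
    "nksd_ustat",
    "nksd_population_mc",
    "expfam_quadratic",
    "LinearScoreMoments",
]

ScoreFunction = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class NKSDEstimate:
    """U-statistic estimate of the NKSD with its raw numerator/denominator."""

    value: float
    numerator: float
    denominator: float
    n: int


def _kernel_chunks(Xc, X, spec: KernelSpec, offset: int):
    """Kernel pair terms for a chunk of rows against the full data.

    Returns ``(K, trace, wlist)`` where ``K`` is the kernel matrix,
    ``trace`` the mixed-derivative trace matrix, and ``wlist`` holds, per
    kernel block, the weight matrix ``W_b = (k / k_b) * 2 f_b'(r2)`` such that
    ``grad_x k`` restricted to block coordinates is ``W_b * (x_b - y_b)``.
    Entries on the global diagonal (chunk row i equals column offset+i) are
    zeroed in all returned matrices, implementing the ``i != j`` convention.
    """
    h = _require_resolved(spec)
    idx_list = _block_views(spec, X.shape[1])
    h2 = h * h
    if len(idx_list) == 1 and spec.family == "rbf":
        # fused fast path: K = exp(-r2/2h^2), W = -K/h^2,
        # trace = K d/h^2 - K r2 / h^4
        d = X.shape[1]
        r2 = _sqdist(Xc, X)
        K = np.exp(r2 * (-0.5 / h2))
        trace = K * r2
        trace *= -1.0 / (h2 * h2)
        trace += K * (d / h2)
        wlist = [K * (-1.0 / h2)]
    else:
        fs, fps, fpps, r2s = [], [], [], []
        for idx in idx_list:
            r2 = _sqdist(Xc[:, idx], X[:, idx])
            f, fp, fpp = _profile(spec.family, r2, h)
            fs.append(f)
            fps.append(fp)
            fpps.append(fpp)
            r2s.append(r2)
        K = fs[0].copy()
        for f in fs[1:]:
            K *= f
        trace = np.zeros_like(K)
        wlist = []
        for idx, f, fp, fpp, r2 in zip(idx_list, fs, fps, fpps, r2s):
            rest = K / f
            trace += rest * (-2.0 * idx.size * fp - 4.0 * r2 * fpp)
            wlist.append(rest * 2.0 * fp)
    nc = Xc.shape[0]
    rows = np.arange(nc)
    cols = offset + rows
    valid = cols < K.shape[1]
    K[rows[valid], cols[valid]] = 0.0
    trace[rows[valid], cols[valid]] = 0.0
    for w in wlist:
        w[rows[valid], cols[valid]] = 0.0
    return K, trace, wlist


def _iter_chunks(n: int, chunk: int):
    for s in range(0, n, chunk):
        yield s, min(s + chunk, n)


def stein_u_term(x, y, score: ScoreFunction, spec: KernelSpec) -> float:
    """The Stein u-function for one pair of points; symmetric in (x, y)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    from .kernels import kernel_derivatives, kernel_eval

    sx = np.asarray(score(x[None, :]), dtype=float).ravel()
    sy = np.asarray(score(y[None, :]), dtype=float).ravel()
    if not (np.all(np.isfinite(sx)) and np.all(np.isfinite(sy))):
        raise ValueError("score function returned non-finite values")
    k = kernel_eval(x, y, spec)
    gx, gy, tr = kernel_derivatives(x, y, spec)
    return float(sx @ sy * k + sx @ gy + sy @ gx + tr)


def nksd_ustat(
    X: np.ndarray,
    score: ScoreFunction,
    spec: KernelSpec,
    *,
    chunk: int = 512,
    dtype=None,
) -> NKSDEstimate:
    """U-statistic NKSD estimate over all ``i != j`` pairs.

    Accumulation is blocked over row chunks (result is independent of the
    chunk size) with chunk totals combined by compensated summation.
    ``dtype=np.float32`` trades the last ~7 significant digits of each pair
    term for a large speedup on big N; totals are always accumulated in
    float64.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty data matrix")
    if n == 1:
        warnings.warn("NKSD of a single observation is 0 by convention", stacklevel=2)
        return NKSDEstimate(0.0, 0.0, 0.0, 1)

    S = np.asarray(score(X), dtype=float)
    if S.shape != X.shape:
        raise ValueError(f"score output shape {S.shape} does not match data {X.shape}")
    if not np.all(np.isfinite(S)):
        bad = np.argwhere(~np.isfinite(S))[:5]
        raise ValueError(f"non-finite score values at rows {sorted(set(bad[:, 0].tolist()))}")

    idx_list = _block_views(spec, X.shape[1])
    if dtype is not None:
        X = X.astype(dtype)
        S = S.astype(dtype)
    nums, dens = [], []
    for s0, s1 in _iter_chunks(n, chunk):
        Xc, Sc = X[s0:s1], S[s0:s1]
        K, trace, wlist = _kernel_chunks(Xc, X, spec, s0)
        U = K * (Sc @ S.T) + trace
        for idx, w in zip(idx_list, wlist):
            Xb, Sb = X[:, idx], S[:, idx]
            Xcb, Scb = Xc[:, idx], Sc[:, idx]
            # s_i' grad_y k  = -W_b * s_i,b . (x_i,b - x_j,b)
            U -= w * (np.einsum("ic,ic->i", Scb, Xcb)[:, None] - Scb @ Xb.T)
            # s_j' grad_x k  = +W_b * s_j,b . (x_i,b - x_j,b)
            U += w * (Xcb @ Sb.T - np.einsum("ic,ic->i", Sb, Xb)[None, :])
        if not np.all(np.isfinite(U)):
            bad = np.argwhere(~np.isfinite(U))[:5]
            pairs = [(int(i) + s0, int(j)) for i, j in bad]
            raise ValueError(f"non-finite Stein pair terms at index pairs {pairs}")
        nums.append(float(U.sum(dtype=np.float64)))
        dens.append(float(K.sum(dtype=np.float64)))
    numerator = math.fsum(nums)
    denominator = math.fsum(dens)
    return NKSDEstimate(numerator / denominator, numerator, denominator, n)


def nksd_population_mc(
    p_sampler: Callable[[np.random.Generator, int], np.ndarray],
    p_score: ScoreFunction,
    q_score: ScoreFunction,
    spec: KernelSpec,
    n_mc: int,
    seed: int,
    *,
    chunk: int = 512,
    dtype=None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the population NKSD from its definition.

    Uses the definitional form ``E[(s_q - s_p)(X)'(s_q - s_p)(Y) k] / E[k]``
    which requires the data score ``s_p``; this exists for testing and
    oracle use only — the production estimator never needs ``s_p``.

    Returns ``(estimate, standard_error)``; the standard error comes from the
    first-order projection of the ratio of the two U-statistics.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be at least 2")
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(p_sampler(rng, n_mc), dtype=float))
    D = np.asarray(q_score(X), dtype=float) - np.asarray(p_score(X), dtype=float)
    n = X.shape[0]
    if dtype is not None:
        X = X.astype(dtype)
        D = D.astype(dtype)
    num = den = 0.0
    row_num = np.zeros(n)
    row_den = np.zeros(n)
    for s0, s1 in _iter_chunks(n, chunk):
        K, _, _ = _kernel_chunks(X[s0:s1], X, spec, s0)
        H = K * (D[s0:s1] @ D.T)
        num += float(H.sum(dtype=np.float64))
        den += float(K.sum(dtype=np.float64))
        row_num[s0:s1] = H.sum(axis=1, dtype=np.float64)
        row_den[s0:s1] = K.sum(axis=1, dtype=np.float64)
    value = num / den
    # Hajek projection of the ratio statistic.
    g = (row_num / (n - 1) - value * row_den / (n - 1)) / (den / (n * (n - 1)))
    se = 2.0 * float(np.std(g, ddof=1)) / math.sqrt(n)
    return value, se


def expfam_quadratic(
    X: np.ndarray,
    t_jacobian: Callable[[np.ndarray], np.ndarray],
    logbase_grad: Callable[[np.ndarray], np.ndarray],
    spec: KernelSpec,
    *,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients ``(A, B, C)`` with ``NKSD_hat(theta) = theta'A theta + B'theta + C``.

    Valid for exponential-family models ``q(x|theta) = lam(x) exp(theta't(x)
    - kappa(theta))``, whose score is affine in theta:
    ``s_theta(x) = grad log lam(x) + (grad t(x))' theta``.

    ``t_jacobian(X)`` must return the stacked Jacobians ``(n, m, d)`` and
    ``logbase_grad(X)`` the base-measure score ``(n, d)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    T = np.asarray(t_jacobian(X), dtype=float)  # (n, m, d)
    G = np.asarray(logbase_grad(X), dtype=float)  # (n, d)
    if T.ndim != 3 or T.shape[0] != n or T.shape[2] != d:
        raise ValueError(f"t_jacobian output shape {T.shape} incompatible with data {X.shape}")
    if G.shape != X.shape:
        raise ValueError(f"logbase_grad output shape {G.shape} incompatible with data {X.shape}")
    m = T.shape[1]
    idx_list = _block_views(spec, d)

    A = np.zeros((m, m))
    B = np.zeros(m)
    C = 0.0
    den = 0.0
    for s0, s1 in _iter_chunks(n, chunk):
        Xc, Tc, Gc = X[s0:s1], T[s0:s1], G[s0:s1]
        K, trace, wlist = _kernel_chunks(Xc, X, spec, s0)
        den += float(K.sum())
        A += np.einsum("ij,iac,jbc->ab", K, Tc, T, optimize=True)
        B += np.einsum("ij,iac,jc->a", K, Tc, G, optimize=True)
        B += np.einsum("ij,jac,ic->a", K, T, Gc, optimize=True)
        C += float(np.einsum("ij,ic,jc->", K, Gc, G, optimize=True)) + float(trace.sum())
        for idx, w in zip(idx_list, wlist):
            Xb = X[:, idx]
            Xcb = Xc[:, idx]
            # grad_y k(x_i, x_j) restricted to block = W_b * (x_j,b - x_i,b)
            avec = w @ Xb - w.sum(axis=1)[:, None] * Xcb  # (chunk, d_b)
            # grad_x k(x_i, x_j) restricted to block = W_b * (x_i,b - x_j,b)
            bvec = w.T @ Xcb - w.sum(axis=0)[:, None] * Xb  # (n, d_b)
            B += np.einsum("iac,ic->a", Tc[:, :, idx], avec, optimize=True)
            B += np.einsum("jac,jc->a", T[:, :, idx], bvec, optimize=True)
            C += float(np.einsum("ic,ic->", Gc[:, idx], avec))
            C += float(np.einsum("jc,jc->", G[:, idx], bvec))
    A = (A + A.T) / 2.0
    return A / den, B / den, C / den


class LinearScoreMoments:
    """Pairwise kernel moments for scores affine in the observation.

    For a model score ``s(x) = W x + m`` the NKSD U-statistic is a function of
    a handful of data/kernel moments that do not involve the parameters, so
    they are computed once (O(N^2 d) time, O(N d) extra memory) and then
    :meth:`nksd_affine` evaluates the estimator in O(d^3) for any ``(W, m)``.
    """

    def __init__(self, X: np.ndarray, spec: KernelSpec, *, chunk: int = 512, dtype=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if dtype is not None:
            X = X.astype(dtype)
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        self.n = n
        self.d = d
        self.spec = spec
        idx_list = _block_views(spec, d)
        self._blocks = idx_list
        k0 = 0.0
        c0 = 0.0
        p1 = np.zeros(d)
        P = np.zeros((d, d))
        M1 = [np.zeros((d, idx.size)) for idx in idx_list]
        for s0, s1 in _iter_chunks(n, chunk):
            Xc = X[s0:s1]
            K, trace, wlist = _kernel_chunks(Xc, X, spec, s0)
            k0 += float(K.sum(dtype=np.float64))
            c0 += float(trace.sum(dtype=np.float64))
            p1 += (K.sum(axis=0, dtype=np.float64) @ X.astype(np.float64))
            P += (Xc.T @ (K @ X)).astype(np.float64)
            for b, (idx, w) in enumerate(zip(idx_list, wlist)):
                Xb = X[:, idx]
                Xcb = Xc[:, idx]
                M1[b] += (Xc.T @ (w @ Xb) - (Xc * w.sum(axis=1)[:, None]).T @ Xcb).astype(np.float64)
        self.k0 = k0
        self.c0 = c0
        self.p1 = p1
        self.P = (P + P.T) / 2.0
        self.M1 = M1

    def nksd_affine(self, W: np.ndarray, m: np.ndarray | float = 0.0) -> float:
        """NKSD estimate for the score ``s(x) = W x + m``."""
        W = np.asarray(W, dtype=float)
        m = np.broadcast_to(np.asarray(m, dtype=float), (self.d,))
        num = float(np.einsum("ab,ca,cb->", self.P, W, W))
        num += 2.0 * float(m @ (W @ self.p1)) + float(m @ m) * self.k0
        for idx, M1 in zip(self._blocks, self.M1):
            num += 2.0 * float(np.trace(W[idx, :] @ M1))
        num += self.c0
        return num / self.k0

    def location_quadratic(self, cov_inv: np.ndarray):
        """``(A, B, C)`` of the NKSD quadratic for the Gaussian location family.

        The family ``N(x | theta, cov)`` has score ``cov^{-1} theta - cov^{-1} x``,
        i.e. ``W = -cov^{-1}`` fixed and ``m = cov^{-1} theta`` linear in theta.
        """
        cov_inv = np.atleast_2d(np.asarray(cov_inv, dtype=float))
        W = -cov_inv
        A = cov_inv @ cov_inv
        B = 2.0 * cov_inv @ (W @ self.p1) / self.k0
        C = float(np.einsum("ab,ca,cb->", self.P, W, W))
        for idx, M1 in zip(self._blocks, self.M1):
            C += 2.0 * float(np.trace(W[idx, :] @ M1))
        C = (C + self.c0) / self.k0
        return (A + A.T) / 2.0, B, C
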