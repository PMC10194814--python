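"""Kernels for the Stein operator: values and the first/second cross-derivatives.

Both kernel families are radial, ``k(x, y) = f(r2)`` with ``r2 = ||x - y||^2``:

* ``rbf``:  ``f(r2) = exp(-r2 / (2 h^2))``
* ``imq``:  ``f(r2) = (1 + r2 / h^2)^(-1/2)`` (inverse multiquadric)

Both are bounded, strictly positive, integrally strictly positive definite,
and belong to the Stein class of absolutely continuous densities, which is
what the kernelized Stein discrepancy requires.  Derivatives are closed-form
in terms of the radial profile and its derivatives with respect to ``r2``:

    grad_x k      =  2 f'(r2) (x - y)
    grad_y k      = -2 f'(r2) (x - y)
    tr(dx dy^T k) = -2 d f'(r2) - 4 r2 f''(r2)

A ``blocks`` partition turns the kernel into a product of per-block radial
kernels, which gives the discrepancy subsystem independence across the blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "kernel_eval",
    "kernel_derivatives",
    "resolve_bandwidth",
    "pairwise_kernel",
]

_FAMILIES = ("rbf", "imq")


@dataclass(frozen=True)
class KernelSpec:
    """Configuration of a Stein kernel.

    Parameters
    ----------
    family : {"rbf", "imq"}
        Radial profile.  Default is the squared-exponential kernel.
    bandwidth : float or "median"
        Length scale ``h``.  The sentinel ``"median"`` is resolved against the
        data (median pairwise distance) by :func:`resolve_bandwidth` before
        any evaluation.
    blocks : sequence of index sequences, optional
        Partition of the dimension indices ``{0, ..., d-1}``.  When given, the
        kernel is the product of independent per-block kernels (all sharing
        ``family`` and ``bandwidth``).
    """

    family: str = "rbf"
    bandwidth: float | str = "median"
    blocks: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {_FAMILIES}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise ValueError("bandwidth must be a positive number or 'median'")
        elif not self.bandwidth > 0:
            raise ValueError("bandwidth must be > 0")
        if self.blocks is not None:
            object.__setattr__(
                self, "blocks", tuple(tuple(int(i) for i in b) for b in self.blocks)
            )

    @property
    def resolved(self) -> bool:
        return not isinstance(self.bandwidth, str)

    def validate_blocks(self, d: int) -> None:
        """Check that ``blocks`` is a partition of ``range(d)``."""
        if self.blocks is None:
            return
        flat = [i for b in self.blocks for i in b]
        if sorted(flat) != list(range(d)):
            raise ValueError(
                f"blocks {self.blocks} do not partition the {d} dimensions "
                "(need full coverage and no overlap)"
            )


def _require_resolved(spec: KernelSpec) -> float:
    if not spec.resolved:
        raise ValueError(
            "kernel bandwidth is the 'median' sentinel; call resolve_bandwidth(X, spec) first"
        )
    return float(spec.bandwidth)


def _profile(family: str, r2: np.ndarray, h: float):
    """Return ``(f, f', f'')`` of the radial profile evaluated at ``r2``.

    Primes are derivatives with respect to ``r2`` (not the distance).
    """
    r2 = np.asarray(r2, dtype=float)
    if family == "rbf":
        f = np.exp(-r2 / (2.0 * h * h))
        fp = -f / (2.0 * h * h)
        fpp = f / (4.0 * h**4)
    else:  # imq
        base = 1.0 + r2 / (h * h)
        f = base ** (-0.5)
        fp = -0.5 / (h * h) * base ** (-1.5)
        fpp = 0.75 / h**4 * base ** (-2.5)
    return f, fp, fpp


def _block_views(spec: KernelSpec, d: int) -> list[np.ndarray]:
    if spec.blocks is None:
        return [np.arange(d)]
    spec.validate_blocks(d)
    return [np.asarray(b, dtype=int) for b in spec.blocks]


def kernel_eval(x: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """Evaluate ``k(x, y)`` for a single pair of points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    h = _require_resolved(spec)
    out = 1.0
    for idx in _block_views(spec, x.size):
        diff = x[idx] - y[idx]
        f, _, _ = _profile(spec.family, diff @ diff, h)
        out *= float(f)
    return out


def kernel_derivatives(x: np.ndarray, y: np.ndarray, spec: KernelSpec):
    """Return ``(grad_x k, grad_y k, trace of the mixed second derivative)``.

    For a product kernel each block contributes its own derivative scaled by
    the remaining blocks' kernel values; the cross-derivative trace has no
    between-block terms because a coordinate lives in exactly one block.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    h = _require_resolved(spec)

    idx_list = _block_views(spec, x.size)
    vals, fps, fpps, r2s, diffs = [], [], [], [], []
    for idx in idx_list:
        diff = x[idx] - y[idx]
        r2 = diff @ diff
        f, fp, fpp = _profile(spec.family, r2, h)
        vals.append(float(f))
        fps.append(float(fp))
        fpps.append(float(fpp))
        r2s.append(float(r2))
        diffs.append(diff)
    total = float(np.prod(vals))

    grad_x = np.zeros_like(x)
    grad_y = np.zeros_like(y)
    cross = 0.0
    for idx, f, fp, fpp, r2, diff in zip(idx_list, vals, fps, fpps, r2s, diffs):
        rest = total / f
        grad_x[idx] = rest * 2.0 * fp * diff
        grad_y[idx] = -rest * 2.0 * fp * diff
        cross += rest * (-2.0 * idx.size * fp - 4.0 * r2 * fpp)
    return grad_x, grad_y, cross


def pairwise_kernel(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix ``K[i, j] = k(X[i], Y[j])``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    h = _require_resolved(spec)
    K = np.ones((X.shape[0], Y.shape[0]))
    for idx in _block_views(spec, X.shape[1]):
        r2 = _sqdist(X[:, idx], Y[:, idx])
        f, _, _ = _profile(spec.family, r2, h)
        K *= f
    return K


def _sqdist(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at zero."""
    xx = np.einsum("ij,ij->i", X, X)
    yy = np.einsum("ij,ij->i", Y, Y)
    r2 = xx[:, None] + yy[None, :] - 2.0 * X @ Y.T
    np.maximum(r2, 0.0, out=r2)
    return r2


def resolve_bandwidth(
    X: np.ndarray, spec: KernelSpec, *, seed: int = 0, cap: int = 1000
) -> KernelSpec:
    """Replace the ``"median"`` sentinel by the median pairwise distance.

    The median is taken over all pairs of a seeded subsample of at most
    ``cap`` rows, so the result is deterministic given ``seed``.  Specs with a
    numeric bandwidth are returned unchanged.
    """
    if spec.resolved:
        return spec
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to resolve a median bandwidth")
    if n > cap:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, size=cap, replace=False)]
    r2 = _sqdist(X, X)
    iu = np.triu_indices(X.shape[0], k=1)
    med = float(np.median(np.sqrt(r2[iu])))
    if med <= 0.0:
        raise ValueError(
            "median pairwise distance is zero (all rows identical); "
            "set the kernel bandwidth explicitly"
        )
    return replace(spec, bandwidth=med)
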