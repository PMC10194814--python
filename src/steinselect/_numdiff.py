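"""Central finite differences for gradients and Hessians of scalar objectives."""

from __future__ import annotations

from typing import Callable

import numpy as np


def num_grad(f: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        step = eps * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2.0 * step)
    return g


def num_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Symmetrized central-difference Hessian."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.zeros((n, n))
    steps = np.array([eps * max(1.0, abs(xi)) for xi in x])
    f0 = f(x)
    # diagonal terms
    for i in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[i] += steps[i]
        xm[i] -= steps[i]
        H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / steps[i] ** 2
    # off-diagonal terms
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy()
            xpm = x.copy()
            xmp = x.copy()
            xmm = x.copy()
            xpp[[i, j]] += [steps[i], steps[j]]
            xpm[i] += steps[i]
            xpm[j] -= steps[j]
            xmp[i] -= steps[i]
            xmp[j] += steps[j]
            xmm[[i, j]] -= [steps[i], steps[j]]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4.0 * steps[i] * steps[j]
            )
    return (H + H.T) / 2.0
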