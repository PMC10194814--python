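"""Seeded synthetic benchmarks and evaluation metrics.

Generators cover the study conditions the selection machinery is validated
on: bivariate Gaussians (data/model/nested-selection toys), a six-dimensional
pPCA layout whose last two dimensions are misspecified in two ways, and small
spin-glass samples drawn by Metropolis MCMC.  Every generator is a pure
function of (parameters, seed).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .kernels import KernelSpec
from .models import ForegroundModel, glass_unnorm_logpdf
from .svc import NKSDObjective

__all__ = [
    "gen_toy",
    "gen_ppca_sim",
    "PPCA_SIM_H",
    "PPCA_SIM_TRUTH",
    "gen_glass",
    "balanced_accuracy",
    "criticism_score",
]

# Factor loadings of the simulation's well-specified block (4 dims, 2 factors).
PPCA_SIM_H = np.array([[1.0, 0.0], [-1.0, 1.0], [0.0, 1.0], [-1.0, -1.0]])
# Dimensions generated outside the pPCA family (1-based: 5 and 6; 0-based indices).
PPCA_SIM_TRUTH = (4, 5)


def gen_toy(N: int, sigma0: np.ndarray | Sequence, seed: int) -> np.ndarray:
    """``N`` i.i.d. draws from a centered bivariate Gaussian with covariance sigma0."""
    sigma0 = np.atleast_2d(np.asarray(sigma0, dtype=float))
    if sigma0.shape != (2, 2) or not np.allclose(sigma0, sigma0.T):
        raise ValueError("sigma0 must be a symmetric 2x2 matrix")
    if np.linalg.eigvalsh(sigma0).min() <= 0:
        raise ValueError("sigma0 must be positive definite")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(2), sigma0, size=N)


def gen_ppca_sim(N: int, scenario: str, seed: int) -> tuple[np.ndarray, tuple[int, ...]]:
    """Six-dimensional benchmark: pPCA on dims 1-4, misspecified dims 5-6.

    Dimensions 1-4 follow a pPCA model with two latent factors (loadings
    :data:`PPCA_SIM_H`) and unit noise variance, so their population
    covariance is ``H H' + I``.  Dimensions 5-6 are a two-component mixture
    driven by a fair Bernoulli ``W``:

    * scenario ``"A"``: ``N(0, 0.05^W I_2)`` — a scale mixture whose marginals
      are visibly non-Gaussian;
    * scenario ``"B"``: unit variances with correlation ``(-1)^W 0.99`` — the
      marginals stay exactly Gaussian and only the dependence between the two
      dimensions breaks the model.

    Returns ``(X, truth)`` with ``truth`` the 0-based indices of the
    misspecified dimensions (always ``(4, 5)`` by construction).
    """
    if scenario not in ("A", "B"):
        raise ValueError("scenario must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((N, 2))
    X14 = Z @ PPCA_SIM_H.T + rng.standard_normal((N, 4))
    W = rng.integers(0, 2, size=N)
    if scenario == "A":
        sd = np.where(W == 1, math.sqrt(0.05), 1.0)
        X56 = rng.standard_normal((N, 2)) * sd[:, None]
    else:
        rho = np.where(W == 1, -0.99, 0.99)
        e1 = rng.standard_normal(N)
        e2 = rng.standard_normal(N)
        X56 = np.stack([e1, rho * e1 + np.sqrt(1.0 - rho**2) * e2], axis=1)
    return np.concatenate([X14, X56], axis=1), PPCA_SIM_TRUTH


def gen_glass(
    N: int,
    theta: np.ndarray,
    d: int,
    *,
    n_burn: int = 2000,
    n_thin: int = 10,
    seed: int = 0,
    step0: float = 1.0,
    target_accept: float = 0.3,
    base_precision: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Metropolis sampling of the (unnormalized) glass density.

    Per-coordinate Gaussian random-walk proposals; the step size adapts
    toward the target acceptance rate during burn-in only and is frozen
    afterwards, so the retained draws form a valid Markov chain.  Returns
    ``(draws, acceptance_rate)`` with ``N`` post-burn-in, thinned draws.
    """
    if d > 10:
        raise ValueError("the default budget targets desk scale: d <= 10")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(d)
    lp = float(glass_unnorm_logpdf(theta, x[None, :], d, base_precision)[0])
    step = float(step0)
    draws = np.empty((N, d))
    accepted = proposed = 0
    total_iters = n_burn + N * n_thin
    out = 0
    for it in range(total_iters):
        for j in range(d):
            xp = x.copy()
            xp[j] += step * rng.standard_normal()
            lpp = float(glass_unnorm_logpdf(theta, xp[None, :], d, base_precision)[0])
            proposed += 1
            if math.log(rng.random()) < lpp - lp:
                x, lp = xp, lpp
                accepted += 1
        if it < n_burn:
            # Robbins-Monro adaptation, frozen after burn-in
            rate = accepted / max(proposed, 1)
            step *= math.exp(0.05 * (rate - target_accept))
        elif (it - n_burn) % n_thin == 0 and out < N:
            draws[out] = x
            out += 1
    return draws, accepted / max(proposed, 1)


def balanced_accuracy(decisions: Sequence[str], truth: Sequence[bool]) -> float:
    """``(TN/N + TP/P) / 2`` with "exclude" treated as the positive label.

    ``truth[j]`` is True when dimension j really is misspecified (should be
    excluded).
    """
    decisions = list(decisions)
    truth = [bool(t) for t in truth]
    if len(decisions) != len(truth):
        raise ValueError("decisions and truth must have the same length")
    pos = [d for d, t in zip(decisions, truth) if t]
    neg = [d for d, t in zip(decisions, truth) if not t]
    if not pos or not neg:
        raise ValueError("truth needs at least one positive and one negative")
    tpr = sum(d == "exclude" for d in pos) / len(pos)
    tnr = sum(d == "include" for d in neg) / len(neg)
    return 0.5 * (tpr + tnr)


def criticism_score(
    full_model: ForegroundModel,
    cand_model: ForegroundModel,
    X: np.ndarray,
    columns: Sequence[int],
    theta0: np.ndarray,
    T: float,
    spec: KernelSpec,
) -> float:
    """Conventional model-criticism comparator to the SVC log-ratio.

    ``log E_j - log E_0``: the change in the (scaled) NKSD fit term when the
    candidate projection is evaluated at the FULL-data optimum ``theta0`` —
    no re-fitting, no volume terms.  Measures mismatch attributed to the
    dropped subspace by the full fitted model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    cols = list(columns)
    if sorted(cols) == list(range(X.shape[1])):
        return 0.0
    full_nksd = NKSDObjective(full_model, X, spec)(theta0)
    cand_nksd = NKSDObjective(cand_model, X[:, cols], spec)(theta0)
    return -(N / T) * cand_nksd + (N / T) * full_nksd
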