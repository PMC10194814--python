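"""Foreground model families: Gaussian location, probabilistic PCA, spin glass.

Each family is packaged as a :class:`ForegroundModel`: a Stein score function
``s_theta(x) = grad_x log q(x | theta)``, an effective parameter dimension
``m_F`` used by the volume terms of the selection score, a prior over the
unconstrained parameterization (constraint transforms contribute their
log-Jacobians), and — where the structure exists — an exponential-family or
affine-score shortcut that the fast NKSD machinery exploits.

All optimization happens in an unconstrained real vector space:

* Gaussian location: the mean itself.
* pPCA: a free ``d x k`` matrix mapped to the Stiefel manifold by QR
  orthonormalization, log-gaps for the factor scales (``L_ii = v + exp(l_i)``
  keeps ``L_ii > v``), and ``log v``.
* glass: fields, couplings, threshold ``mu`` and ``log tau``.

Only the score enters the discrepancy, so the glass model's intractable
normalizing constant never needs to be computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln

__all__ = [
    "ForegroundModel",
    "PPCAParams",
    "GlassParams",
    "gaussian_model",
    "ppca_model",
    "glass_model",
    "glass_per_dimension_params",
    "delta_energy",
    "delta_energy_matrix",
]


@dataclass
class ForegroundModel:
    """A parametric foreground model exposed through its Stein score.

    ``score(theta, X)`` maps an unconstrained parameter vector and an
    ``(n, d)`` data batch to the ``(n, d)`` score matrix.  ``param_dim`` is
    the effective parameter dimension ``m_F`` (for pPCA this is the Stiefel
    quotient dimension, smaller than the length ``n_free`` of the
    unconstrained vector).
    """

    name: str
    dim: int
    param_dim: int
    n_free: int
    score: Callable[[np.ndarray, np.ndarray], np.ndarray]
    prior_logpdf: Callable[[np.ndarray], float]
    default_init: np.ndarray | None = None
    init_from_data: Optional[Callable[[np.ndarray], np.ndarray]] = None
    expfam: Optional[tuple[Callable, Callable]] = None  # (t_jacobian, logbase_grad)
    affine: Optional[Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]] = None
    # score affine in BOTH x and theta: s(x) = W x + M theta + m0, constant W.
    # Makes the NKSD an explicit quadratic in theta via the kernel moments.
    affine_linear: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None
    constrain: Optional[Callable[[np.ndarray], object]] = None
    log_density: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    prior_sampler: Optional[Callable[[np.random.Generator], np.ndarray]] = None
    # Gaussian prior moments in unconstrained space, when the prior is Gaussian
    # (enables the closed-form SVC backend).
    gaussian_prior: Optional[tuple[np.ndarray, np.ndarray]] = None

    def initial_point(self, X: np.ndarray | None = None) -> np.ndarray:
        if self.init_from_data is not None and X is not None:
            return np.asarray(self.init_from_data(X), dtype=float)
        if self.default_init is not None:
            return np.asarray(self.default_init, dtype=float)
        return np.zeros(self.n_free)


# ---------------------------------------------------------------------------
# Gaussian location family


def gaussian_model(
    mean_free: bool = True,
    cov: np.ndarray | float = 1.0,
    prior_mean: np.ndarray | float = 0.0,
    prior_var: float = 10.0,
    *,
    d: int | None = None,
    fixed_mean: np.ndarray | float = 0.0,
    name: str | None = None,
) -> ForegroundModel:
    """Gaussian model ``N(x | theta, cov)`` with fixed SPD covariance.

    With ``mean_free`` the mean is the parameter (``m_F = d``) under a
    ``N(prior_mean, prior_var I)`` prior; otherwise the mean is pinned at
    ``fixed_mean`` and ``m_F = 0``.  The score is affine in both ``x`` and
    ``theta``, so the exponential-family quadratic applies with natural
    statistic Jacobian ``cov^{-1}`` and base-measure score ``-cov^{-1} x``.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if d is not None and cov.shape == (1, 1):
        cov = cov[0, 0] * np.eye(d)
    dd = cov.shape[0]
    if cov.shape != (dd, dd) or not np.allclose(cov, cov.T):
        raise ValueError("cov must be a symmetric matrix")
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin <= 0:
        raise ValueError("cov must be symmetric positive definite")
    cov_inv = np.linalg.inv(cov)

    if mean_free:
        mu0 = np.broadcast_to(np.asarray(prior_mean, dtype=float), (dd,)).copy()
        Sigma0 = prior_var * np.eye(dd)

        def score(theta, X):
            theta = np.asarray(theta, dtype=float)
            return (theta - np.atleast_2d(X)) @ cov_inv

        def t_jacobian(X):
            n = np.atleast_2d(X).shape[0]
            return np.broadcast_to(cov_inv, (n, dd, dd)).copy()

        def logbase_grad(X):
            return -np.atleast_2d(X) @ cov_inv

        def prior_logpdf(theta):
            return float(
                stats.multivariate_normal.logpdf(np.asarray(theta), mean=mu0, cov=Sigma0)
            )

        def affine(theta):
            return -cov_inv, cov_inv @ np.asarray(theta, dtype=float)

        def log_density(theta, X):
            return stats.multivariate_normal.logpdf(np.atleast_2d(X), mean=theta, cov=cov)

        def prior_sampler(rng):
            return rng.normal(mu0, math.sqrt(prior_var))

        return ForegroundModel(
            name=name or f"gaussian_location_d{dd}",
            dim=dd,
            param_dim=dd,
            n_free=dd,
            score=score,
            prior_logpdf=prior_logpdf,
            default_init=np.zeros(dd),
            init_from_data=lambda X: np.atleast_2d(X).mean(axis=0),
            expfam=(t_jacobian, logbase_grad),
            affine=affine,
            affine_linear=(-cov_inv, cov_inv.copy(), np.zeros(dd)),
            log_density=log_density,
            prior_sampler=prior_sampler,
            gaussian_prior=(mu0, Sigma0),
        )

    mean = np.broadcast_to(np.asarray(fixed_mean, dtype=float), (dd,)).copy()

    def score_fixed(theta, X):
        return (mean - np.atleast_2d(X)) @ cov_inv

    return ForegroundModel(
        name=name or f"gaussian_fixed_d{dd}",
        dim=dd,
        param_dim=0,
        n_free=0,
        score=score_fixed,
        prior_logpdf=lambda theta: 0.0,
        default_init=np.zeros(0),
        affine=lambda theta: (-cov_inv, cov_inv @ mean),
        affine_linear=(-cov_inv, np.zeros((dd, 0)), cov_inv @ mean),
        log_density=lambda theta, X: stats.multivariate_normal.logpdf(
            np.atleast_2d(X), mean=mean, cov=cov
        ),
    )


# ---------------------------------------------------------------------------
# Probabilistic PCA


@dataclass(frozen=True)
class PPCAParams:
    """Constrained pPCA parameters: ``x ~ N(0, U (L - v I) U' + v I)``."""

    U: np.ndarray  # (d, k), orthonormal columns
    L: np.ndarray  # (k,), diagonal scales, each > v
    v: float  # noise variance
    k: int

    @property
    def cov(self) -> np.ndarray:
        d = self.U.shape[0]
        return self.U @ np.diag(self.L - self.v) @ self.U.T + self.v * np.eye(d)

    @property
    def H(self) -> np.ndarray:
        return self.U @ np.diag(np.sqrt(self.L - self.v))


def _qr_orthonormal(A: np.ndarray) -> np.ndarray:
    """Q factor with positive diagonal of R, a deterministic Stiefel retraction."""
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs[None, :]


def stiefel_log_volume(d: int, k: int) -> float:
    """log of the volume of the Stiefel manifold of d x k orthonormal frames."""
    out = 0.0
    for i in range(d - k + 1, d + 1):
        out += math.log(2.0) + (i / 2.0) * math.log(math.pi) - gammaln(i / 2.0)
    return out


def ppca_model(d: int, k: int, alpha: float = 0.1, *, name: str | None = None) -> ForegroundModel:
    """Probabilistic PCA with the orthonormal-factor parameterization.

    The marginal of an observation is ``N(0, C)`` with
    ``C = U diag(L - v) U' + v I`` (eigenvalues ``L_1..L_k`` and ``v`` with
    multiplicity ``d - k``), so the score is ``-C^{-1} x`` — affine in ``x``.
    Priors: ``U`` uniform on the Stiefel manifold, ``L_ii ~
    InvGamma(alpha/2, alpha/2)``, ``v ~ InvGamma((alpha/2+1)(d-k)-1,
    (alpha/2)(d-k))``.

    ``m_F = dk - k(k+1)/2 + k + 1``: the Stiefel quotient dimension plus the
    ``k`` scales and the noise variance.  The unconstrained vector is longer
    (``dk + k + 1``) because the free matrix behind the QR map carries
    ``k(k+1)/2`` gauge directions; volume terms always use ``m_F``.
    """
    if not 1 <= k < d:
        raise ValueError(f"need 1 <= k < d, got k={k}, d={d}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_free = d * k + k + 1
    m_f = d * k - k * (k + 1) // 2 + k + 1
    a_v = (alpha / 2.0 + 1.0) * (d - k) - 1.0
    b_v = (alpha / 2.0) * (d - k)
    if a_v <= 0:
        raise ValueError("noise-variance prior shape is nonpositive; increase d - k or alpha")
    log_vol_stiefel = stiefel_log_volume(d, k)

    def unpack(theta):
        theta = np.asarray(theta, dtype=float)
        A = theta[: d * k].reshape(d, k)
        ell = theta[d * k : d * k + k]
        logv = theta[-1]
        return A, ell, logv

    def constrain(theta) -> PPCAParams:
        A, ell, logv = unpack(theta)
        v = float(np.exp(logv))
        U = _qr_orthonormal(A)
        L = v + np.exp(ell)
        return PPCAParams(U=U, L=L, v=v, k=k)

    def cov_inv(theta):
        A, ell, logv = unpack(theta)
        v = float(np.exp(logv))
        U = _qr_orthonormal(A)
        e = np.exp(ell)  # L - v
        # Woodbury: (U diag(e) U' + v I)^{-1} = (I - U diag(e/(e+v)) U') / v
        return (np.eye(d) - (U * (e / (e + v))[None, :]) @ U.T) / v

    def score(theta, X):
        return -np.atleast_2d(X) @ cov_inv(theta)

    def affine(theta):
        return -cov_inv(theta), np.zeros(d)

    def prior_logpdf(theta):
        A, ell, logv = unpack(theta)
        v = float(np.exp(logv))
        L = v + np.exp(ell)
        lp = -log_vol_stiefel  # uniform density on the Stiefel manifold
        lp += float(np.sum(stats.invgamma.logpdf(L, a=alpha / 2.0, scale=alpha / 2.0)))
        lp += float(stats.invgamma.logpdf(v, a=a_v, scale=b_v))
        # log-Jacobian of (ell, log v) -> (L, v): triangular, det = v * prod(exp(ell))
        lp += logv + float(np.sum(ell))
        return lp

    def init_from_data(X):
        X = np.atleast_2d(X)
        S = np.cov(X, rowvar=False)
        w, V = np.linalg.eigh(S)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        v0 = max(float(np.mean(w[k:])), 1e-3)
        gaps = np.maximum(w[:k] - v0, 1e-3)
        theta = np.concatenate([V[:, :k].ravel(), np.log(gaps), [math.log(v0)]])
        return theta

    def log_density(theta, X):
        p = constrain(theta)
        return stats.multivariate_normal.logpdf(np.atleast_2d(X), mean=np.zeros(d), cov=p.cov)

    return ForegroundModel(
        name=name or f"ppca_d{d}_k{k}",
        dim=d,
        param_dim=m_f,
        n_free=n_free,
        score=score,
        prior_logpdf=prior_logpdf,
        default_init=np.concatenate([np.eye(d, k).ravel(), np.zeros(k), [0.0]]),
        init_from_data=init_from_data,
        affine=affine,
        constrain=constrain,
        log_density=log_density,
    )


# ---------------------------------------------------------------------------
# Glass (continuous-relaxation Ising) model


@dataclass(frozen=True)
class GlassParams:
    """Constrained glass parameters.

    ``J`` is stored for ordered pairs ``j < j'`` only (upper triangle), as a
    ``(n_pairs, 2, 2)`` array in row-major pair order.
    """

    H: np.ndarray  # (d, 2) field vectors
    J: np.ndarray  # (n_pairs, 2, 2)
    mu: float
    tau: float


def glass_per_dimension_params(d: int) -> int:
    """Foreground parameters tied to one data dimension: couplings plus field."""
    return 4 * (d - 1) + 2


def _glass_unpack(theta: np.ndarray, d: int):
    theta = np.asarray(theta, dtype=float)
    n_pairs = d * (d - 1) // 2
    H = theta[: 2 * d].reshape(d, 2)
    J = theta[2 * d : 2 * d + 4 * n_pairs].reshape(n_pairs, 2, 2)
    mu = float(theta[-2])
    tau = float(np.exp(theta[-1]))
    return H, J, mu, tau


def _coupling_tensor(J: np.ndarray, d: int) -> np.ndarray:
    """Symmetrized (d, d, 2, 2) coupling tensor: entry [j, j'] multiplies z_j' as
    seen from gene j; ``[j', j] = [j, j'].T`` and the diagonal is zero."""
    full = np.zeros((d, d, 2, 2))
    p = 0
    for j in range(d):
        for jp in range(j + 1, d):
            full[j, jp] = J[p]
            full[jp, j] = J[p].T
            p += 1
    return full


def _spins(X: np.ndarray, mu: float, tau: float):
    """Logistic spins z (n, d, 2) and the derivative dz1/dx (n, d)."""
    z1 = expit(tau * (X - mu))
    dz1 = tau * z1 * (1.0 - z1)
    Z = np.stack([z1, 1.0 - z1], axis=-1)
    return Z, dz1


def glass_unnorm_logpdf(
    theta: np.ndarray, X: np.ndarray, d: int, base_precision: float = 1.0
) -> np.ndarray:
    """Unnormalized log density of the glass model (per observation).

    The spin energies are bounded, so the pure glass energy alone is not
    integrable on R^d; ``base_precision > 0`` adds an isotropic Gaussian base
    measure ``-base_precision * ||x||^2 / 2`` that anchors the continuous
    relaxation (expression values are standardized in practice).  The
    normalizing constant remains intractable either way and never enters the
    score.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    H, J, mu, tau = _glass_unpack(theta, d)
    Z, _ = _spins(X, mu, tau)
    full = _coupling_tensor(J, d)
    energy = np.einsum("ija,ja->i", Z, H)
    # pairwise term: sum over j' > j of z_j' J z_j'', counted once
    energy += 0.5 * np.einsum("ija,jkab,ikb->i", Z, full, Z)
    if base_precision:
        energy = energy - 0.5 * base_precision * np.einsum("ij,ij->i", X, X)
    return energy


def glass_model(
    d: int,
    prior_scales: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    *,
    base_precision: float = 1.0,
    name: str | None = None,
) -> ForegroundModel:
    """Continuous spin-glass relaxation of an Ising model for expression data.

    Each gene carries a logistic spin ``z_j = (z_j1, 1 - z_j1)`` with
    ``z_j1 = sigmoid(tau (x_j - mu))``; genes interact through 2x2 coupling
    blocks ``J_jj'`` and feel fields ``H_j``.  The density's normalizing
    constant is unknown, but the score only involves derivatives of the
    unnormalized log density, so NKSD-based selection applies unchanged.

    Priors: Normal(0, h_sd) on field entries, Laplace(0, j_scale) on coupling
    entries (sparsity), Normal(0, mu_sd) on the threshold and
    Normal(0, tau_sd) on ``log tau``.

    ``base_precision`` adds an isotropic Gaussian base measure to the energy
    (see :func:`glass_unnorm_logpdf`); set it to 0 for the pure spin energy.
    """
    if d < 2:
        raise ValueError("glass model needs d >= 2")
    h_sd, j_scale, mu_sd, tau_sd = prior_scales
    n_pairs = d * (d - 1) // 2
    n_free = 2 * d + 4 * n_pairs + 2

    def score(theta, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        H, J, mu, tau = _glass_unpack(theta, d)
        Z, dz1 = _spins(X, mu, tau)
        full = _coupling_tensor(J, d)
        # effective field on gene j: H_j + sum_{j' != j} J_eff[j, j'] z_j'
        phi = H[None, :, :] + np.einsum("jkab,ikb->ija", full, Z)
        out = dz1 * (phi[..., 0] - phi[..., 1])
        if base_precision:
            out = out - base_precision * X
        return out

    def prior_logpdf(theta):
        H, J, mu, tau = _glass_unpack(theta, d)
        lp = float(np.sum(stats.norm.logpdf(H, scale=h_sd)))
        lp += float(np.sum(stats.laplace.logpdf(J, scale=j_scale)))
        lp += float(stats.norm.logpdf(mu, scale=mu_sd))
        lp += float(stats.norm.logpdf(np.log(tau), scale=tau_sd))
        return lp

    return ForegroundModel(
        name=name or f"glass_d{d}",
        dim=d,
        param_dim=n_free,
        n_free=n_free,
        score=score,
        prior_logpdf=prior_logpdf,
        default_init=np.zeros(n_free),
        constrain=lambda th: GlassParams(*_glass_unpack(th, d)),
        log_density=lambda th, X: glass_unnorm_logpdf(th, X, d, base_precision),
    )


def delta_energy(J_block: np.ndarray) -> float:
    """Interaction energy ``dE = J_21 + J_12 - J_22 - J_11`` of one 2x2 block.

    Positive values mean two genes prefer opposite on/off states costs more
    energy than aligned states (the four coefficients sum to zero, so a
    constant shift of the block leaves dE unchanged).
    """
    J = np.asarray(J_block, dtype=float)
    if J.shape != (2, 2):
        raise ValueError(f"expected a 2x2 coupling block, got shape {J.shape}")
    return float(J[1, 0] + J[0, 1] - J[1, 1] - J[0, 0])


def delta_energy_matrix(params: GlassParams, d: int | None = None) -> np.ndarray:
    """Symmetric d x d matrix of pairwise interaction energies, zero diagonal."""
    n_pairs = params.J.shape[0]
    if d is None:
        d = int(round((1 + math.sqrt(1 + 8 * n_pairs)) / 2))
    out = np.zeros((d, d))
    p = 0
    for j in range(d):
        for jp in range(j + 1, d):
            out[j, jp] = out[jp, j] = delta_energy(params.J[p])
            p += 1
    return out
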