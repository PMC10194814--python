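"""Candidate-model builders for selection scans.

A leave-one-out scan evaluates the same model family on many projections of
the data.  For the optimum-transfer shortcut all candidates must share one
unconstrained parameter space, so these builders return, for a column subset,
the projected model expressed in the FULL model's parameters: components tied
to dropped dimensions simply stop influencing the objective (and the
effective dimension ``m_F`` shrinks accordingly).

Projection is exact in both families: a coordinate subset of a Gaussian is
the Gaussian with the sub-covariance, and the marginal of a pPCA vector on a
subset of coordinates is the zero-mean Gaussian with the corresponding
submatrix of ``U diag(L - v) U' + v I``.
"""

from __future__ import annotations

import numpy as np

from .models import ForegroundModel, gaussian_model, ppca_model

__all__ = ["gaussian_loo_builder", "ppca_loo_builder", "gaussian_subset_builder"]


def gaussian_loo_builder(d: int, cov: np.ndarray | float = 1.0,
                         prior_mean: float = 0.0, prior_var: float = 10.0):
    """Shared-parameter Gaussian location builder over column subsets."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape == (1, 1):
        cov = cov[0, 0] * np.eye(d)
    full = gaussian_model(True, cov, prior_mean, prior_var)

    def builder(cols: tuple[int, ...]) -> ForegroundModel:
        cols = tuple(cols)
        if cols == tuple(range(d)):
            return full
        idx = list(cols)
        sub_inv = np.linalg.inv(cov[np.ix_(idx, idx)])
        E = np.zeros((len(idx), d))
        E[np.arange(len(idx)), idx] = 1.0
        M = sub_inv @ E
        mu0 = np.full(d, prior_mean, dtype=float)

        def score(theta, X):
            theta = np.asarray(theta, dtype=float)
            return (theta[idx] - np.atleast_2d(X)) @ sub_inv

        return ForegroundModel(
            name=f"gaussian_sub_{cols}",
            dim=len(idx),
            param_dim=len(idx),
            n_free=d,
            score=score,
            prior_logpdf=full.prior_logpdf,
            default_init=np.zeros(d),
            affine=lambda th: (-sub_inv, M @ np.asarray(th, dtype=float)),
            affine_linear=(-sub_inv, M, np.zeros(len(idx))),
            gaussian_prior=(mu0, prior_var * np.eye(d)),
        )

    return builder


def gaussian_subset_builder(d: int, cov: np.ndarray | float = 1.0,
                            prior_mean: float = 0.0, prior_var: float = 10.0):
    """Standalone Gaussian location builder (each subset owns its parameters)."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape == (1, 1):
        cov = cov[0, 0] * np.eye(d)

    def builder(cols: tuple[int, ...]) -> ForegroundModel:
        idx = list(cols)
        return gaussian_model(True, cov[np.ix_(idx, idx)], prior_mean, prior_var)

    return builder


def ppca_loo_builder(d: int, k: int, alpha: float = 0.1):
    """Shared-parameter pPCA builder over column subsets.

    The candidate for a subset scores the projected data against the
    submatrix of the full model's covariance; rows of the factor matrix tied
    to dropped dimensions become inert.  ``m_F`` uses the Stiefel quotient
    count for the reduced dimension.
    """
    full = ppca_model(d, k, alpha)

    def builder(cols: tuple[int, ...]) -> ForegroundModel:
        cols = tuple(cols)
        if cols == tuple(range(d)):
            return full
        idx = list(cols)
        ds = len(idx)
        m_f = ds * k - k * (k + 1) // 2 + k + 1

        def sub_cov_inv(theta):
            p = full.constrain(theta)
            C = p.cov[np.ix_(idx, idx)]
            return np.linalg.inv(C)

        def score(theta, X):
            return -np.atleast_2d(X) @ sub_cov_inv(theta)

        return ForegroundModel(
            name=f"ppca_sub_{cols}",
            dim=ds,
            param_dim=m_f,
            n_free=full.n_free,
            score=score,
            prior_logpdf=full.prior_logpdf,
            default_init=full.default_init,
            init_from_data=None,
            affine=lambda th: (-sub_cov_inv(th), np.zeros(ds)),
            constrain=full.constrain,
        )

    return builder
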