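"""scikit-learn style estimators over the NKSD/SVC machinery.

These wrap the library's fitting and selection cores in the familiar
fit/transform surface so they compose with sklearn pipelines and model
selection.  Fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .kernels import KernelSpec
from .models import ForegroundModel
from .selection import loo_scan, subset_search
from .svc import BackgroundPolicy, fit_min_nksd, svc_score

__all__ = [
    "MinimumSteinDiscrepancyEstimator",
    "SteinVolumeCriterion",
    "LeaveOneOutSelector",
    "SubsetSearchSelector",
]


class MinimumSteinDiscrepancyEstimator(BaseEstimator):
    """Fit a foreground model by minimizing the NKSD U-statistic.

    Parameters
    ----------
    model_factory : callable ``(d,) -> ForegroundModel``
        Builds the foreground model for d-dimensional data.
    kernel : KernelSpec
    seed : int

    Attributes
    ----------
    theta_ : ndarray
        Minimum Stein discrepancy estimate (unconstrained space).
    nksd_min_ : float
    hessian_ : ndarray
    params_ : object
        Constrained parameters, when the model defines a transform.
    """

    def __init__(self, model_factory=None, kernel=KernelSpec(), seed=0):
        self.model_factory = model_factory
        self.kernel = kernel
        self.seed = seed

    def fit(self, X, y=None):
        X = check_array(X)
        model = self.model_factory(X.shape[1])
        res = fit_min_nksd(model, X, self.kernel, seed=self.seed)
        self.model_ = model
        self.theta_ = res.theta
        self.nksd_min_ = res.nksd_min
        self.hessian_ = res.hessian
        self.converged_ = res.converged
        self.params_ = model.constrain(res.theta) if model.constrain else None
        return self

    def score(self, X, y=None):
        """Negative NKSD of held-out data under the fitted parameters."""
        check_is_fitted(self, "theta_")
        from .svc import NKSDObjective

        X = check_array(X)
        return -NKSDObjective(self.model_, X, self.kernel)(self.theta_)


class SteinVolumeCriterion(BaseEstimator):
    """Compute the log SVC of a foreground model on the full data space."""

    def __init__(self, model_factory=None, kernel=KernelSpec(), T=1.0,
                 policy=BackgroundPolicy(), r_b=0, backend="laplace", seed=0):
        self.model_factory = model_factory
        self.kernel = kernel
        self.T = T
        self.policy = policy
        self.r_b = r_b
        self.backend = backend
        self.seed = seed

    def fit(self, X, y=None):
        X = check_array(X)
        model = self.model_factory(X.shape[1])
        res = svc_score(model, X, self.kernel, self.T, self.policy, self.r_b,
                        backend=self.backend, seed=self.seed)
        self.model_ = model
        self.result_ = res
        self.log_svc_ = res.log_svc
        self.theta_ = res.theta_hat
        return self

    def score(self, X=None, y=None):
        check_is_fitted(self, "log_svc_")
        return self.log_svc_


class LeaveOneOutSelector(BaseEstimator, TransformerMixin):
    """Feature selector from a leave-one-out SVC scan.

    Keeps the dimensions whose exclusion does not raise the SVC, i.e. the
    maximal foreground on which the model is judged well-specified.
    """

    def __init__(self, model_builder=None, kernel=KernelSpec(), T=1.0,
                 policy=BackgroundPolicy(), backend="bic", transfer=True,
                 reoptimize=False, mb_mode="policy", seed=0):
        self.model_builder = model_builder
        self.kernel = kernel
        self.T = T
        self.policy = policy
        self.backend = backend
        self.transfer = transfer
        self.reoptimize = reoptimize
        self.mb_mode = mb_mode
        self.seed = seed

    def fit(self, X, y=None):
        X = check_array(X)
        report = loo_scan(
            X, self.model_builder, spec=self.kernel, T=self.T, policy=self.policy,
            backend=self.backend, transfer=self.transfer, reoptimize=self.reoptimize,
            mb_mode=self.mb_mode, seed=self.seed,
        )
        self.report_ = report
        rows = [r for r in report.rows if r["candidate"] != "full"]
        self.log_ratios_ = np.array([r["log_ratio"] for r in rows])
        self.support_ = np.array([r["decision"] == "include" for r in rows])
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        return X[:, self.support_]


class SubsetSearchSelector(BaseEstimator, TransformerMixin):
    """Feature selector by stochastic subset search (leave-one-out REINFORCE)."""

    def __init__(self, model_builder=None, kernel=KernelSpec(), T=1.0,
                 policy=BackgroundPolicy(), backend="variational", steps=200,
                 batch=4, lr=0.25, seed=0, backend_kwargs=None):
        self.model_builder = model_builder
        self.kernel = kernel
        self.T = T
        self.policy = policy
        self.backend = backend
        self.steps = steps
        self.batch = batch
        self.lr = lr
        self.seed = seed
        self.backend_kwargs = backend_kwargs

    def fit(self, X, y=None):
        X = check_array(X)
        probs, best, trace = subset_search(
            X, self.model_builder, spec=self.kernel, T=self.T, policy=self.policy,
            backend=self.backend, steps=self.steps, batch=self.batch, lr=self.lr,
            seed=self.seed, backend_kwargs=self.backend_kwargs,
        )
        self.inclusion_probabilities_ = probs
        self.best_subset_ = best
        self.trace_ = trace
        self.support_ = probs > 0.5
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        return X[:, self.support_]
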