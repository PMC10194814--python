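"""Foreground selection: pairwise comparisons, leave-one-out scans, subset search.

A foreground candidate is a projection of the data — a column subset or a
general orthonormal ``V`` — to which the parametric model of interest is
applied; the orthogonal complement is the background, entering the score only
through its effective dimension.  All candidates in a scan share the model's
unconstrained parameter space, which is what allows the implicit-function
(first-order) transfer of the fitted optimum from the full foreground to each
candidate without re-optimizing.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ._numdiff import num_grad, num_hessian
from .kernels import KernelSpec, resolve_bandwidth
from .models import ForegroundModel
from .svc import (
    BackgroundPolicy,
    FitResult,
    NKSDObjective,
    SVCResult,
    background_dim,
    fit_min_nksd,
    svc_score,
)

__all__ = [
    "ForegroundCandidate",
    "SelectionReport",
    "project",
    "compare",
    "transfer_optimum",
    "loo_scan",
    "subset_search",
]

ModelBuilder = Callable[[tuple[int, ...]], ForegroundModel]


@dataclass(frozen=True)
class ForegroundCandidate:
    """A candidate foreground subspace: a column subset or an orthonormal V."""

    name: str
    columns: Optional[tuple[int, ...]] = None
    V: Optional[np.ndarray] = None

    def __post_init__(self):
        if (self.columns is None) == (self.V is None):
            raise ValueError("specify exactly one of columns or V")
        if self.columns is not None:
            object.__setattr__(self, "columns", tuple(int(c) for c in self.columns))

    def r_f(self, d: int) -> int:
        return len(self.columns) if self.columns is not None else self.V.shape[1]

    def r_b(self, d: int) -> int:
        return d - self.r_f(d)


def project(X: np.ndarray, cand: ForegroundCandidate, *, tol: float = 1e-8) -> np.ndarray:
    """Project every row of X onto the candidate foreground (never a row subset)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if cand.columns is not None:
        if cand.columns and max(cand.columns) >= X.shape[1]:
            raise ValueError("candidate columns exceed data dimension")
        return X[:, list(cand.columns)]
    V = np.asarray(cand.V, dtype=float)
    if V.shape[0] != X.shape[1]:
        raise ValueError("V row count must equal data dimension")
    if not np.allclose(V.T @ V, np.eye(V.shape[1]), atol=tol):
        raise ValueError("V must have orthonormal columns")
    return X @ V


def compare(result1: SVCResult, result2: SVCResult) -> float:
    """log score ratio ``log K1 - log K2``; antisymmetric by construction.

    Comparisons across different temperatures, kernels, sample sizes or
    background policies are silently meaningless, so mismatched
    configurations raise.
    """
    if result1.config_key != result2.config_key:
        raise ValueError(
            "cannot compare SVC results computed under different configurations: "
            f"{result1.config_key} vs {result2.config_key}"
        )
    return float(result1.log_svc - result2.log_svc)


def transfer_optimum(
    theta0: np.ndarray,
    grad2: np.ndarray,
    hess1: np.ndarray,
    *,
    jitter0: float = 1e-8,
) -> np.ndarray:
    """First-order transfer of an optimum to a perturbed objective.

    Given ``theta0`` minimizing l1 (so grad l1 = 0), the minimizer of l2 is
    approximated by one implicit-function-theorem step
    ``theta0 - Hess(l1)^{-1} grad l2(theta0)``.  The Hessian factorization can
    be reused across many candidates by the caller.
    """
    theta0 = np.asarray(theta0, dtype=float)
    grad2 = np.asarray(grad2, dtype=float)
    H = (np.asarray(hess1, dtype=float) + np.asarray(hess1, dtype=float).T) / 2.0
    jitter = jitter0 * (1.0 + float(np.abs(np.diag(H)).max() if H.size else 1.0))
    for _ in range(4):
        try:
            L = np.linalg.cholesky(H)
            step = np.linalg.solve(L.T, np.linalg.solve(L, grad2))
            return theta0 - step
        except np.linalg.LinAlgError:
            H = H + jitter * np.eye(H.shape[0])
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        "Hessian is singular beyond the jitter budget; re-optimize the candidate exactly"
    )


@dataclass
class SelectionReport:
    """Per-candidate scores and include/exclude decisions of a scan."""

    reference: str
    rows: list[dict]
    config: dict
    seed: int

    @property
    def fingerprint(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df.attrs["config_fingerprint"] = self.fingerprint
        return df

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# config_fingerprint={self.fingerprint}\tseed={self.seed}\n")
            df.to_csv(fh, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "reference": self.reference,
                    "seed": self.seed,
                    "config_fingerprint": self.fingerprint,
                    "config": {k: str(v) for k, v in self.config.items()},
                    "rows": self.rows,
                },
                fh,
                indent=2,
            )

    def decisions(self) -> dict[str, str]:
        """Map candidate name -> include/exclude (for the dimension it drops)."""
        return {r["candidate"]: r["decision"] for r in self.rows if r["candidate"] != self.reference}


def _candidate_grad(obj: NKSDObjective, theta0: np.ndarray) -> np.ndarray:
    if obj.quadratic is not None:
        A, B, _ = obj.quadratic
        return 2.0 * A @ theta0 + B
    return num_grad(obj, theta0)


def _score_at(
    model: ForegroundModel,
    obj: NKSDObjective,
    theta: np.ndarray,
    *,
    backend: str,
    T: float,
    m_B: float,
    N: int,
    key: tuple,
    hessian: np.ndarray | None = None,
) -> SVCResult:
    """Backend score for a candidate at a given (possibly transferred) theta."""
    nksd = obj(theta)
    fit_term = -(N / T) * nksd
    bg = 0.5 * m_B * math.log(2.0 * math.pi / N)
    if backend == "bic":
        fg = 0.5 * model.param_dim * math.log(2.0 * math.pi / N)
        return SVCResult(fit_term + fg + bg, fit_term, fg, bg, theta, "bic",
                         model.param_dim, m_B, N, T, key)
    if backend == "laplace":
        from .svc import _laplace_logdet

        H = hessian
        if H is None:
            H = 2.0 * obj.quadratic[0] if obj.quadratic is not None else num_hessian(obj, theta)
        logdet, flags = _laplace_logdet(H / T, model.param_dim)
        if logdet is None:
            fg = 0.5 * model.param_dim * math.log(2.0 * math.pi / N)
            return SVCResult(fit_term + fg + bg, fit_term, fg, bg, theta, "bic",
                             model.param_dim, m_B, N, T, key,
                             ("laplace_fell_back_to_bic",))
        fg = (model.prior_logpdf(theta) - 0.5 * logdet
              + 0.5 * model.param_dim * math.log(2.0 * math.pi / N))
        return SVCResult(fit_term + fg + bg, fit_term, fg, bg, theta, "laplace",
                         model.param_dim, m_B, N, T, key, flags)
    raise ValueError(f"loo_scan transfer path supports bic/laplace, not {backend!r}")


def loo_scan(
    X: np.ndarray,
    model_builder: ModelBuilder,
    *,
    spec: KernelSpec = KernelSpec(),
    T: float = 1.0,
    policy: BackgroundPolicy = BackgroundPolicy(),
    backend: str = "bic",
    transfer: bool = True,
    reoptimize: bool = False,
    mb_mode: str = "policy",
    names: Sequence[str] | None = None,
    seed: int = 0,
    decision_threshold: float = 0.0,
) -> SelectionReport:
    """Leave-one-out data selection scan.

    Compares the full foreground (all d dimensions) against the d candidates
    that each drop one dimension, reporting ``log K_j - log K_0`` per
    candidate.  ``model_builder(columns)`` must return the foreground model
    for the projected data, sharing the full model's unconstrained parameter
    space so the optimum transfers by one Newton-type step (``transfer=True``,
    with optional exact re-optimization started from the transferred point).

    ``mb_mode="policy"`` charges each candidate r_B = 1 background dimension
    through the policy; ``mb_mode="match_foreground"`` instead sets
    ``m_Bj = m_F0 - m_Fj``, the device that makes the SVC ratio directly
    comparable to the conventional model-criticism score.

    A dimension is *included* when dropping it does not raise the score
    (``log K_j - log K_0 <= threshold``), ties broken toward inclusion.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, d = X.shape
    if d < 2:
        raise ValueError("leave-one-out needs at least 2 dimensions")
    if names is None:
        names = [f"dim{j + 1}" for j in range(d)]
    spec = resolve_bandwidth(X, spec, seed=seed)

    full_cols = tuple(range(d))
    model0 = model_builder(full_cols)
    obj0 = NKSDObjective(model0, X, spec)
    fit0 = fit_min_nksd(model0, X, spec, seed=seed, objective=obj0,
                        with_hessian=transfer or backend == "laplace")
    key = (float(T), int(N), spec.family, float(spec.bandwidth), spec.blocks, policy)
    ref = _score_at(model0, obj0, fit0.theta, backend=backend, T=T,
                    m_B=background_dim(policy, 0, N), N=N, key=key,
                    hessian=fit0.hessian if fit0.hessian.size else None)

    config = {
        "T": T, "backend": backend, "policy": policy, "kernel": spec,
        "transfer": transfer, "reoptimize": reoptimize, "mb_mode": mb_mode,
        "N": N, "d": d,
    }
    rows = [{
        "candidate": "full", "drops": "", "log_svc": ref.log_svc, "log_ratio": 0.0,
        "m_F": ref.m_F, "m_B": ref.m_B, "decision": "reference", "error": "",
    }]
    for j in range(d):
        cols = tuple(c for c in full_cols if c != j)
        row = {"candidate": f"drop_{names[j]}", "drops": names[j]}
        try:
            model_j = model_builder(cols)
            Xj = X[:, list(cols)]
            obj_j = NKSDObjective(model_j, Xj, spec)
            if transfer:
                grad_j = _candidate_grad(obj_j, fit0.theta)
                theta_j = transfer_optimum(fit0.theta, grad_j, fit0.hessian)
                if reoptimize:
                    fit_j = fit_min_nksd(model_j, Xj, spec, init=theta_j, seed=seed,
                                         objective=obj_j, with_hessian=backend == "laplace")
                    theta_j, hess_j = fit_j.theta, fit_j.hessian
                else:
                    hess_j = None
            else:
                fit_j = fit_min_nksd(model_j, Xj, spec, seed=seed, objective=obj_j,
                                     with_hessian=backend == "laplace")
                theta_j, hess_j = fit_j.theta, fit_j.hessian
            if mb_mode == "match_foreground":
                m_Bj = float(model0.param_dim - model_j.param_dim)
            else:
                m_Bj = background_dim(policy, 1, N)
            res_j = _score_at(model_j, obj_j, theta_j, backend=backend, T=T,
                              m_B=m_Bj, N=N, key=key, hessian=hess_j)
            ratio = res_j.log_svc - ref.log_svc
            row.update({
                "log_svc": res_j.log_svc, "log_ratio": ratio, "m_F": res_j.m_F,
                "m_B": res_j.m_B,
                "decision": "include" if ratio <= decision_threshold else "exclude",
                "error": "",
            })
        except Exception as e:  # record the failure, continue the scan
            row.update({"log_svc": float("nan"), "log_ratio": float("nan"),
                        "m_F": float("nan"), "m_B": float("nan"),
                        "decision": "error", "error": str(e)})
        rows.append(row)
    return SelectionReport(reference="full", rows=rows, config=config, seed=seed)


def subset_search(
    X: np.ndarray,
    model_builder: ModelBuilder,
    *,
    spec: KernelSpec = KernelSpec(),
    T: float = 1.0,
    policy: BackgroundPolicy = BackgroundPolicy(),
    backend: str = "variational",
    steps: int = 200,
    batch: int = 4,
    lr: float = 0.25,
    seed: int = 0,
    names: Sequence[str] | None = None,
    backend_kwargs: dict | None = None,
) -> tuple[np.ndarray, tuple[int, ...], list]:
    """Stochastic search over coordinate subsets by leave-one-out REINFORCE.

    Maintains per-dimension Bernoulli inclusion logits; each step samples
    ``batch >= 2`` subsets, scores each candidate's SVC objective (including
    the background volume of its excluded dimensions), and updates the logits
    with the leave-one-out control-variate gradient estimator.  Subset scores
    are memoized — the objective is deterministic given the config — so
    revisited subsets cost nothing.

    Returns ``(inclusion_probabilities, best_subset, trace)`` where the best
    subset is the highest-scoring one visited.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, d = X.shape
    if batch < 2:
        raise ValueError("need at least 2 subsets per step for the control variate")
    spec = resolve_bandwidth(X, spec, seed=seed)
    rng = np.random.default_rng(seed)
    backend_kwargs = dict(backend_kwargs or {})
    cache: dict[tuple[int, ...], float] = {}
    failures = 0

    def score_subset(cols: tuple[int, ...]) -> float:
        if cols in cache:
            return cache[cols]
        r_b = d - len(cols)
        if len(cols) == 0:
            val = 0.5 * background_dim(policy, r_b, N) * math.log(2.0 * math.pi / N)
        else:
            model = model_builder(cols)
            res = svc_score(model, X[:, list(cols)], spec, T, policy, r_b,
                            backend=backend, seed=seed, **backend_kwargs)
            val = res.log_svc
        cache[cols] = val
        return val

    logits = np.zeros(d)
    trace = []
    best_cols: tuple[int, ...] | None = None
    best_val = -math.inf
    for step in range(steps):
        p = 1.0 / (1.0 + np.exp(-logits))
        draws = (rng.random((batch, d)) < p[None, :]).astype(float)
        vals = np.empty(batch)
        ok = True
        for b in range(batch):
            cols = tuple(np.flatnonzero(draws[b]).tolist())
            try:
                vals[b] = score_subset(cols)
            except Exception:
                failures += 1
                if failures > 20:
                    raise RuntimeError(
                        f"subset search aborted after repeated scoring failures; trace={trace[-5:]}"
                    )
                ok = False
                break
            if math.isfinite(vals[b]) and vals[b] > best_val:
                best_val = vals[b]
                best_cols = cols
        if not ok or not np.all(np.isfinite(vals)):
            continue  # step rejected
        baseline = (vals.sum() - vals) / (batch - 1)
        g = ((vals - baseline)[:, None] * (draws - p[None, :])).mean(axis=0)
        logits = logits + lr * g
        trace.append({"step": step, "mean_score": float(vals.mean()),
                      "probs": (1.0 / (1.0 + np.exp(-logits))).tolist()})
    probs = 1.0 / (1.0 + np.exp(-logits))
    if best_cols is None:
        best_cols = tuple(np.flatnonzero(probs > 0.5).tolist())
    return probs, best_cols, trace
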