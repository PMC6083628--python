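"""Maximum likelihood for structured multivariate-normal models with missing data.

Each participant contributes the marginal density of their observed
sub-vector only (the missing-at-random marginal likelihood; no imputation).
Rows are grouped by missingness pattern so the per-iteration cost scales with
the number of distinct patterns, not the number of participants.

A model is a callable ``theta -> (mu, Sigma, dmu, dSigma)`` where ``dmu`` has
shape ``(P, D)`` and ``dSigma`` shape ``(P, D, D)`` — the analytic derivatives
of the mean vector and covariance matrix with respect to each of the ``P``
parameters.  The gradient of the negative log-likelihood follows the standard
matrix-normal identities; an optional finite-difference check lives in the
test suite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PatternGroup:
    idx: np.ndarray      # observed column indices
    data: np.ndarray     # (n_rows, len(idx)) observed values


@dataclass
class MVNFit:
    theta: np.ndarray
    nll: float
    converged: bool
    n_iter: int
    message: str


def pattern_groups(X: np.ndarray) -> list[PatternGroup]:
    """Group the rows of ``X`` (NaN = missing) by missingness pattern.

    Rows with no observed entries are dropped.
    """
    X = np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    groups: list[PatternGroup] = []
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    for p in range(patterns.shape[0]):
        idx = np.flatnonzero(patterns[p])
        if idx.size == 0:
            continue
        rows = X[inverse == p][:, idx]
        groups.append(PatternGroup(idx=idx, data=rows))
    return groups


def nll_and_grad(theta: np.ndarray, model, groups: list[PatternGroup]):
    """Total negative log-likelihood and its gradient over all patterns."""
    mu, sigma, dmu, dsigma = model(theta)
    nll = 0.0
    grad = np.zeros(len(theta))
    for g in groups:
        d = g.idx.size
        n_p = g.data.shape[0]
        s = sigma[np.ix_(g.idx, g.idx)]
        try:
            chol = np.linalg.cholesky(s)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(len(theta))
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        resid = g.data - mu[g.idx]
        z = np.linalg.solve(chol, resid.T)  # (d, n_p)
        quad = float(np.sum(z * z))
        nll += 0.5 * (n_p * (d * _LOG2PI + logdet) + quad)

        inv = np.linalg.inv(s)
        rsum = resid.sum(axis=0)
        scatter = resid.T @ resid
        m = inv @ scatter @ inv
        ds = dsigma[:, g.idx][:, :, g.idx]
        grad += 0.5 * n_p * np.einsum("ij,kij->k", inv, ds)
        grad -= 0.5 * np.einsum("ij,kij->k", m, ds)
        grad -= dmu[:, g.idx] @ (inv @ rsum)
    return nll, grad


def fit_mvn(
    model,
    theta0: np.ndarray,
    groups: list[PatternGroup],
    bounds=None,
    gtol: float = 1e-8,
    maxiter: int = 500,
) -> MVNFit:
    res = optimize.minimize(
        nll_and_grad,
        np.asarray(theta0, dtype=float),
        args=(model, groups),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-13, "gtol": gtol, "maxiter": maxiter, "maxcor": 25},
    )
    return MVNFit(
        theta=res.x,
        nll=float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
    )


def numeric_hessian(fun_grad, theta: np.ndarray, model, groups) -> np.ndarray:
    """Hessian of the NLL by central differences of the analytic gradient."""
    theta = np.asarray(theta, dtype=float)
    p = len(theta)
    hess = np.zeros((p, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = fun_grad(tp, model, groups)
        _, gm = fun_grad(tm, model, groups)
        hess[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (hess + hess.T)
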