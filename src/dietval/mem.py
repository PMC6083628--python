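"""Latent-variable measurement-error model for dietary validation studies.

Model (all on the natural-log scale).  Participant ``i`` has latent usual
intake ``T_i ~ N(mu_T, sigma2_T)``.  On occasion ``j``:

* reference (recovery biomarker or TEE surrogate): ``R_ij = T_i + u_ij``,
  ``u_ij ~ N(0, sigma2_u)`` — the unbiased-reference anchor (intercept 0,
  slope 1) that identifies the scale of ``T``;
* self-report tool ``m``: ``Q_ijm = beta0_m + beta1_m T_i + r_im + eps_ijm``
  with person-specific bias ``r_im ~ N(0, sigma2_r_m)`` (correlated across
  tools, covariance ``sigma_rAB``) and within-person error
  ``eps_ijm ~ N(0, sigma2_eps_m)``.

Parameters are estimated by maximum likelihood on each participant's observed
sub-vector of the implied multivariate normal (missing at random is handled
by marginalization, never imputation).  The optimizer works on an
unconstrained reparameterization (log variances, arctanh-scaled bias
correlation) with method-of-moments starting values; on complete balanced
data the moment estimator is itself the ML solution, because the structured
covariance spans a quadratic subspace.

Derived quantities, for a tool averaged over ``k`` repeat administrations:

* attenuation factor
  ``lambda(k) = beta1*sigma2_T / (beta1^2*sigma2_T + sigma2_r + sigma2_eps/k)``
  — the multiplier by which log relative risks estimated with the tool are
  biased toward the null;
* correlation with true intake
  ``rho(k) = beta1*sqrt(sigma2_T) / sqrt(beta1^2*sigma2_T + sigma2_r + sigma2_eps/k)``;
* mean % difference: participant means of log tool minus log reference,
  back-transformed, ``(exp(mean d) - 1) * 100`` with a t-based 95% CI.

Confidence intervals for lambda and rho come from the delta method on the
inverse observed information (default) or a participant-resampling bootstrap.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _mvn
from .config import BIOMARKER, TOOLS
from .errors import (
    ConvergenceError,
    IdentifiabilityError,
    InputError,
    UndefinedResultError,
)

__all__ = [
    "MEMParams",
    "ToolMEM",
    "fit_mem",
    "moment_estimates",
    "attenuation_factor",
    "correlation_with_truth",
    "mean_pct_difference",
    "derived_ci",
    "PctDifference",
    "ValidationResult",
]


@dataclass
class ToolMEM:
    """Bias/error parameters of one self-report tool (log scale)."""

    beta0: float
    beta1: float
    sigma2_r: float
    sigma2_eps: float


@dataclass
class MEMParams:
    """Fitted measurement-error model parameters with diagnostics."""

    mu_T: float
    sigma2_T: float
    sigma2_u: float
    tools: dict[str, ToolMEM]
    sigma_rAB: float = 0.0
    n: int = 0
    n_occasions: int = 0
    loglik: float | None = None
    converged: bool = True
    method: str = "ml"
    theta: np.ndarray | None = field(default=None, repr=False)
    theta_cov: np.ndarray | None = field(default=None, repr=False)
    tool_labels: tuple = ()


@dataclass
class PctDifference:
    value: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class ValidationResult:
    """Validation summary for one tool × nutrient."""

    tool: str
    nutrient: str
    n: int
    k: int
    attenuation: float
    attenuation_ci: tuple[float, float]
    correlation: float
    correlation_ci: tuple[float, float]
    pct_difference: float
    pct_difference_ci: tuple[float, float]
    loglik: float | None
    converged: bool


# ---------------------------------------------------------------------------
# data layout


def _wide_log_matrix(dataset, nutrient, reference=BIOMARKER, tools=TOOLS):
    """Participants × (reference, tool…) × occasion matrix of log values."""
    if nutrient not in dataset.columns:
        raise InputError(f"dataset has no column {nutrient!r}")
    insts = [reference, *tools]
    sub = dataset.loc[
        dataset["instrument"].isin(insts),
        ["participant_id", "occasion", "instrument", nutrient],
    ]
    bad = sub[sub[nutrient].notna() & (sub[nutrient] <= 0)]
    if len(bad):
        records = bad[["participant_id", "occasion", "instrument"]].head(10).to_dict("records")
        raise InputError(
            f"non-positive {nutrient!r} values cannot be log-transformed: {records}"
        )
    occasions = sorted(sub["occasion"].unique())
    if len(occasions) < 2:
        raise IdentifiabilityError(
            "at least 2 occasions are required to separate person-specific bias "
            "from within-person error"
        )
    wide = sub.pivot_table(
        index="participant_id", columns=["instrument", "occasion"], values=nutrient
    )
    cols = pd.MultiIndex.from_product([insts, occasions])
    wide = wide.reindex(columns=cols)
    X = np.log(wide.to_numpy(dtype=float))
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    ids = wide.index.to_numpy()[keep]
    n_inst_observed = sum(
        1 for b in range(len(insts)) if np.isfinite(X[:, b * len(occasions):(b + 1) * len(occasions)]).any()
    )
    if not np.isfinite(X[:, : len(occasions)]).any():
        raise IdentifiabilityError(f"no {reference!r} observations for {nutrient!r}")
    if n_inst_observed < 2:
        raise IdentifiabilityError(
            f"fewer than 2 instruments observed for {nutrient!r}; the model is unidentified"
        )
    return X, ids, len(occasions)


# ---------------------------------------------------------------------------
# moments


def moment_estimates(X: np.ndarray, K: int, tool_labels=TOOLS) -> MEMParams:
    """Closed-form method-of-moments estimates from the wide log matrix.

    Uses ML conventions (divisor n, block-averaged means) so that on complete
    balanced data these ARE the maximum-likelihood estimates.  With missing
    entries, pairwise-complete moments give starting values only.
    """
    n_tools = len(tool_labels)
    D = K * (1 + n_tools)
    if X.shape[1] != D:
        raise InputError(f"expected {D} columns, got {X.shape[1]}")
    blocks = [np.arange(b * K, (b + 1) * K) for b in range(1 + n_tools)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        block_mean = np.array([np.nanmean(X[:, b]) for b in blocks])
        center = np.repeat(block_mean, K)
        Xc = X - center
        mask = np.isfinite(Xc)
        Xz = np.where(mask, Xc, 0.0)
        counts = mask.T.astype(float) @ mask.astype(float)
        S = (Xz.T @ Xz) / np.maximum(counts, 1.0)

    def diag_mean(b):
        return float(np.mean(np.diag(S)[blocks[b]]))

    def offdiag_mean(b):
        sub = S[np.ix_(blocks[b], blocks[b])]
        return float((sub.sum() - np.trace(sub)) / (K * (K - 1)))

    def cross_mean(b1, b2):
        return float(S[np.ix_(blocks[b1], blocks[b2])].mean())

    sigma2_T = offdiag_mean(0)
    sigma2_u = diag_mean(0) - sigma2_T
    tools: dict[str, ToolMEM] = {}
    beta1s = []
    for m, label in enumerate(tool_labels, start=1):
        c = cross_mean(0, m)
        beta1 = c / sigma2_T if sigma2_T > 0 else 1.0
        b_m = offdiag_mean(m)
        sigma2_r = b_m - beta1 ** 2 * sigma2_T
        sigma2_eps = diag_mean(m) - b_m
        beta0 = block_mean[m] - beta1 * block_mean[0]
        tools[label] = ToolMEM(beta0, beta1, sigma2_r, sigma2_eps)
        beta1s.append(beta1)
    sigma_rAB = 0.0
    if n_tools == 2:
        sigma_rAB = cross_mean(1, 2) - beta1s[0] * beta1s[1] * sigma2_T
    return MEMParams(
        mu_T=float(block_mean[0]),
        sigma2_T=sigma2_T,
        sigma2_u=sigma2_u,
        tools=tools,
        sigma_rAB=sigma_rAB,
        n=X.shape[0],
        n_occasions=K,
        method="moments",
        tool_labels=tuple(tool_labels),
    )


# ---------------------------------------------------------------------------
# ML machinery


def _pack(params: MEMParams, floor: float) -> np.ndarray:
    def logv(v):
        return math.log(max(v, floor))

    theta = [params.mu_T, logv(params.sigma2_T), logv(params.sigma2_u)]
    for label in params.tool_labels:
        t = params.tools[label]
        theta += [t.beta0, t.beta1, logv(t.sigma2_r), logv(t.sigma2_eps)]
    if len(params.tool_labels) == 2:
        ta, tb = (params.tools[l] for l in params.tool_labels)
        denom = math.sqrt(max(ta.sigma2_r, floor) * max(tb.sigma2_r, floor))
        rho = np.clip(params.sigma_rAB / denom, -0.99, 0.99)
        theta.append(math.atanh(rho))
    return np.array(theta)


def _unpack(theta: np.ndarray, tool_labels, K: int) -> MEMParams:
    n_tools = len(tool_labels)
    tools = {}
    for m, label in enumerate(tool_labels):
        o = 3 + 4 * m
        tools[label] = ToolMEM(
            beta0=float(theta[o]),
            beta1=float(theta[o + 1]),
            sigma2_r=float(np.exp(theta[o + 2])),
            sigma2_eps=float(np.exp(theta[o + 3])),
        )
    sigma_rAB = 0.0
    if n_tools == 2:
        ta, tb = (tools[l] for l in tool_labels)
        sigma_rAB = float(
            np.tanh(theta[-1]) * math.sqrt(ta.sigma2_r * tb.sigma2_r)
        )
    return MEMParams(
        mu_T=float(theta[0]),
        sigma2_T=float(np.exp(theta[1])),
        sigma2_u=float(np.exp(theta[2])),
        tools=tools,
        sigma_rAB=sigma_rAB,
        n_occasions=K,
        tool_labels=tuple(tool_labels),
    )


def _mem_model(K: int, n_tools: int):
    """Build the theta -> (mu, Sigma, dmu, dSigma) callable for the fitter."""
    D = K * (1 + n_tools)
    P = 3 + 4 * n_tools + (1 if n_tools == 2 else 0)
    blocks = [np.arange(b * K, (b + 1) * K) for b in range(1 + n_tools)]
    indic = [np.zeros(D) for _ in range(1 + n_tools)]
    for b, blk in enumerate(blocks):
        indic[b][blk] = 1.0
    eye_blocks = [np.diag(v) for v in indic]
    j_blocks = [np.outer(v, v) for v in indic]
    cross = None
    if n_tools == 2:
        cross = np.outer(indic[1], indic[2]) + np.outer(indic[2], indic[1])

    def model(theta):
        mu_T = theta[0]
        s2T = np.exp(np.clip(theta[1], -40, 20))
        s2u = np.exp(np.clip(theta[2], -40, 20))
        tb = []
        for m in range(n_tools):
            o = 3 + 4 * m
            tb.append(
                (
                    theta[o],
                    theta[o + 1],
                    np.exp(np.clip(theta[o + 2], -40, 20)),
                    np.exp(np.clip(theta[o + 3], -40, 20)),
                )
            )
        w = indic[0].copy()
        for m in range(n_tools):
            w += tb[m][1] * indic[m + 1]
        sigma = s2T * np.outer(w, w) + s2u * eye_blocks[0]
        mu = mu_T * indic[0]
        for m in range(n_tools):
            b0, b1, s2r, s2e = tb[m]
            sigma += s2r * j_blocks[m + 1] + s2e * eye_blocks[m + 1]
            mu = mu + (b0 + b1 * mu_T) * indic[m + 1]
        rho = 0.0
        if n_tools == 2:
            rho = np.tanh(theta[-1])
            c_ab = rho * np.sqrt(tb[0][2] * tb[1][2])
            sigma = sigma + c_ab * cross

        dmu = np.zeros((P, D))
        dsigma = np.zeros((P, D, D))
        dmu[0] = w  # d/d mu_T
        dsigma[1] = s2T * np.outer(w, w)  # d/d log sigma2_T
        dsigma[2] = s2u * eye_blocks[0]  # d/d log sigma2_u
        for m in range(n_tools):
            o = 3 + 4 * m
            b0, b1, s2r, s2e = tb[m]
            dmu[o] = indic[m + 1]  # beta0
            dmu[o + 1] = mu_T * indic[m + 1]  # beta1 (mean part)
            dsigma[o + 1] = s2T * (
                np.outer(indic[m + 1], w) + np.outer(w, indic[m + 1])
            )
            dsigma[o + 2] = s2r * j_blocks[m + 1]
            dsigma[o + 3] = s2e * eye_blocks[m + 1]
        if n_tools == 2:
            root = np.sqrt(tb[0][2] * tb[1][2])
            dsigma[5] += 0.5 * rho * root * cross
            dsigma[9] += 0.5 * rho * root * cross
            dsigma[P - 1] = (1.0 - rho ** 2) * root * cross
        return mu, sigma, dmu, dsigma

    return model


def _fit_matrix(
    X: np.ndarray,
    K: int,
    tool_labels=TOOLS,
    theta0: np.ndarray | None = None,
    compute_cov: bool = True,
    gtol: float = 1e-8,
) -> MEMParams:
    n_tools = len(tool_labels)
    mom = moment_estimates(X, K, tool_labels)
    scale = max(mom.sigma2_T + mom.sigma2_u, 1e-12)
    degenerate_tol = 1e-10 * scale
    within = [mom.sigma2_u] + [t.sigma2_eps for t in mom.tools.values()]
    if all(v <= degenerate_tol for v in within):
        # noiseless data: the Gaussian likelihood is singular and the moment
        # solution is the exact limit of the ML estimator
        mom.converged = True
        return mom

    floor = 1e-8 * scale
    if theta0 is None:
        theta0 = _pack(mom, floor)
    model = _mem_model(K, n_tools)
    groups = _mvn.pattern_groups(X)
    P = len(theta0)
    bounds = [(None, None)] * P
    for j in (1, 2, *(3 + 4 * m + 2 for m in range(n_tools)), *(3 + 4 * m + 3 for m in range(n_tools))):
        bounds[j] = (math.log(floor) - 10.0, math.log(scale) + 10.0)
    if n_tools == 2:
        bounds[P - 1] = (-6.0, 6.0)
    fit = _mvn.fit_mvn(model, theta0, groups, bounds=bounds, gtol=gtol)
    params = _unpack(fit.theta, tool_labels, K)
    params.n = X.shape[0]
    params.loglik = -fit.nll
    params.converged = fit.converged
    params.method = "ml"
    params.theta = fit.theta
    if compute_cov:
        hess = _mvn.numeric_hessian(_mvn.nll_and_grad, fit.theta, model, groups)
        try:
            cov = np.linalg.inv(hess)
            if not np.all(np.isfinite(cov)):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
        params.theta_cov = cov
    return params


def fit_mem(
    dataset: pd.DataFrame,
    nutrient: str,
    reference: str = BIOMARKER,
    tools=TOOLS,
    compute_cov: bool = True,
) -> MEMParams:
    """Fit the measurement-error model for one nutrient by maximum likelihood.

    ``reference`` names the instrument anchored as unbiased for usual intake
    (the recovery-biomarker convention).  Missing entries are marginalized
    out under the missing-at-random assumption.  Non-convergence is flagged
    on the returned object, never silently replaced.
    """
    X, _, K = _wide_log_matrix(dataset, nutrient, reference, tools)
    return _fit_matrix(X, K, tuple(tools), compute_cov=compute_cov)


# ---------------------------------------------------------------------------
# derived quantities


def _check_k(k):
    if not (k == math.inf or k >= 1):
        raise InputError("number of administrations k must be >= 1")


def attenuation_factor(params: MEMParams, tool: str, k: float = 1) -> float:
    """Attenuation factor lambda for the mean of ``k`` repeat administrations."""
    _check_k(k)
    t = params.tools[tool]
    eps_term = 0.0 if k == math.inf else t.sigma2_eps / k
    denom = t.beta1 ** 2 * params.sigma2_T + t.sigma2_r + eps_term
    if denom <= 0:
        raise UndefinedResultError(
            f"attenuation factor undefined for {tool!r}: zero single-day variance"
        )
    return t.beta1 * params.sigma2_T / denom


def correlation_with_truth(params: MEMParams, tool: str, k: float = 1) -> float:
    """Correlation rho between the k-administration mean and usual intake."""
    _check_k(k)
    if params.sigma2_T <= 0:
        raise UndefinedResultError("correlation undefined when sigma2_T = 0")
    t = params.tools[tool]
    eps_term = 0.0 if k == math.inf else t.sigma2_eps / k
    denom = t.beta1 ** 2 * params.sigma2_T + t.sigma2_r + eps_term
    if denom <= 0:
        raise UndefinedResultError(
            f"correlation undefined for {tool!r}: zero single-day variance"
        )
    return t.beta1 * math.sqrt(params.sigma2_T) / math.sqrt(denom)


def mean_pct_difference(
    dataset: pd.DataFrame,
    tool: str,
    nutrient: str,
    reference: str = BIOMARKER,
    level: float = 0.95,
) -> PctDifference:
    """Mean % difference of the tool vs the reference, back-transformed.

    Per participant: mean of log tool values minus mean of log reference
    values over their replicates; the grand mean difference and its t-based
    CI are back-transformed as ``(exp(d) - 1) * 100``.
    """
    def participant_means(inst):
        sub = dataset.loc[
            (dataset["instrument"] == inst) & dataset[nutrient].notna(),
            ["participant_id", nutrient],
        ]
        bad = sub[sub[nutrient] <= 0]
        if len(bad):
            raise InputError(
                f"non-positive {nutrient!r} values for instrument {inst!r}"
            )
        return np.log(sub[nutrient]).groupby(sub["participant_id"]).mean()

    d = (participant_means(tool) - participant_means(reference)).dropna()
    if d.empty:
        raise InputError(
            f"no participants have both {tool!r} and {reference!r} values for {nutrient!r}"
        )
    n = len(d)
    mean = float(d.mean())
    if n > 1:
        half = stats.t.ppf(0.5 + level / 2.0, n - 1) * d.std(ddof=1) / math.sqrt(n)
    else:
        half = math.nan
    to_pct = lambda x: (math.exp(x) - 1.0) * 100.0
    return PctDifference(to_pct(mean), to_pct(mean - half), to_pct(mean + half), n)


def _functional_value(theta, tool_labels, K, functional, tool, k):
    params = _unpack(np.asarray(theta, float), tool_labels, K)
    if functional in ("attenuation", "lambda"):
        return attenuation_factor(params, tool, k)
    if functional in ("correlation", "rho"):
        return correlation_with_truth(params, tool, k)
    raise InputError(f"unknown functional {functional!r}")


def derived_ci(
    params: MEMParams,
    functional: str,
    tool: str,
    k: float = 1,
    method: str = "delta",
    dataset: pd.DataFrame | None = None,
    nutrient: str | None = None,
    reference: str = BIOMARKER,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% CI for an attenuation factor or correlation.

    ``delta`` propagates the inverse observed information through the
    functional's gradient; ``bootstrap`` refits on participant resamples and
    takes percentile limits.  A singular information matrix falls back to the
    bootstrap (with a warning) when a dataset is available.
    """
    if method not in ("delta", "bootstrap"):
        raise InputError(f"unknown CI method {method!r}")
    labels, K = params.tool_labels, params.n_occasions
    if method == "delta":
        if params.theta is None or params.theta_cov is None:
            if dataset is not None and nutrient is not None:
                warnings.warn(
                    "singular or missing information matrix; falling back to bootstrap"
                )
                method = "bootstrap"
            else:
                raise ConvergenceError(
                    "delta CI unavailable: no parameter covariance from the fit"
                )
        else:
            theta = params.theta
            f0 = _functional_value(theta, labels, K, functional, tool, k)
            grad = np.zeros(len(theta))
            for j in range(len(theta)):
                h = 1e-6 * max(1.0, abs(theta[j]))
                tp, tm = theta.copy(), theta.copy()
                tp[j] += h
                tm[j] -= h
                grad[j] = (
                    _functional_value(tp, labels, K, functional, tool, k)
                    - _functional_value(tm, labels, K, functional, tool, k)
                ) / (2.0 * h)
            var = float(grad @ params.theta_cov @ grad)
            if var < 0:
                var = 0.0
            z = stats.norm.ppf(0.5 + level / 2.0)
            half = z * math.sqrt(var)
            return (f0 - half, f0 + half)

    if dataset is None or nutrient is None:
        raise InputError("bootstrap CI requires the dataset and nutrient")
    X, _, K = _wide_log_matrix(dataset, nutrient, reference, labels)
    rng = np.random.default_rng(seed)
    values = []
    n = X.shape[0]
    for _ in range(n_boot):
        Xb = X[rng.integers(0, n, n)]
        try:
            pb = _fit_matrix(Xb, K, labels, theta0=params.theta, compute_cov=False)
            values.append(_functional_value_params(pb, functional, tool, k))
        except (IdentifiabilityError, UndefinedResultError):
            continue
    if not values:
        raise ConvergenceError("bootstrap produced no valid replicates")
    lo, hi = np.percentile(values, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return (float(lo), float(hi))


def _functional_value_params(params, functional, tool, k):
    if functional in ("attenuation", "lambda"):
        return attenuation_factor(params, tool, k)
    if functional in ("correlation", "rho"):
        return correlation_with_truth(params, tool, k)
    raise InputError(f"unknown functional {functional!r}")
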