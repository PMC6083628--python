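"""Agreement statistics: absolute-agreement ICC and log-scale Bland–Altman.

The ICC comes from a two-way mixed-effects model on occasion-level values
with the assessment method as a fixed effect,

    y_smo = mu + tau_m + b_s + g_sm + e_smo,

where ``b_s ~ N(0, sigma2_subject)`` is the subject effect, ``g_sm`` a
subject-by-method interaction with method-specific variance and ``e_smo``
a method-specific residual.  Fitting is by maximum likelihood on each
subject's observed sub-vector (same machinery as the measurement-error
model); on complete balanced data the orbit-averaged moment estimator is the
ML solution.  The absolute-agreement ICC for ``M`` fixed methods is

    ICC = sigma2_subject /
          (sigma2_subject + mean_m sigma2_int_m + mean_m sigma2_e_m
           + sum_m tau_m^2 / (M - 1)),

which penalizes systematic offsets between methods as disagreement.
Heterogeneous method variances enter through their arithmetic mean.

Bland–Altman agreement works on log-scale paired differences
``d_i = log x_i - log y_i``; the mean difference and the limits
``mean ± 1.96 sd`` are back-transformed to percentage ratios, so the limits
refer to the ratio of geometric means.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _mvn
from .errors import InputError

__all__ = [
    "MixedModelComponents",
    "AgreementResult",
    "BlandAltman",
    "fit_two_way_mixed",
    "icc_absolute",
    "bland_altman_log",
]


@dataclass
class MixedModelComponents:
    """Variance components and fixed method effects of the two-way model."""

    methods: tuple[str, ...]
    sigma2_subject: float
    sigma2_int: dict[str, float]
    sigma2_resid: dict[str, float]
    tau: dict[str, float]           # sum-to-zero fixed method effects
    grand_mean: float
    n_subjects: int
    n_occasions: int
    loglik: float | None = None
    converged: bool = True
    method: str = "ml"
    theta: np.ndarray | None = field(default=None, repr=False)


@dataclass
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class BlandAltman:
    pct_difference: float
    ci_low: float
    ci_high: float
    loa_lower: float
    loa_upper: float
    n: int


@dataclass
class AgreementResult:
    """Agreement summary for one method pair × nutrient."""

    methods: tuple[str, str]
    nutrient: str
    icc: float
    icc_ci: tuple[float, float]
    pct_difference: float
    pct_difference_ci: tuple[float, float]
    loa: tuple[float, float]
    n: int
    occasion_level: bool = True


# ---------------------------------------------------------------------------


def _to_cube(data, methods=None):
    """Coerce input to an (n_subjects, M, K) array with NaN for missing.

    Accepts an ndarray already in that shape, or a tidy DataFrame with
    columns ``subject``, ``method``, ``occasion``, ``value``.
    """
    if isinstance(data, np.ndarray):
        if data.ndim != 3:
            raise InputError("array input must have shape (subjects, methods, occasions)")
        m = data.shape[1]
        methods = tuple(methods) if methods else tuple(f"method_{i}" for i in range(m))
        return data.astype(float), methods
    df = data
    for col in ("subject", "method", "occasion", "value"):
        if col not in df.columns:
            raise InputError(f"tidy input needs a {col!r} column")
    methods = tuple(methods) if methods else tuple(pd.unique(df["method"]))
    occasions = sorted(df["occasion"].unique())
    wide = df.pivot_table(index="subject", columns=["method", "occasion"], values="value")
    cols = pd.MultiIndex.from_product([methods, occasions])
    wide = wide.reindex(columns=cols)
    cube = wide.to_numpy(float).reshape(len(wide), len(methods), len(occasions))
    return cube, methods


def _orbit_moments(X: np.ndarray, M: int, K: int):
    """Orbit-averaged moments (ML conventions) for the two-way structure."""
    blocks = [np.arange(m * K, (m + 1) * K) for m in range(M)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.array([np.nanmean(X[:, b]) for b in blocks])
        Xc = X - np.repeat(mu, K)
        mask = np.isfinite(Xc)
        Xz = np.where(mask, Xc, 0.0)
        counts = mask.T.astype(float) @ mask.astype(float)
        S = (Xz.T @ Xz) / np.maximum(counts, 1.0)
    cross = []
    for a in range(M):
        for b in range(a + 1, M):
            cross.append(S[np.ix_(blocks[a], blocks[b])].mean())
    sigma2_subject = float(np.mean(cross)) if cross else 0.0
    sigma2_int, sigma2_resid = [], []
    for m in range(M):
        sub = S[np.ix_(blocks[m], blocks[m])]
        off = (sub.sum() - np.trace(sub)) / (K * (K - 1)) if K > 1 else np.trace(sub) / K
        sigma2_int.append(float(off - sigma2_subject))
        sigma2_resid.append(float(np.trace(sub) / K - off))
    return mu, sigma2_subject, sigma2_int, sigma2_resid


def _mixed_model(M: int, K: int):
    D = M * K
    indic = []
    for m in range(M):
        v = np.zeros(D)
        v[m * K:(m + 1) * K] = 1.0
        indic.append(v)
    ones = np.ones((D, D))
    j_blocks = [np.outer(v, v) for v in indic]
    eye_blocks = [np.diag(v) for v in indic]
    P = M + 1 + 2 * M

    def model(theta):
        mu = np.repeat(theta[:M], K)
        s2s = np.exp(np.clip(theta[M], -40, 20))
        s2i = np.exp(np.clip(theta[M + 1:M + 1 + M], -40, 20))
        s2e = np.exp(np.clip(theta[M + 1 + M:], -40, 20))
        sigma = s2s * ones
        for m in range(M):
            sigma = sigma + s2i[m] * j_blocks[m] + s2e[m] * eye_blocks[m]
        dmu = np.zeros((P, D))
        dsigma = np.zeros((P, D, D))
        for m in range(M):
            dmu[m] = indic[m]
        dsigma[M] = s2s * ones
        for m in range(M):
            dsigma[M + 1 + m] = s2i[m] * j_blocks[m]
            dsigma[M + 1 + M + m] = s2e[m] * eye_blocks[m]
        return mu, sigma, dmu, dsigma

    return model


def fit_two_way_mixed(data, methods=None, heterogeneous: bool = True) -> MixedModelComponents:
    """ML fit of the two-way mixed model on occasion-level values.

    ``heterogeneous=False`` still fits method-specific variances but is
    accepted for interface compatibility; the homogeneous special case is the
    sub-model with equal components, which the ML fit covers.
    """
    X3, method_labels = _to_cube(data, methods)
    n, M, K = X3.shape
    if M < 2:
        raise InputError("at least two methods are required")
    if n < 2:
        raise InputError("at least two subjects are required")
    X = X3.reshape(n, M * K)
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    n = X.shape[0]

    mu, s2s, s2i, s2e = _orbit_moments(X, M, K)
    scale = max(s2s + max(s2i) + max(s2e), np.nanvar(X), 1e-12)
    tol = 1e-10 * scale
    if all(v <= tol for v in s2e) and all(abs(v) <= tol for v in s2i):
        # degenerate (noiseless) data: ML is singular; the moment solution is
        # the exact limit
        tau = mu - mu.mean()
        return MixedModelComponents(
            methods=method_labels,
            sigma2_subject=max(s2s, 0.0),
            sigma2_int={m: max(v, 0.0) for m, v in zip(method_labels, s2i)},
            sigma2_resid={m: max(v, 0.0) for m, v in zip(method_labels, s2e)},
            tau=dict(zip(method_labels, tau)),
            grand_mean=float(mu.mean()),
            n_subjects=n,
            n_occasions=K,
            method="moments",
        )

    floor = 1e-8 * scale
    theta0 = np.concatenate(
        [
            mu,
            [math.log(max(s2s, floor))],
            np.log(np.maximum(s2i, floor)),
            np.log(np.maximum(s2e, floor)),
        ]
    )
    model = _mixed_model(M, K)
    groups = _mvn.pattern_groups(X)
    bounds = [(None, None)] * M + [(math.log(floor) - 10.0, math.log(scale) + 10.0)] * (
        1 + 2 * M
    )
    fit = _mvn.fit_mvn(model, theta0, groups, bounds=bounds)
    mu_hat = fit.theta[:M]
    s2s = float(np.exp(fit.theta[M]))
    s2i = np.exp(fit.theta[M + 1:M + 1 + M])
    s2e = np.exp(fit.theta[M + 1 + M:])
    tau = mu_hat - mu_hat.mean()
    return MixedModelComponents(
        methods=method_labels,
        sigma2_subject=s2s,
        sigma2_int=dict(zip(method_labels, map(float, s2i))),
        sigma2_resid=dict(zip(method_labels, map(float, s2e))),
        tau=dict(zip(method_labels, map(float, tau))),
        grand_mean=float(mu_hat.mean()),
        n_subjects=n,
        n_occasions=K,
        loglik=-fit.nll,
        converged=fit.converged,
        method="ml",
        theta=fit.theta,
    )


def icc_absolute(
    components: MixedModelComponents,
    data=None,
    methods=None,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> ICCResult:
    """Absolute-agreement ICC from fitted components.

    When the underlying data are supplied, a participant-resampling bootstrap
    (percentile) CI is attached; otherwise the CI is NaN.
    """
    M = len(components.methods)
    denom_parts = (
        components.sigma2_subject
        + float(np.mean(list(components.sigma2_int.values())))
        + float(np.mean(list(components.sigma2_resid.values())))
        + sum(t ** 2 for t in components.tau.values()) / (M - 1)
    )
    if denom_parts <= 0:
        raise InputError("all variance components are zero; ICC undefined")
    icc = components.sigma2_subject / denom_parts

    lo = hi = math.nan
    if data is not None:
        cube, labels = _to_cube(data, methods or components.methods)
        rng = np.random.default_rng(seed)
        n = cube.shape[0]
        vals = []
        for _ in range(n_boot):
            comp = fit_two_way_mixed(cube[rng.integers(0, n, n)], methods=labels)
            vals.append(icc_absolute(comp).value)
        lo, hi = (
            float(v)
            for v in np.percentile(vals, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
        )
    return ICCResult(float(icc), lo, hi, components.n_subjects)


def bland_altman_log(x, y, level: float = 0.95) -> BlandAltman:
    """Log-scale Bland–Altman comparison of two paired positive series.

    Returns the % difference of geometric means with a t-based CI and the
    % limits of agreement ``exp(mean d ± 1.96 sd(d)) - 1`` (sample SD).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("paired series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise InputError("at least 2 complete pairs are required")
    bad = (x <= 0) | (y <= 0)
    if bad.any():
        raise InputError(
            f"non-positive values at pair indices {np.flatnonzero(bad)[:10].tolist()}"
        )
    d = np.log(x) - np.log(y)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    n = len(d)
    z = stats.norm.ppf(0.5 + level / 2.0)  # 1.96 at the default level
    half_ci = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / math.sqrt(n)
    pct = lambda v: (math.exp(v) - 1.0) * 100.0
    return BlandAltman(
        pct_difference=pct(mean),
        ci_low=pct(mean - half_ci),
        ci_high=pct(mean + half_ci),
        loa_lower=pct(mean - z * sd),
        loa_upper=pct(mean + z * sd),
        n=n,
    )
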