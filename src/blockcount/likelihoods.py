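"""Count-model families with block-level random intercepts and offsets.

Implements four families for per-block event counts ``y`` with a
population-at-risk offset ``N`` (coefficient fixed at 1):

``poisson``
    ``y ~ Poisson(mu)`` with ``ln mu = x'beta + ln N (+ gamma)``.
``nb``
    NB2 negative binomial, ``Var(y) = mu (1 + kappa mu)``; ``kappa -> 0``
    recovers the Poisson.
``hurdle_poisson`` / ``hurdle_nb``
    Two-part models: a logistic part for ``P(y = 0)`` (linear predictor
    ``x'alpha``, no offset) and a zero-truncated Poisson/NB part for the
    positive counts.  The two random-intercept streams are independent, so
    the marginal likelihood factorizes and each factor is integrated
    separately.

Random intercepts are integrated out of the likelihood by mode-centred,
curvature-scaled (adaptive) Gauss-Hermite quadrature; a single node is the
Laplace approximation.  Variance components and the dispersion parameter are
optimized on the log scale, so the search is unconstrained; standard errors
on the natural scale come from the delta method applied to the inverse
observed information.

The logistic part of the hurdle families models ``p = P(y = 0)``.  Under the
opposite convention (modelling ``P(y >= 1)``) every ``alpha`` coefficient
flips sign; nothing else changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, gammaln, log_expit, logsumexp
from scipy.stats import norm

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "ModelParams",
    "FitResult",
    "poisson_logpmf",
    "nb_logpmf",
    "truncated_logpmf",
    "hurdle_logpmf",
    "marginal_loglik",
    "fit",
    "aic",
    "variance_inflation",
    "predict_expected_counts",
    "predicted_count_probabilities",
]

FAMILIES = ("poisson", "nb", "hurdle_poisson", "hurdle_nb")
HURDLE_FAMILIES = ("hurdle_poisson", "hurdle_nb")
NB_FAMILIES = ("nb", "hurdle_nb")

#: below this dispersion the NB pmf switches to its Poisson limit
KAPPA_POISSON_LIMIT = 1e-7
#: probabilities are clamped to this range inside logs
PROB_EPS = 1e-12

_SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# probability mass functions
# ---------------------------------------------------------------------------


def _check_counts(y, minimum=0):
    y = np.asarray(y)
    if np.any(y < minimum):
        raise ValueError(f"counts must be >= {minimum}, got min {np.min(y)}")
    return np.asarray(y, dtype=float)


def poisson_logpmf(y, mu):
    """Log pmf of Poisson(mu) at count ``y``."""
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def nb_logpmf(y, mu, kappa):
    """Log pmf of the NB2 negative binomial at count ``y``.

    Mean ``mu``, variance ``mu (1 + kappa mu)``.  For ``kappa`` at or below
    :data:`KAPPA_POISSON_LIMIT` the Poisson limit is returned.
    """
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa <= KAPPA_POISSON_LIMIT:
        return poisson_logpmf(y, mu)
    inv = 1.0 / kappa
    l1p = np.log1p(kappa * mu)
    return (
        gammaln(y + inv)
        - gammaln(y + 1.0)
        - gammaln(inv)
        - inv * l1p
        + y * (np.log(kappa) + np.log(mu) - l1p)
    )


def _log1mexp(logp):
    """log(1 - exp(logp)) for logp <= 0, stable near both ends."""
    logp = np.asarray(logp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            logp > -np.log(2.0),
            np.log(-np.expm1(logp)),
            np.log1p(-np.exp(logp)),
        )
    return out


def _log_p0(mu, kappa):
    """log P(0) of the base (Poisson or NB) pmf."""
    mu = np.asarray(mu, dtype=float)
    if kappa is None or kappa <= KAPPA_POISSON_LIMIT:
        return -mu
    return -np.log1p(kappa * mu) / kappa


def truncated_logpmf(y, mu, kappa=None):
    """Log pmf of the zero-truncated Poisson (``kappa=None``) or NB.

    ``log[f(y) / (1 - f(0))]`` for ``y >= 1``; stable when ``f(0) ~ 1``.
    """
    y = np.asarray(y)
    if np.any(y < 1):
        raise ValueError("truncated pmf is defined for y >= 1 only")
    base = poisson_logpmf(y, mu) if kappa is None else nb_logpmf(y, mu, kappa)
    return base - _log1mexp(_log_p0(mu, kappa))


def hurdle_logpmf(y, p0, mu, kappa=None):
    """Log pmf of the hurdle model: ``p0`` at zero, else truncated count."""
    y = _check_counts(y)
    p0 = np.clip(np.asarray(p0, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    y_safe = np.maximum(y, 1.0)
    pos = truncated_logpmf(y_safe, mu, kappa) + np.log1p(-p0)
    return np.where(y == 0, np.log(p0), pos)


def aic(loglik, n_params):
    """Akaike information criterion, ``-2 logL + 2 p``."""
    if n_params < 0:
        raise ValueError("n_params must be non-negative")
    return -2.0 * loglik + 2.0 * n_params


def variance_inflation(kappa, mu, r=1.0):
    """Variance-to-mean ratio ``1 + kappa mu**(r-1)`` of the NB family.

    With the linear variance function (``r = 1``) the ratio is ``1 + kappa``
    for every ``mu``.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return 1.0 + kappa * mu ** (r - 1.0)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Family plus random-effect / design configuration for a fit."""

    family: str = "poisson"
    random_effects: bool = False
    offset_column: str = "n_tests"
    covariate_columns: Sequence[str] = ("x1", "x2", "x3")
    response_column: str = "y"
    quadrature_points: int = 7
    gtol: float = 1e-5
    max_iter: int = 500

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        q = self.quadrature_points
        if q < 1 or q % 2 == 0:
            raise ValueError("quadrature_points must be a positive odd integer")
        object.__setattr__(self, "covariate_columns", tuple(self.covariate_columns))

    @property
    def is_hurdle(self):
        return self.family in HURDLE_FAMILIES

    @property
    def is_nb(self):
        return self.family in NB_FAMILIES

    @property
    def n_params(self):
        """Free-parameter count (coefficients + kappa + variance components)."""
        k = 1 + len(self.covariate_columns)
        p = k * (2 if self.is_hurdle else 1)
        if self.is_nb:
            p += 1
        if self.random_effects:
            p += 2 if self.is_hurdle else 1
        return p


@dataclass
class ModelParams:
    """Natural-scale parameter values for one model."""

    beta: np.ndarray
    alpha: Optional[np.ndarray] = None
    kappa: Optional[float] = None
    sigma2: float = 0.0
    sigma2_zero: float = 0.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)


# ---------------------------------------------------------------------------
# likelihood parts: per-block log-likelihood and derivatives in gamma
# ---------------------------------------------------------------------------


def _count_part(y, eta, kappa):
    """(ll, d1, d2) of the untruncated count log-likelihood at eta = ln mu."""
    mu = np.exp(eta)
    if kappa is None:
        ll = y * eta - mu - gammaln(y + 1.0)
        return ll, y - mu, -mu
    km = kappa * mu
    l1p = np.log1p(km)
    inv = 1.0 / kappa
    ll = (
        gammaln(y + inv)
        - gammaln(y + 1.0)
        - gammaln(inv)
        - inv * l1p
        + y * (np.log(kappa) + eta - l1p)
    )
    d1 = (y - mu) / (1.0 + km)
    d2 = -mu * (1.0 + kappa * y) / (1.0 + km) ** 2
    return ll, d1, d2


def _trunc_part(y, eta, kappa):
    """(ll, d1, d2) of the zero-truncated count log-likelihood (y >= 1)."""
    ll, d1, d2 = _count_part(y, eta, kappa)
    mu = np.exp(eta)
    if kappa is None:
        s, s1, s2 = -mu, -mu, -mu
    else:
        km = kappa * mu
        s = -np.log1p(km) / kappa
        s1 = -mu / (1.0 + km)
        s2 = -mu / (1.0 + km) ** 2
    log1mf0 = _log1mexp(s)
    r = np.exp(s - log1mf0)  # f0 / (1 - f0)
    c1 = s1 * r
    c2 = r * (s2 + s1 * s1 * np.exp(-log1mf0))
    return ll - log1mf0, d1 + c1, d2 + c2


def _bern_part(z, eta):
    """(ll, d1, d2) of the Bernoulli zero-indicator part; p = P(y=0) = expit(eta)."""
    p = expit(eta)
    ll = z * log_expit(eta) + (1.0 - z) * log_expit(-eta)
    return ll, z - p, -p * (1.0 - p)


def _agh_logmarginal(part, sigma2, n, n_points, posterior_mean=False):
    """Per-block log of the RE-marginalized likelihood factor.

    ``part(gamma)`` returns (ll, d1, d2), broadcasting over a leading axis.
    Mode-centred, curvature-scaled Gauss-Hermite with ``n_points`` nodes;
    one node is the Laplace approximation.
    """
    inv_s2 = 1.0 / sigma2
    gam = np.zeros(n)
    for _ in range(200):
        _, d1, d2 = part(gam)
        g1 = d1 - gam * inv_s2
        g2 = np.minimum(d2 - inv_s2, -1e-10)
        step = np.clip(-g1 / g2, -2.0, 2.0)
        gam = gam + step
        if np.max(np.abs(step)) < 1e-11:
            break
    _, _, d2m = part(gam)
    shat = np.sqrt(-1.0 / np.minimum(d2m - inv_s2, -1e-10))
    t, w = hermgauss(n_points)
    nodes = gam[None, :] + _SQRT2 * shat[None, :] * t[:, None]
    ll_nodes, _, _ = part(nodes)
    g_nodes = ll_nodes - 0.5 * nodes**2 * inv_s2 - 0.5 * np.log(2.0 * np.pi * sigma2)
    logw = np.log(w)[:, None] + t[:, None] ** 2 + g_nodes
    log_int = logsumexp(logw, axis=0) + 0.5 * np.log(2.0) + np.log(shat)
    if posterior_mean:
        pw = np.exp(logw - logsumexp(logw, axis=0, keepdims=True))
        return log_int, nodes, pw
    return log_int


# ---------------------------------------------------------------------------
# marginal log-likelihood
# ---------------------------------------------------------------------------


def _design(spec, data):
    cols = list(spec.covariate_columns)
    for c in cols + [spec.response_column, spec.offset_column]:
        if c not in data.columns:
            raise ValueError(f"column {c!r} missing from the block table")
    X = data[cols].to_numpy(dtype=float) if cols else np.empty((len(data), 0))
    y = data[spec.response_column].to_numpy(dtype=float)
    offs = data[spec.offset_column].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must contain non-negative integers")
    if np.any(offs < 1):
        raise ValueError("offsets must be >= 1 (log-offset undefined at 0)")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    return X, y, np.log(offs)


def _loglik_core(spec, p, X, y, log_offs, posterior_mean=False):
    """Total marginal log-likelihood; optionally also EB modes of the REs."""
    n = len(y)
    q = spec.quadrature_points
    kappa = None
    if spec.is_nb:
        kappa = None if p.kappa is None or p.kappa <= KAPPA_POISSON_LIMIT else p.kappa
    # empirical-Bayes summaries: posterior mean of gamma, the posterior
    # expectation E[e^gamma | y] (the correct conditional rate multiplier),
    # and for hurdle the posterior zero probability E[p0 | y]
    s2 = p.sigma2 if spec.random_effects else 0.0
    eb = {
        "gamma": np.zeros(n),
        "gamma_zero": None,
        "mean_exp_gamma": np.ones(n),
        "p0_cond": None,
    }

    if not spec.is_hurdle:
        eta0 = p.beta[0] + X @ p.beta[1:] + log_offs
        if not np.all(np.isfinite(eta0)):
            return (-np.inf, eb) if posterior_mean else -np.inf
        if not spec.random_effects or p.sigma2 == 0.0:
            total = float(np.sum(_count_part(y, eta0, kappa)[0]))
        else:
            part = lambda g: _count_part(y, eta0 + g, kappa)
            out = _agh_logmarginal(part, p.sigma2, n, q, posterior_mean)
            if posterior_mean:
                out, nodes, pw = out
                eb["gamma"] = np.sum(pw * nodes, axis=0)
                eb["mean_exp_gamma"] = np.sum(pw * np.exp(nodes), axis=0)
            total = float(np.sum(out))
        return (total, eb) if posterior_mean else total

    # hurdle: independent RE streams, likelihood factorizes
    eta_a = p.alpha[0] + X @ p.alpha[1:]
    z = (y == 0).astype(float)
    if not np.all(np.isfinite(eta_a)):
        return (-np.inf, eb) if posterior_mean else -np.inf
    if not spec.random_effects or p.sigma2_zero == 0.0:
        total = float(np.sum(_bern_part(z, eta_a)[0]))
        eb["gamma_zero"] = np.zeros(n)
        eb["p0_cond"] = expit(eta_a)
    else:
        part = lambda g: _bern_part(z, eta_a + g)
        out = _agh_logmarginal(part, p.sigma2_zero, n, q, posterior_mean)
        if posterior_mean:
            out, nodes, pw = out
            eb["gamma_zero"] = np.sum(pw * nodes, axis=0)
            eb["p0_cond"] = np.sum(pw * expit(eta_a + nodes), axis=0)
        total = float(np.sum(out))

    pos = y >= 1
    if posterior_mean:
        # blocks without positive counts carry no truncated-part data, so
        # their conditional rate multiplier is the prior mean e^{s2/2}
        eb["mean_exp_gamma"] = np.full(n, np.exp(0.5 * s2))
    if np.any(pos):
        yp = y[pos]
        eta_b = p.beta[0] + X[pos] @ p.beta[1:] + log_offs[pos]
        if not np.all(np.isfinite(eta_b)):
            return (-np.inf, eb) if posterior_mean else -np.inf
        if not spec.random_effects or p.sigma2 == 0.0:
            total += float(np.sum(_trunc_part(yp, eta_b, kappa)[0]))
            if posterior_mean:
                eb["mean_exp_gamma"][pos] = 1.0
        else:
            part = lambda g: _trunc_part(yp, eta_b + g, kappa)
            out = _agh_logmarginal(part, p.sigma2, int(pos.sum()), q, posterior_mean)
            if posterior_mean:
                out, nodes, pw = out
                g_full = np.zeros(n)
                g_full[pos] = np.sum(pw * nodes, axis=0)
                eb["gamma"] = g_full
                eb["mean_exp_gamma"][pos] = np.sum(pw * np.exp(nodes), axis=0)
            total += float(np.sum(out))
    return (total, eb) if posterior_mean else total


def marginal_loglik(spec, params, data):
    """Marginal log-likelihood of ``params`` for ``data`` under ``spec``.

    Random intercepts are integrated out by adaptive Gauss-Hermite
    quadrature with ``spec.quadrature_points`` nodes; with the variance at
    zero (or ``random_effects`` off) this is exactly the fixed-effects
    log-likelihood.
    """
    X, y, log_offs = _design(spec, data)
    _validate_params(spec, params, X.shape[1])
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ll = _loglik_core(spec, params, X, y, log_offs)
    return ll


def _validate_params(spec, p, k):
    if len(p.beta) != k + 1:
        raise ValueError(f"beta must have length {k + 1}")
    if spec.is_hurdle:
        if p.alpha is None or len(p.alpha) != k + 1:
            raise ValueError(f"alpha must have length {k + 1} for hurdle families")
    if spec.is_nb and p.kappa is None:
        raise ValueError("kappa required for NB families")
    if p.sigma2 < 0 or p.sigma2_zero < 0:
        raise ValueError("variance components must be non-negative")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Maximum marginal-likelihood fit of one :class:`ModelSpec`."""

    spec: ModelSpec
    params: ModelParams
    se: ModelParams
    loglik: float
    n_params: int
    aic: float
    converged: bool
    gradient_norm: float
    n_obs: int
    block_ids: np.ndarray = None
    re_estimates: Optional[dict] = None
    _theta: np.ndarray = field(default=None, repr=False)
    _scaling: tuple = field(default=None, repr=False)

    def coef_table(self):
        """Tidy per-parameter table: estimate, SE, Wald z, two-sided p."""
        rows = []
        names = ["intercept"] + list(self.spec.covariate_columns)

        def add(part, labels, est, se):
            for i, lab in enumerate(labels):
                e = est[i] if np.ndim(est) else est
                s = se[i] if np.ndim(se) else se
                z = e / s if (s is not None and np.isfinite(s) and s > 0) else np.nan
                p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
                rows.append(
                    {"part": part, "term": lab, "estimate": e, "se": s, "z": z, "p": p}
                )

        add("count", names, self.params.beta, self.se.beta)
        if self.spec.is_hurdle:
            add("zero", names, self.params.alpha, self.se.alpha)
        if self.spec.is_nb:
            add("dispersion", ["kappa"], [self.params.kappa], [self.se.kappa])
        if self.spec.random_effects:
            add("variance", ["sigma2"], [self.params.sigma2], [self.se.sigma2])
            if self.spec.is_hurdle:
                add(
                    "variance",
                    ["sigma2_zero"],
                    [self.params.sigma2_zero],
                    [self.se.sigma2_zero],
                )
        return pd.DataFrame(rows)

    def to_dict(self):
        table = self.coef_table()
        return {
            "family": self.spec.family,
            "random_effects": self.spec.random_effects,
            "quadrature_points": self.spec.quadrature_points,
            "coefficients": table.to_dict(orient="records"),
            "loglik": self.loglik,
            "minus2_loglik": -2.0 * self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "convergence": {
                "converged": bool(self.converged),
                "gradient_norm": self.gradient_norm,
            },
        }


def _theta_layout(spec, k):
    """Slices of the internal optimizer vector (standardized scale)."""
    idx = {}
    pos = 0
    idx["beta"] = slice(pos, pos + k + 1)
    pos += k + 1
    if spec.is_hurdle:
        idx["alpha"] = slice(pos, pos + k + 1)
        pos += k + 1
    if spec.is_nb:
        idx["log_kappa"] = pos
        pos += 1
    if spec.random_effects:
        idx["log_sigma2"] = pos
        pos += 1
        if spec.is_hurdle:
            idx["log_sigma2_zero"] = pos
            pos += 1
    return idx, pos


def _unpack(spec, theta, idx):
    beta = theta[idx["beta"]]
    alpha = theta[idx["alpha"]] if spec.is_hurdle else None
    kappa = float(np.exp(theta[idx["log_kappa"]])) if spec.is_nb else None
    s2 = float(np.exp(theta[idx["log_sigma2"]])) if spec.random_effects else 0.0
    s2z = (
        float(np.exp(theta[idx["log_sigma2_zero"]]))
        if (spec.random_effects and spec.is_hurdle)
        else 0.0
    )
    return ModelParams(beta=beta, alpha=alpha, kappa=kappa, sigma2=s2, sigma2_zero=s2z)


def _coef_to_std(coef, means, sds):
    """Raw-scale coefficients (intercept first) -> standardized scale."""
    out = np.array(coef, dtype=float)
    slopes = out[1:] * sds
    out[0] = out[0] + np.sum(out[1:] * means)
    out[1:] = slopes
    return out


def _destd_matrix(means, sds):
    """Linear map taking standardized-scale coefficients to raw scale."""
    k = len(means)
    T = np.zeros((k + 1, k + 1))
    T[0, 0] = 1.0
    for j in range(k):
        T[0, j + 1] = -means[j] / sds[j]
        T[j + 1, j + 1] = 1.0 / sds[j]
    return T


def _numeric_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def _start_theta(spec, idx, size, y, log_offs, start, means, sds):
    theta0 = np.zeros(size)
    if start is not None:
        theta0[idx["beta"]] = _coef_to_std(start.beta, means, sds)
        if spec.is_hurdle and start.alpha is not None:
            theta0[idx["alpha"]] = _coef_to_std(start.alpha, means, sds)
        if spec.is_nb:
            theta0[idx["log_kappa"]] = np.log(max(start.kappa or 0.5, 1e-4))
        if spec.random_effects:
            theta0[idx["log_sigma2"]] = np.log(max(start.sigma2, 1e-3) or 0.5)
            if spec.is_hurdle:
                theta0[idx["log_sigma2_zero"]] = np.log(
                    max(start.sigma2_zero, 1e-3) or 0.5
                )
        return theta0
    # moment-based defaults
    rate = max(np.sum(y), 0.5) / np.sum(np.exp(log_offs))
    theta0[idx["beta"]][0] = np.log(rate)
    if spec.is_hurdle:
        p0 = np.clip(np.mean(y == 0), 0.02, 0.98)
        theta0[idx["alpha"]][0] = np.log(p0 / (1.0 - p0))
    if spec.is_nb:
        theta0[idx["log_kappa"]] = np.log(0.5)
    if spec.random_effects:
        theta0[idx["log_sigma2"]] = np.log(0.5)
        if spec.is_hurdle:
            theta0[idx["log_sigma2_zero"]] = np.log(0.5)
    return theta0


def fit(spec: ModelSpec, data: pd.DataFrame, start: ModelParams = None, compute_se=True):
    """Fit ``spec`` to a block table by maximum marginal likelihood.

    Quasi-Newton (BFGS) on an internally standardized covariate scale with
    log-parameterized variance components.  Random-effects fits warm-start
    from the corresponding fixed-effects fit unless ``start`` is given.
    Standard errors come from the numerically differentiated observed
    information (delta method for kappa and the variances); a singular
    information matrix yields missing SEs with a warning, never an
    exception.
    """
    X, y, log_offs = _design(spec, data)
    n, k = X.shape
    if spec.is_hurdle and (not np.any(y == 0) or not np.any(y > 0)):
        raise ValueError("hurdle fits need at least one zero and one positive count")
    means = X.mean(axis=0) if k else np.empty(0)
    sds = X.std(axis=0) if k else np.empty(0)
    if np.any(sds == 0):
        bad = [spec.covariate_columns[j] for j in np.where(sds == 0)[0]]
        raise ValueError(f"constant covariate column(s): {bad}")
    Xs = (X - means) / sds if k else X

    idx, size = _theta_layout(spec, k)
    if start is None and spec.random_effects:
        base = fit(replace(spec, random_effects=False), data, compute_se=False)
        start = base.params
        start.sigma2 = 0.5
        start.sigma2_zero = 0.5
    theta0 = _start_theta(spec, idx, size, y, log_offs, start, means, sds)

    def negll(theta):
        p = _unpack(spec, theta, idx)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll = _loglik_core(spec, p, Xs, y, log_offs)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    res = optimize.minimize(
        negll,
        theta0,
        method="BFGS",
        options={"gtol": spec.gtol, "maxiter": spec.max_iter},
    )
    theta_hat = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm <= max(spec.gtol * 100, 5e-3)
    p_std = _unpack(spec, theta_hat, idx)
    loglik = -negll(theta_hat)

    # map to the raw covariate scale
    T = _destd_matrix(means, sds)
    beta = T @ p_std.beta
    alpha = T @ p_std.alpha if spec.is_hurdle else None
    params = ModelParams(
        beta=beta,
        alpha=alpha,
        kappa=p_std.kappa,
        sigma2=p_std.sigma2,
        sigma2_zero=p_std.sigma2_zero,
    )

    se = ModelParams(
        beta=np.full(k + 1, np.nan),
        alpha=np.full(k + 1, np.nan) if spec.is_hurdle else None,
        kappa=np.nan if spec.is_nb else None,
        sigma2=np.nan,
        sigma2_zero=np.nan,
    )
    if compute_se:
        cov = None
        try:
            H = _numeric_hessian(negll, theta_hat)
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                warnings.warn("observed information not positive definite; some SEs missing")
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; standard errors missing")
        if cov is not None:
            J = np.zeros((size, size))
            J[idx["beta"], idx["beta"]] = T
            if spec.is_hurdle:
                J[idx["alpha"], idx["alpha"]] = T
            if spec.is_nb:
                J[idx["log_kappa"], idx["log_kappa"]] = params.kappa
            if spec.random_effects:
                J[idx["log_sigma2"], idx["log_sigma2"]] = params.sigma2
                if spec.is_hurdle:
                    J[idx["log_sigma2_zero"], idx["log_sigma2_zero"]] = (
                        params.sigma2_zero
                    )
            cov_nat = J @ cov @ J.T
            with np.errstate(invalid="ignore"):
                sds_nat = np.sqrt(np.diag(cov_nat))
            se.beta = sds_nat[idx["beta"]]
            if spec.is_hurdle:
                se.alpha = sds_nat[idx["alpha"]]
            if spec.is_nb:
                se.kappa = float(sds_nat[idx["log_kappa"]])
            if spec.random_effects:
                se.sigma2 = float(sds_nat[idx["log_sigma2"]])
                if spec.is_hurdle:
                    se.sigma2_zero = float(sds_nat[idx["log_sigma2_zero"]])

    re_estimates = None
    if spec.random_effects:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            _, re_estimates = _loglik_core(
                spec, p_std, Xs, y, log_offs, posterior_mean=True
            )

    block_ids = (
        data["block_id"].to_numpy() if "block_id" in data.columns else np.arange(n)
    )
    return FitResult(
        spec=spec,
        params=params,
        se=se,
        loglik=loglik,
        n_params=spec.n_params,
        aic=aic(loglik, spec.n_params),
        converged=converged,
        gradient_norm=grad_norm,
        n_obs=n,
        block_ids=block_ids,
        re_estimates=re_estimates,
        _theta=theta_hat,
        _scaling=(means, sds),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

_PRED_NODES = 41


def _gauss_expect(func, sigma2, n_points=_PRED_NODES):
    """E[func(gamma)] for gamma ~ N(0, sigma2), plain Gauss-Hermite."""
    if sigma2 <= 0:
        return func(0.0)
    t, w = hermgauss(n_points)
    vals = [wi * func(_SQRT2 * np.sqrt(sigma2) * ti) for ti, wi in zip(t, w)]
    return sum(vals) / np.sqrt(np.pi)


def _trunc_mean(mu, kappa):
    """Mean of the zero-truncated base distribution, mu / (1 - f(0))."""
    return np.exp(np.log(mu) - _log1mexp(_log_p0(mu, kappa)))


def predict_expected_counts(fit_result: FitResult, data: pd.DataFrame = None, mode="marginal"):
    """Per-block expected counts from a fitted model.

    ``marginal`` integrates the random intercepts out (for the log link this
    multiplies by ``exp(sigma2/2)``; hurdle factors are integrated by
    quadrature).  ``conditional`` plugs in the empirical-Bayes RE estimates
    and is only defined for the training blocks.
    """
    if mode not in ("marginal", "conditional"):
        raise ValueError("mode must be 'marginal' or 'conditional'")
    spec = fit_result.spec
    p = fit_result.params
    if data is None:
        raise ValueError("pass the block table to predict for")
    X, _, log_offs = _design(spec, data)
    kappa = None
    if spec.is_nb and p.kappa is not None and p.kappa > KAPPA_POISSON_LIMIT:
        kappa = p.kappa

    mean_exp = np.ones(len(data))
    p0_cond = None
    if mode == "conditional" and spec.random_effects:
        ids = data["block_id"].to_numpy() if "block_id" in data.columns else None
        if ids is None or len(ids) != len(fit_result.block_ids) or np.any(
            ids != fit_result.block_ids
        ):
            raise ValueError(
                "conditional predictions are defined for the training blocks "
                "only; use mode='marginal' for out-of-sample blocks"
            )
        mean_exp = fit_result.re_estimates["mean_exp_gamma"]
        p0_cond = fit_result.re_estimates["p0_cond"]

    eta_b = p.beta[0] + X @ p.beta[1:] + log_offs
    s2 = p.sigma2 if spec.random_effects else 0.0
    if not spec.is_hurdle:
        if mode == "marginal":
            return np.exp(eta_b + 0.5 * s2)
        # conditional mean uses E[e^gamma | y], not e^{E[gamma | y]}
        return np.exp(eta_b) * mean_exp

    eta_a = p.alpha[0] + X @ p.alpha[1:]
    s2z = p.sigma2_zero if spec.random_effects else 0.0
    if mode == "marginal":
        prob_pos = _gauss_expect(
            lambda g: 1.0 - np.clip(expit(eta_a + g), PROB_EPS, 1.0 - PROB_EPS), s2z
        )
        mean_pos = _gauss_expect(lambda g: _trunc_mean(np.exp(eta_b + g), kappa), s2)
        return prob_pos * mean_pos
    if p0_cond is None:
        p0_cond = expit(eta_a)
    p0 = np.clip(p0_cond, PROB_EPS, 1.0 - PROB_EPS)
    return (1.0 - p0) * _trunc_mean(np.exp(eta_b) * mean_exp, kappa)


def predicted_count_probabilities(fit_result: FitResult, data: pd.DataFrame, max_count: int):
    """Matrix P(y_i = j), j = 0..max_count, marginal over the random effects.

    Used by the probability-summing variant of the frequency comparison.
    """
    spec = fit_result.spec
    p = fit_result.params
    X, _, log_offs = _design(spec, data)
    kappa = None
    if spec.is_nb and p.kappa is not None and p.kappa > KAPPA_POISSON_LIMIT:
        kappa = p.kappa
    ys = np.arange(max_count + 1)
    eta_b = p.beta[0] + X @ p.beta[1:] + log_offs
    s2 = p.sigma2 if spec.random_effects else 0.0

    if not spec.is_hurdle:

        def pmf(g):
            mu = np.exp(eta_b + g)[:, None]
            base = poisson_logpmf if kappa is None else (
                lambda yy, mm: nb_logpmf(yy, mm, kappa)
            )
            return np.exp(base(ys[None, :], mu))

        return _gauss_expect(pmf, s2)

    eta_a = p.alpha[0] + X @ p.alpha[1:]
    s2z = p.sigma2_zero if spec.random_effects else 0.0
    p0 = _gauss_expect(
        lambda g: np.clip(expit(eta_a + g), PROB_EPS, 1.0 - PROB_EPS), s2z
    )

    def tpmf(g):
        mu = np.exp(eta_b + g)[:, None]
        return np.exp(truncated_logpmf(ys[None, 1:], mu, kappa))

    tp = _gauss_expect(tpmf, s2)
    out = np.empty((len(eta_b), max_count + 1))
    out[:, 0] = p0
    out[:, 1:] = (1.0 - p0)[:, None] * tp
    return out
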