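"""Weighted Gaussian linear mixed models fit by maximum likelihood.

Used for the log-response-ratio metrics (relative richness SR and relative
total abundance TA).  The model is

    y = X beta + Z_u u [+ Z_v v] + e,   e_i ~ N(0, sigma_e^2 / w_i)

with random intercepts u per source (and optionally v per study, nested in
sources) and observation weights entering as multipliers on the residual
precision — the lme4 ``weights`` convention.  The marginal covariance
V = sigma_e^2 diag(1/w) + sigma_u^2 Z_u Z_u' [+ sigma_v^2 Z_v Z_v'] is built
densely (metric tables hold at most a few hundred rows); beta is profiled
out by GLS at each variance-parameter evaluation.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg, optimize

from .beta_mixed import FitOptions
from .results import FitResult

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


def _profile_loglik(log_params, y, X, w, Zs):
    """Profile (over beta) marginal log-likelihood; returns (ll, beta, cov_beta)."""
    sigma2_e = np.exp(log_params[0])
    n = len(y)
    V = np.diag(sigma2_e / w)
    for k, Z in enumerate(Zs):
        sigma2_k = np.exp(log_params[1 + k])
        V += sigma2_k * (Z @ Z.T)
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -1e12, None, None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    try:
        cov_beta = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError:
        return -1e12, None, None
    beta = cov_beta @ (X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = linalg.cho_solve((c, low), r)
    ll = -0.5 * (n * _LOG2PI + logdet + r @ Vi_r)
    return float(ll), beta, cov_beta


def fit_gaussian_lmm(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    source_idx: np.ndarray,
    *,
    study_idx: np.ndarray | None = None,
    term_names: list[str] | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """ML fit of the weighted Gaussian mixed model.

    ``study_idx`` adds a second, study-level random intercept (nested
    structure).  A random-effect variance driven to (numerical) zero is
    pinned there and flagged ``singular`` rather than raised.
    """
    opts = options or FitOptions()
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")

    def indicator(idx):
        idx = np.asarray(idx)
        Z = np.zeros((len(idx), int(idx.max()) + 1))
        Z[np.arange(len(idx)), idx] = 1.0
        return Z

    Zs = [indicator(source_idx)]
    levels = ["source"]
    if study_idx is not None:
        Zs.append(indicator(study_idx))
        levels.append("study")

    # variance starting values from a weighted OLS residual split
    wsq = np.sqrt(w)
    beta0, *_ = np.linalg.lstsq(X * wsq[:, None], y * wsq, rcond=None)
    resid = y - X @ beta0
    tot = max(float(np.var(resid)), 1e-8)
    k_var = 1 + len(Zs)
    base = np.log(np.full(k_var, tot / k_var))

    rng = np.random.default_rng(opts.seed)
    neg = lambda lp: -_profile_loglik(lp, y, X, w, Zs)[0]
    best = None
    for start in range(opts.n_starts):
        x0 = base if start == 0 else base + rng.normal(0, 0.5, size=k_var)
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    lp = best.x
    ll, beta, cov_beta = _profile_loglik(lp, y, X, w, Zs)
    converged = bool(best.success) and beta is not None
    if beta is None:
        raise np.linalg.LinAlgError("marginal covariance not positive definite")

    p = X.shape[1]
    names = term_names or [f"x{i}" for i in range(p)]
    re_vars = {lev: float(np.exp(lp[1 + k])) for k, lev in enumerate(levels)}
    singular = any(v < 1e-8 for v in re_vars.values())
    if singular:
        logger.warning("singular fit: a random-effect variance is pinned at ~0")
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    return FitResult(
        family="gaussian",
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        cov_fixed=cov_beta,
        random_variances=re_vars,
        precision=float(np.exp(lp[0])),
        loglik=ll,
        n_obs=len(y),
        n_params=p + k_var,
        converged=converged,
        term_names=names,
        random_structure="source_study_nested" if study_idx is not None else "source_only",
        message=str(best.message),
        singular=singular,
    )
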