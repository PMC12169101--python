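"""Weighted beta-regression mixed models with a logit link.

The response (intactness or similarity after the Smithson–Verkuilen
compression) is modelled as Beta(mu_i phi, (1 - mu_i) phi) with
logit(mu_i) = x_i' beta + u_{source(i)} [+ v_{study(i)}].  Study weights
multiply the per-observation log-likelihood contributions, so a study whose
reference community samples many species counts for more.

The marginal likelihood integrates the random intercepts out numerically:

* single source-level intercept — adaptive Gauss–Hermite quadrature (the
  integration grid is recentred at the conditional mode and rescaled by the
  conditional curvature, per source), 15 nodes by default;
* nested source/study intercepts — a Laplace approximation around the joint
  conditional mode of each source's random-effect block.

Parameters (beta, ln phi, ln sigma) are maximized with BFGS from several
seeded starts; standard errors come from the inverse of a finite-difference
Hessian of the negative marginal log-likelihood at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .results import FitResult

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FitOptions:
    """Optimizer settings shared by both model families."""

    n_quad: int = 15
    n_starts: int = 3
    seed: int = 0
    gtol: float = 1e-8
    max_iter: int = 500


def _beta_loglik_terms(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
    """Per-observation beta log-density at logit-scale linear predictor eta."""
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def _beta_dloglik_deta(y: np.ndarray, eta: np.ndarray, phi: float):
    """First and second derivatives of the beta log-density w.r.t. eta."""
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    c = np.log(y) - np.log1p(-y)
    g = c - special.digamma(a) + special.digamma(b)
    dmu = mu * (1.0 - mu)
    d1 = phi * dmu * g
    gp = -phi * (special.polygamma(1, a) + special.polygamma(1, b))
    d2 = dmu * phi * ((1.0 - 2.0 * mu) * g + dmu * gp)
    return d1, d2


class _BetaMarginal:
    """Marginal log-likelihood machinery for one design.

    ``source_idx`` maps observations to sources (0..G-1); ``study_idx`` (for
    the nested structure) maps observations to studies (0..S-1), with
    ``study_source`` giving each study's source.
    """

    def __init__(self, y, X, weights, source_idx, study_idx=None, study_source=None,
                 n_quad=15):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.w = np.asarray(weights, float)
        self.source_idx = np.asarray(source_idx)
        self.n_sources = int(self.source_idx.max()) + 1
        self.study_idx = None if study_idx is None else np.asarray(study_idx)
        self.study_source = None if study_source is None else np.asarray(study_source)
        self.nodes, self.qweights = np.polynomial.hermite.hermgauss(n_quad)
        self.p = self.X.shape[1]

    # --- single random intercept: adaptive Gauss-Hermite ---

    def _objective_single(self, eta0, phi, var_u, u):
        """Per-source penalized objective f_g(u) - u^2 / (2 var)."""
        eta = eta0 + u[self.source_idx]
        terms = self.w * _beta_loglik_terms(self.y, eta, phi)
        f = np.bincount(self.source_idx, terms, minlength=self.n_sources)
        return f - u**2 / (2.0 * var_u)

    def _modes_single(self, eta0, phi, var_u, n_iter=100, tol=1e-9):
        """Per-source conditional modes of the random intercept.

        Damped Newton with per-source backtracking: every accepted step
        increases that source's penalized objective, so the modes (and hence
        the outer marginal log-likelihood) vary smoothly in the parameters.
        """
        u = np.zeros(self.n_sources)
        obj = self._objective_single(eta0, phi, var_u, u)
        for _ in range(n_iter):
            eta = eta0 + u[self.source_idx]
            d1, d2 = _beta_dloglik_deta(self.y, eta, phi)
            g = np.bincount(self.source_idx, self.w * d1, minlength=self.n_sources)
            g -= u / var_u
            h = np.bincount(self.source_idx, self.w * d2, minlength=self.n_sources)
            h -= 1.0 / var_u
            h = np.minimum(h, -1e-8)
            step = np.clip(-g / h, -10.0, 10.0)
            alpha = np.ones(self.n_sources)
            for _bt in range(20):
                cand = self._objective_single(eta0, phi, var_u, u + alpha * step)
                worse = cand < obj - 1e-13
                if not worse.any():
                    break
                alpha[worse] *= 0.5
            u = u + alpha * step
            obj = self._objective_single(eta0, phi, var_u, u)
            if np.max(np.abs(alpha * step)) < tol:
                break
        eta = eta0 + u[self.source_idx]
        _, d2 = _beta_dloglik_deta(self.y, eta, phi)
        curv = -(np.bincount(self.source_idx, self.w * d2, minlength=self.n_sources)
                 - 1.0 / var_u)
        return u, np.maximum(curv, 1e-8)

    def loglik_single(self, beta, phi, sd_u) -> float:
        eta0 = self.X @ beta
        if sd_u < 1e-8:
            return float(np.sum(self.w * _beta_loglik_terms(self.y, eta0, phi)))
        var_u = sd_u * sd_u
        uhat, curv = self._modes_single(eta0, phi, var_u)
        scale = np.sqrt(2.0 / curv)  # (G,)
        # u grid: (G, K)
        ugrid = uhat[:, None] + scale[:, None] * self.nodes[None, :]
        eta = eta0[:, None] + ugrid[self.source_idx, :]
        terms = self.w[:, None] * _beta_loglik_terms(self.y[:, None], eta, phi)
        fsum = np.zeros((self.n_sources, terms.shape[1]))
        np.add.at(fsum, self.source_idx, terms)
        # h(u) = f(u) - u^2/(2 var) ; integrand exp(h); GH with weight e^{-x^2}
        h = fsum - ugrid**2 / (2.0 * var_u)
        log_integrand = h + self.nodes[None, :] ** 2 + np.log(self.qweights)[None, :]
        log_int = special.logsumexp(log_integrand, axis=1) + np.log(scale)
        ll = np.sum(log_int) - self.n_sources * (np.log(sd_u) + 0.5 * _LOG2PI)
        return float(ll)

    # --- nested source/study intercepts: Laplace ---

    def _loglik_nested(self, beta, phi, sd_u, sd_v) -> float:
        eta0 = self.X @ beta
        var_u = max(sd_u * sd_u, 1e-12)
        var_v = max(sd_v * sd_v, 1e-12)
        n_studies = int(self.study_idx.max()) + 1
        u = np.zeros(self.n_sources)
        v = np.zeros(n_studies)
        src = self.source_idx
        stu = self.study_idx
        stu_src = self.study_source

        def objective(u_, v_):
            eta = eta0 + u_[src] + v_[stu]
            terms = self.w * _beta_loglik_terms(self.y, eta, phi)
            f = np.bincount(src, terms, minlength=self.n_sources)
            pen_v = np.bincount(stu_src, v_**2, minlength=self.n_sources)
            return f - u_**2 / (2.0 * var_u) - pen_v / (2.0 * var_v)

        obj = objective(u, v)
        for _ in range(100):
            eta = eta0 + u[src] + v[stu]
            d1, d2 = _beta_dloglik_deta(self.y, eta, phi)
            wd1 = self.w * d1
            wd2 = self.w * d2
            g_u = np.bincount(src, wd1, minlength=self.n_sources) - u / var_u
            g_v = np.bincount(stu, wd1, minlength=n_studies) - v / var_v
            # arrow-structured Hessian blocks per source
            h_uu = np.bincount(src, wd2, minlength=self.n_sources) - 1.0 / var_u
            h_vv = np.bincount(stu, wd2, minlength=n_studies) - 1.0 / var_v
            h_uv = np.bincount(stu, wd2, minlength=n_studies)  # d2 sum per study
            h_uu = np.minimum(h_uu, -1e-8)
            h_vv = np.minimum(h_vv, -1e-8)
            # solve [h_uu, h_uv; h_uv', h_vv] step = -g via the Schur complement
            ratio = h_uv / h_vv
            schur = h_uu - np.bincount(stu_src, h_uv * ratio, minlength=self.n_sources)
            schur = np.minimum(schur, -1e-8)
            rhs_u = g_u - np.bincount(stu_src, ratio * g_v, minlength=self.n_sources)
            step_u = np.clip(-rhs_u / schur, -10.0, 10.0)
            step_v = np.clip(-(g_v + h_uv * step_u[stu_src]) / h_vv, -10.0, 10.0)
            # per-source backtracking: accepted steps never lower the objective
            alpha = np.ones(self.n_sources)
            for _bt in range(20):
                cand = objective(u + alpha * step_u, v + alpha[stu_src] * step_v)
                worse = cand < obj - 1e-13
                if not worse.any():
                    break
                alpha[worse] *= 0.5
            u = u + alpha * step_u
            v = v + alpha[stu_src] * step_v
            obj = objective(u, v)
            if max(np.max(np.abs(alpha * step_u)),
                   np.max(np.abs(alpha[stu_src] * step_v))) < 1e-9:
                break
        eta = eta0 + u[src] + v[stu]
        d1, d2 = _beta_dloglik_deta(self.y, eta, phi)
        wd2 = self.w * d2
        h_uu = np.minimum(np.bincount(src, wd2, minlength=self.n_sources) - 1.0 / var_u, -1e-10)
        h_vv = np.minimum(np.bincount(stu, wd2, minlength=n_studies) - 1.0 / var_v, -1e-10)
        h_uv = np.bincount(stu, wd2, minlength=n_studies)
        # log det(-H) via Schur: det = prod(-h_vv) * prod(-(schur))
        ratio = h_uv / h_vv
        schur = np.minimum(
            h_uu - np.bincount(stu_src, h_uv * ratio, minlength=self.n_sources), -1e-10
        )
        logdet_negH = np.sum(np.log(-h_vv)) + np.sum(np.log(-schur))
        f = float(np.sum(self.w * _beta_loglik_terms(self.y, eta, phi)))
        h_at_mode = (
            f
            - np.sum(u**2) / (2 * var_u)
            - np.sum(v**2) / (2 * var_v)
        )
        dim = self.n_sources + n_studies
        ll = (
            h_at_mode
            + 0.5 * dim * _LOG2PI
            - 0.5 * logdet_negH
            - self.n_sources * (np.log(np.sqrt(var_u)) + 0.5 * _LOG2PI)
            - n_studies * (np.log(np.sqrt(var_v)) + 0.5 * _LOG2PI)
        )
        return float(ll)

    def loglik_fixed_only(self, beta, phi) -> float:
        """Weighted log-likelihood with the random-effect variance pinned at 0."""
        eta = self.X @ beta
        return float(np.sum(self.w * _beta_loglik_terms(self.y, eta, phi)))

    def loglik(self, params: np.ndarray, n_var: int) -> float:
        beta = params[: self.p]
        phi = np.exp(params[self.p])
        if not np.isfinite(phi) or phi <= 0:
            return -1e12
        # plateau rather than cliff: degenerate (zero-variance) data drive
        # phi to infinity and a hard bound would stall the optimizer mid-path
        phi = min(phi, 1e8)
        try:
            if n_var == 0:
                return self.loglik_fixed_only(beta, phi)
            if n_var == 2:
                sd_u = np.exp(params[self.p + 1])
                sd_v = np.exp(params[self.p + 2])
                return self._loglik_nested(beta, phi, sd_u, sd_v)
            sd_u = np.exp(params[self.p + 1])
            return self.loglik_single(beta, phi, sd_u)
        except (FloatingPointError, np.linalg.LinAlgError):
            return -1e12


def _numerical_hessian(f, x, eps=1e-4):
    """Central-difference Hessian of scalar f at x (scale-aware steps)."""
    n = len(x)
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_beta_mixed(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    source_idx: np.ndarray,
    *,
    study_idx: np.ndarray | None = None,
    study_source: np.ndarray | None = None,
    term_names: list[str] | None = None,
    options: FitOptions | None = None,
    random_effects: bool = True,
) -> FitResult:
    """Maximize the weighted marginal likelihood of the beta mixed model.

    Parameters
    ----------
    y:
        Responses strictly inside (0, 1) (already compressed).
    X:
        Fixed-effect design matrix.
    weights:
        Positive per-observation weights multiplying log-likelihood terms.
    source_idx:
        Observation -> source index (0-based, dense).
    study_idx, study_source:
        Present for the nested (1|source/study) structure: observation ->
        study index, and study -> source index.
    """
    opts = options or FitOptions()
    y = np.asarray(y, float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta responses must lie strictly in (0, 1); apply the transform first")
    X = np.asarray(X, float)
    nested = study_idx is not None
    model = _BetaMarginal(y, X, weights, source_idx, study_idx, study_source,
                          n_quad=opts.n_quad)
    p = X.shape[1]
    n_var = (2 if nested else 1) if random_effects else 0
    n_params = p + 1 + n_var

    # starting values: weighted least squares on the logit scale
    z = np.log(y) - np.log1p(-y)
    wsq = np.sqrt(np.asarray(weights, float))
    beta0, *_ = np.linalg.lstsq(X * wsq[:, None], z * wsq, rcond=None)
    base = np.concatenate([beta0, [np.log(5.0)], np.full(n_var, np.log(0.3))])

    rng = np.random.default_rng(opts.seed)
    best = None
    for start in range(opts.n_starts):
        x0 = base if start == 0 else base + rng.normal(0, 0.3, size=n_params)
        neg = lambda th: -model.loglik(th, n_var)
        res = optimize.minimize(
            neg, x0, method="BFGS",
            options={"gtol": opts.gtol, "maxiter": opts.max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    # simplex polish then a BFGS restart: finite-difference gradients can
    # stall on plateaus (phi at its cap) or mid-path on stiff weighted fits
    neg = lambda th: -model.loglik(th, n_var)
    best_x, best_fun, success = best.x, best.fun, bool(best.success)
    for _ in range(3):
        polish = optimize.minimize(
            neg, best_x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxfev": 300 * n_params},
        )
        if polish.fun <= best_fun:
            best_x, best_fun = polish.x, polish.fun
        retry = optimize.minimize(
            neg, best_x, method="BFGS",
            options={"gtol": opts.gtol, "maxiter": opts.max_iter},
        )
        improved = retry.fun < best_fun - 1e-10
        if retry.fun <= best_fun:
            best_x, best_fun = retry.x, retry.fun
            success = success or bool(retry.success)
        if not improved:
            break
    theta = best_x
    ll = -best_fun
    converged = bool(
        success or polish.success
        or np.linalg.norm(best.jac, np.inf) < 1e-3
    )
    if not converged:
        logger.warning("beta mixed model did not converge: %s", best.message)

    H = _numerical_hessian(neg, theta)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            # observed information not PD (optimum marginal or FD noise):
            # clip eigenvalues to restore a usable covariance
            evals, evecs = np.linalg.eigh(H)
            evals = np.maximum(evals, 1e-6)
            cov = evecs @ np.diag(1.0 / evals) @ evecs.T
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
        cov_fixed = cov[:p, :p]
    except np.linalg.LinAlgError:
        cov_fixed = np.full((p, p), np.nan)
        se_all = np.full(n_params, np.nan)
        converged = False

    names = term_names or [f"x{i}" for i in range(p)]
    rv = {}
    if n_var >= 1:
        rv["source"] = float(np.exp(theta[p + 1]) ** 2)
    if n_var == 2:
        rv["study"] = float(np.exp(theta[p + 2]) ** 2)
    return FitResult(
        family="beta_logit",
        coefficients=dict(zip(names, theta[:p])),
        standard_errors=dict(zip(names, se_all[:p])),
        cov_fixed=cov_fixed,
        random_variances=rv,
        precision=float(np.exp(theta[p])),
        loglik=ll,
        n_obs=len(y),
        n_params=n_params,
        converged=converged,
        term_names=names,
        random_structure=(
            "none" if n_var == 0
            else "source_study_nested" if nested else "source_only"
        ),
        message=str(best.message),
        singular=bool(n_var >= 1 and np.exp(theta[p + 1]) < 1e-4),
    )


def marginal_loglik_grid_oracle(
    y, X, weights, source_idx, beta, phi, sd_u, *, grid_half_width=8.0, n_grid=4001
) -> float:
    """Dense-trapezoid integration of the single-intercept marginal likelihood.

    Independent of the quadrature path: evaluates the integrand on a fine
    fixed grid (no mode adaptation) for cross-checking ``loglik_single``.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    w = np.asarray(weights, float)
    source_idx = np.asarray(source_idx)
    eta0 = X @ beta
    n_sources = int(source_idx.max()) + 1
    grid = np.linspace(-grid_half_width * sd_u, grid_half_width * sd_u, n_grid)
    ll = 0.0
    for g in range(n_sources):
        mask = source_idx == g
        contrib = np.zeros(n_grid)
        for yi, ei, wi in zip(y[mask], eta0[mask], w[mask]):
            contrib += wi * _beta_loglik_terms(np.full(n_grid, yi), ei + grid, phi)
        log_norm = -0.5 * (grid / sd_u) ** 2 - np.log(sd_u) - 0.5 * _LOG2PI
        integrand = contrib + log_norm
        m = integrand.max()
        ll += m + np.log(np.trapezoid(np.exp(integrand - m), grid))
    return float(ll)
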