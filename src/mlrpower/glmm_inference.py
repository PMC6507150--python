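"""Maximum-likelihood fitting of the two-level logistic mixed model.

The marginal likelihood integrates the conditional Bernoulli likelihood of
each cluster over its random effects,

    L_j(theta) = integral  prod_i Bernoulli(y_ij | expit(eta_ij(u)))
                           * N(u; 0, Sigma_u)  du,

which has no closed form for the logit link.  It is approximated per
cluster by adaptive Gauss-Hermite quadrature (AGQ): nodes are recentred at
the cluster's posterior mode and rescaled by the Cholesky factor of the
inverse negative Hessian there.  One quadrature node per dimension
reproduces the Laplace approximation exactly.

Fitting maximizes the AGQ log-likelihood over the fixed effects and an
unconstrained parameterization of the random-effects covariance (log
standard deviations, atanh correlation when the covariance is freed).
Wald standard errors come from the observed information (numerical Hessian
of the marginal log-likelihood) at the optimum.  Inference on the variance
components uses one-degree-of-freedom likelihood-ratio tests between
adjacent models of the random-effects ladder: none -> intercept ->
intercept + slope (slope added with the covariance fixed at zero, so
exactly one parameter is added per step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, log_ndtr
from scipy.stats import chi2

from .model_core import FixedEffects, RandomEffectsCov
from .simulate import SimulatedDataset

__all__ = [
    "ModelStructure",
    "FitResult",
    "LRTResult",
    "DegenerateDataError",
    "marginal_loglik",
    "fit",
    "wald_pvalue",
    "lrt_random_effect",
]

FIXED_NAMES = ("gamma00", "gamma10", "gamma01", "gamma11")

#: many-distinct-values cutoff below which rows are pooled into
#: (cluster, unique x) sufficient statistics — a pure speed optimization
_MAX_GROUP_LEVELS = 16

_LOG_SD_BOUNDS = (-7.0, 3.0)
_FIXED_BOUNDS = (-40.0, 40.0)


class DegenerateDataError(ValueError):
    """Raised when the outcome carries no information (e.g. constant y)."""


@dataclass(frozen=True)
class ModelStructure:
    """Which random effects the candidate model carries.

    The ladder is hierarchical: a random slope requires a random intercept,
    and freeing the intercept-slope covariance requires a random slope.
    """

    random_intercept: bool = True
    random_slope: bool = True
    free_covariance: bool = False

    def __post_init__(self) -> None:
        if self.random_slope and not self.random_intercept:
            raise ValueError("a random slope requires a random intercept")
        if self.free_covariance and not self.random_slope:
            raise ValueError("a free covariance requires a random slope")

    @property
    def n_random_dims(self) -> int:
        return int(self.random_intercept) + int(self.random_slope)

    @property
    def variance_names(self) -> tuple[str, ...]:
        names = []
        if self.random_intercept:
            names.append("sigma0_sq")
        if self.random_slope:
            names.append("sigma1_sq")
        if self.free_covariance:
            names.append("sigma01")
        return tuple(names)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    converged: bool
    n_quadrature: int
    structure: ModelStructure
    message: str = ""
    n_clusters: int = 0
    n_obs: int = 0

    def report(self) -> str:
        lines = [
            f"two-level logistic fit ({self.n_clusters} clusters, {self.n_obs} rows)",
            f"  structure: intercept={self.structure.random_intercept} "
            f"slope={self.structure.random_slope} "
            f"free_cov={self.structure.free_covariance}",
            f"  log-likelihood: {self.loglik:.6f}  (AGQ nodes/dim: {self.n_quadrature})",
            f"  converged: {self.converged}" + (f"  [{self.message}]" if self.message else ""),
        ]
        for name in FIXED_NAMES:
            se = self.std_errors.get(name, float("nan"))
            lines.append(f"  {name:9s} = {self.estimates[name]: .5f}  (SE {se:.5f})")
        for name in self.structure.variance_names:
            lines.append(f"  {name:9s} = {self.estimates[name]: .5f}")
        return "\n".join(lines)


@dataclass
class LRTResult:
    """One-df likelihood-ratio test between adjacent random-effects models."""

    statistic: float
    df: int
    p_value: float
    converged: bool = True
    loglik_full: float = float("nan")
    loglik_reduced: float = float("nan")


# ---------------------------------------------------------------------------
# design: per-cluster sufficient statistics
# ---------------------------------------------------------------------------


class _Design:
    """Per-cluster (x-group) counts and success totals, padded rectangular.

    For discrete x (binary predictors) rows collapse to a handful of groups
    per cluster; otherwise each row is its own group.  Likelihood values are
    identical either way.
    """

    def __init__(self, data: SimulatedDataset):
        if data.n_level2 < 2:
            raise DegenerateDataError("need at least 2 clusters")
        y = np.asarray(data.y)
        if y.min() == y.max():
            raise DegenerateDataError("outcome is constant; model is degenerate")
        order = np.argsort(data.cluster_id, kind="stable")
        J, n1 = data.n_level2, data.n_level1
        x = np.asarray(data.x, dtype=float)[order].reshape(J, n1)
        yy = y[order].reshape(J, n1).astype(float)
        self.z = data.cluster_z()
        self.n_clusters = J
        self.n_obs = J * n1

        uniq = np.unique(x)
        if uniq.size <= _MAX_GROUP_LEVELS:
            G = uniq.size
            idx = np.searchsorted(uniq, x)  # (J, n1) group index
            n = np.zeros((J, G))
            s = np.zeros((J, G))
            rows = np.repeat(np.arange(J), n1)
            np.add.at(n, (rows, idx.ravel()), 1.0)
            np.add.at(s, (rows, idx.ravel()), yy.ravel())
            self.xg = np.broadcast_to(uniq, (J, G)).copy()
            self.n = n
            self.s = s
        else:
            self.xg = x
            self.n = np.ones_like(x)
            self.s = yy

    # linear predictor offsets per cluster for given fixed effects
    def ab(self, gam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = gam[0] + gam[2] * self.z
        b = gam[1] + gam[3] * self.z
        return a, b


def _softplus(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def _cond_loglik(design: _Design, a, b, u0, u1) -> np.ndarray:
    """Conditional Bernoulli log-likelihood per cluster.

    a, b: (J,) fixed offsets; u0, u1: (J, K) random-effect values.
    Returns (J, K).
    """
    eta = (a + u0.T).T[:, :, None] + ((b + u1.T).T[:, :, None]) * design.xg[:, None, :]
    return np.sum(
        design.s[:, None, :] * eta - design.n[:, None, :] * _softplus(eta), axis=2
    )


# ---------------------------------------------------------------------------
# posterior modes (vectorized damped Newton, log-concave objective)
# ---------------------------------------------------------------------------


def _modes_1d(design: _Design, a, b, s0_sq: float):
    """Mode and negative Hessian of log p(y_j|u) + log N(u;0,s0) per cluster."""
    J = design.n_clusters
    u = np.zeros(J)

    def obj(u):
        eta = (a + u)[:, None] + b[:, None] * design.xg
        return (
            np.sum(design.s * eta - design.n * _softplus(eta), axis=1)
            - 0.5 * u * u / s0_sq
        )

    f = obj(u)
    for _ in range(100):
        eta = (a + u)[:, None] + b[:, None] * design.xg
        p = expit(eta)
        g = np.sum(design.s - design.n * p, axis=1) - u / s0_sq
        w = np.sum(design.n * p * (1.0 - p), axis=1) + 1.0 / s0_sq
        step = g / w
        np.clip(step, -5.0, 5.0, out=step)
        t = np.ones(J)
        for _ in range(30):
            f_new = obj(u + t * step)
            bad = f_new < f - 1e-12
            if not bad.any():
                break
            t[bad] *= 0.5
        u = u + t * step
        f = obj(u)
        if np.max(np.abs(g)) < 1e-10:
            break
    eta = (a + u)[:, None] + b[:, None] * design.xg
    p = expit(eta)
    neg_hess = np.sum(design.n * p * (1.0 - p), axis=1) + 1.0 / s0_sq
    return u, neg_hess


def _modes_2d(design: _Design, a, b, Sinv: np.ndarray):
    """2-D posterior modes; returns modes (J,2) and negative Hessians (J,2,2)."""
    J = design.n_clusters
    u = np.zeros((J, 2))

    def obj(u):
        eta = (a + u[:, 0])[:, None] + (b + u[:, 1])[:, None] * design.xg
        quad = np.einsum("ji,ik,jk->j", u, Sinv, u)
        return np.sum(design.s * eta - design.n * _softplus(eta), axis=1) - 0.5 * quad

    f = obj(u)
    for _ in range(100):
        eta = (a + u[:, 0])[:, None] + (b + u[:, 1])[:, None] * design.xg
        p = expit(eta)
        r = design.s - design.n * p
        g0 = np.sum(r, axis=1) - (u @ Sinv)[:, 0]
        g1 = np.sum(r * design.xg, axis=1) - (u @ Sinv)[:, 1]
        w = design.n * p * (1.0 - p)
        h00 = np.sum(w, axis=1) + Sinv[0, 0]
        h01 = np.sum(w * design.xg, axis=1) + Sinv[0, 1]
        h11 = np.sum(w * design.xg**2, axis=1) + Sinv[1, 1]
        det = h00 * h11 - h01 * h01
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        norm = np.hypot(step0, step1)
        scale = np.minimum(1.0, 5.0 / np.maximum(norm, 1e-300))
        step = np.column_stack([step0 * scale, step1 * scale])
        t = np.ones(J)
        for _ in range(30):
            f_new = obj(u + t[:, None] * step)
            bad = f_new < f - 1e-12
            if not bad.any():
                break
            t[bad] *= 0.5
        u = u + t[:, None] * step
        f = obj(u)
        if max(np.max(np.abs(g0)), np.max(np.abs(g1))) < 1e-10:
            break
    eta = (a + u[:, 0])[:, None] + (b + u[:, 1])[:, None] * design.xg
    p = expit(eta)
    w = design.n * p * (1.0 - p)
    neg_hess = np.empty((J, 2, 2))
    neg_hess[:, 0, 0] = np.sum(w, axis=1) + Sinv[0, 0]
    neg_hess[:, 0, 1] = neg_hess[:, 1, 0] = np.sum(w * design.xg, axis=1) + Sinv[0, 1]
    neg_hess[:, 1, 1] = np.sum(w * design.xg**2, axis=1) + Sinv[1, 1]
    return u, neg_hess


# ---------------------------------------------------------------------------
# marginal log-likelihood by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


def _loglik_no_random(design: _Design, gam: np.ndarray) -> float:
    a, b = design.ab(gam)
    eta = a[:, None] + b[:, None] * design.xg
    return float(np.sum(design.s * eta - design.n * _softplus(eta)))


def _loglik_1d(design: _Design, gam, s0_sq: float, K: int) -> float:
    a, b = design.ab(gam)
    mu, neg_h = _modes_1d(design, a, b, s0_sq)
    nodes, weights = hermgauss(K)
    c = 1.0 / np.sqrt(neg_h)  # (J,)
    u = mu[:, None] + math.sqrt(2.0) * c[:, None] * nodes  # (J, K)
    cll = _cond_loglik(design, a, b, u, np.zeros_like(u))
    log_f = cll - 0.5 * np.log(2.0 * math.pi * s0_sq) - 0.5 * u * u / s0_sq
    log_terms = np.log(weights) + nodes**2 + log_f
    m = log_terms.max(axis=1)
    log_int = m + np.log(np.sum(np.exp(log_terms - m[:, None]), axis=1))
    return float(np.sum(0.5 * math.log(2.0) + np.log(c) + log_int))


def _loglik_2d(design: _Design, gam, Sigma: np.ndarray, K: int) -> float:
    a, b = design.ab(gam)
    det_S = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
    if det_S <= 0 or Sigma[0, 0] <= 0 or Sigma[1, 1] <= 0:
        raise ValueError("random-effects covariance must be positive definite")
    Sinv = np.array(
        [[Sigma[1, 1], -Sigma[0, 1]], [-Sigma[0, 1], Sigma[0, 0]]]
    ) / det_S
    mu, neg_h = _modes_2d(design, a, b, Sinv)

    # analytic 2x2 inverse + Cholesky of (neg_h)^-1 per cluster
    det_h = neg_h[:, 0, 0] * neg_h[:, 1, 1] - neg_h[:, 0, 1] ** 2
    inv00 = neg_h[:, 1, 1] / det_h
    inv01 = -neg_h[:, 0, 1] / det_h
    inv11 = neg_h[:, 0, 0] / det_h
    c00 = np.sqrt(inv00)
    c10 = inv01 / c00
    c11 = np.sqrt(np.maximum(inv11 - c10**2, 1e-300))

    nodes, weights = hermgauss(K)
    XI0, XI1 = np.meshgrid(nodes, nodes, indexing="ij")
    xi0, xi1 = XI0.ravel(), XI1.ravel()  # (K^2,)
    logw = np.add.outer(np.log(weights), np.log(weights)).ravel() + xi0**2 + xi1**2

    r2 = math.sqrt(2.0)
    u0 = mu[:, 0][:, None] + r2 * c00[:, None] * xi0  # (J, K^2)
    u1 = mu[:, 1][:, None] + r2 * (c10[:, None] * xi0 + c11[:, None] * xi1)

    cll = _cond_loglik(design, a, b, u0, u1)
    quad = (
        Sinv[0, 0] * u0**2 + 2.0 * Sinv[0, 1] * u0 * u1 + Sinv[1, 1] * u1**2
    )
    log_f = cll - math.log(2.0 * math.pi) - 0.5 * math.log(det_S) - 0.5 * quad
    log_terms = logw + log_f
    m = log_terms.max(axis=1)
    log_int = m + np.log(np.sum(np.exp(log_terms - m[:, None]), axis=1))
    log_det_C = np.log(c00) + np.log(c11)
    return float(np.sum(math.log(2.0) + log_det_C + log_int))


def _loglik(design: _Design, gam, Sigma, structure: ModelStructure, K: int) -> float:
    if structure.n_random_dims == 0:
        return _loglik_no_random(design, gam)
    if structure.n_random_dims == 1:
        return _loglik_1d(design, gam, Sigma[0, 0], K)
    return _loglik_2d(design, gam, Sigma, K)


def marginal_loglik(
    params: dict[str, float],
    data: SimulatedDataset,
    structure: ModelStructure | None = None,
    n_quadrature: int = 7,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood at a parameter point.

    ``params`` holds the fixed effects (gamma00, gamma10, gamma01, gamma11)
    and the applicable covariance entries (sigma0_sq, sigma1_sq, sigma01).
    ``n_quadrature`` is the node count per random-effect dimension; 1 gives
    the Laplace approximation.
    """
    if structure is None:
        structure = ModelStructure()
    n_quadrature = int(n_quadrature)
    if n_quadrature < 1:
        raise ValueError("n_quadrature must be a positive integer")
    gam = np.array([params.get(k, 0.0) for k in FIXED_NAMES], dtype=float)
    cov = RandomEffectsCov(
        sigma0_sq=params.get("sigma0_sq", 0.0) if structure.random_intercept else 0.0,
        sigma1_sq=params.get("sigma1_sq", 0.0) if structure.random_slope else 0.0,
        sigma01=params.get("sigma01", 0.0) if structure.free_covariance else 0.0,
    )
    design = _Design(data)
    if structure.random_intercept and cov.sigma0_sq <= 0:
        raise ValueError("sigma0_sq must be > 0 for a random-intercept model")
    if structure.random_slope and cov.sigma1_sq <= 0:
        raise ValueError("sigma1_sq must be > 0 for a random-slope model")
    return _loglik(design, gam, cov.matrix(), structure, n_quadrature)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _unpack(theta: np.ndarray, structure: ModelStructure):
    gam = theta[:4]
    d = structure.n_random_dims
    Sigma = np.zeros((2, 2))
    if d >= 1:
        sd0 = math.exp(theta[4])
        Sigma[0, 0] = sd0 * sd0
    if d == 2:
        sd1 = math.exp(theta[5])
        Sigma[1, 1] = sd1 * sd1
        if structure.free_covariance:
            rho = math.tanh(theta[6])
            Sigma[0, 1] = Sigma[1, 0] = rho * sd0 * sd1
    return gam, Sigma


def _n_params(structure: ModelStructure) -> int:
    return 4 + structure.n_random_dims + int(structure.free_covariance)


def _bounds(structure: ModelStructure):
    bounds = [_FIXED_BOUNDS] * 4
    bounds += [_LOG_SD_BOUNDS] * structure.n_random_dims
    if structure.free_covariance:
        bounds += [(-5.0, 5.0)]
    return bounds


def _plain_logistic_start(design: _Design) -> np.ndarray:
    """Newton fit of the fixed-effects-only logistic model (MoM-style start)."""
    gam = np.zeros(4)
    for _ in range(25):
        a, b = design.ab(gam)
        eta = a[:, None] + b[:, None] * design.xg
        p = expit(eta)
        r = design.s - design.n * p
        w = design.n * p * (1.0 - p)
        X = [
            np.ones_like(design.xg),
            design.xg,
            np.broadcast_to(design.z[:, None], design.xg.shape),
            design.z[:, None] * design.xg,
        ]
        g = np.array([np.sum(r * Xk) for Xk in X])
        H = np.array([[np.sum(w * Xa * Xb) for Xb in X] for Xa in X])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -3.0, 3.0)
        gam = gam + step
        if np.max(np.abs(g)) < 1e-9:
            break
    return np.clip(gam, -10.0, 10.0)


def _mom_start(design: _Design, structure: ModelStructure) -> np.ndarray:
    theta = np.zeros(_n_params(structure))
    theta[:4] = _plain_logistic_start(design)
    # crude intercept-variance guess: spread of clamped cluster-level logits
    if structure.random_intercept:
        pbar = np.clip(
            design.s.sum(axis=1) / design.n.sum(axis=1), 0.02, 0.98
        )
        v = max(np.var(np.log(pbar / (1.0 - pbar))), 0.05)
        theta[4] = 0.5 * math.log(min(v, 10.0))
    if structure.random_slope:
        theta[5] = 0.5 * math.log(0.3)
    return theta


def fit(
    data: SimulatedDataset,
    structure: ModelStructure | None = None,
    *,
    n_quadrature: int = 7,
    compute_se: bool = True,
    gtol: float = 1e-5,
    maxiter: int = 300,
) -> FitResult:
    """Maximum marginal likelihood fit.

    Optimizes with L-BFGS-B on the unconstrained scale (log-SDs, atanh
    correlation), starting from zeros and — if that start fails to converge —
    from a method-of-moments-style start (plain-logistic fixed effects plus a
    cluster-logit variance guess).  Wald standard errors for the fixed
    effects come from the inverse observed information at the optimum.
    """
    if structure is None:
        structure = ModelStructure()
    design = _Design(data)
    if design.n_clusters < 2:
        raise DegenerateDataError("need at least 2 clusters")

    def nll(theta):
        gam, Sigma = _unpack(theta, structure)
        try:
            return -_loglik(design, gam, Sigma, structure, n_quadrature)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e12

    bounds = _bounds(structure)
    starts = [np.zeros(_n_params(structure)), _mom_start(design, structure)]
    results = []
    messages = []
    for k, theta0 in enumerate(starts):
        res = optimize.minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            jac="3-point",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
        )
        messages.append(f"start {k}: {res.message}")
        results.append(res)
        if res.success and np.isfinite(res.fun) and res.fun < 1e11:
            break  # first converged start wins; second is the rescue
    ok = [r for r in results if r.success and np.isfinite(r.fun) and r.fun < 1e11]
    best = min(ok, key=lambda r: r.fun) if ok else min(results, key=lambda r: r.fun)
    converged = bool(ok)
    theta = np.asarray(best.x, dtype=float)
    gam, Sigma = _unpack(theta, structure)

    estimates = dict(zip(FIXED_NAMES, gam))
    if structure.random_intercept:
        estimates["sigma0_sq"] = Sigma[0, 0]
    if structure.random_slope:
        estimates["sigma1_sq"] = Sigma[1, 1]
    if structure.free_covariance:
        estimates["sigma01"] = Sigma[0, 1]

    std_errors: dict[str, float] = {}
    message = "; ".join(messages)
    if converged and compute_se:
        try:
            H = _numerical_hessian(nll, theta)
            cov_theta = np.linalg.inv(H)
            var_fixed = np.diag(cov_theta)[:4]
            if np.any(var_fixed <= 0) or not np.all(np.isfinite(var_fixed)):
                raise np.linalg.LinAlgError("non-positive information")
            std_errors = dict(zip(FIXED_NAMES, np.sqrt(var_fixed)))
        except np.linalg.LinAlgError:
            converged = False
            message += "; observed information not positive definite"

    return FitResult(
        estimates={k: float(v) for k, v in estimates.items()},
        std_errors={k: float(v) for k, v in std_errors.items()},
        loglik=float(-best.fun),
        converged=converged,
        n_quadrature=n_quadrature,
        structure=structure,
        message=message,
        n_clusters=design.n_clusters,
        n_obs=design.n_obs,
    )


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def wald_pvalue(fit_result: FitResult, coefficient: str) -> float:
    """Two-sided Wald p-value for one fixed-effect coefficient."""
    if coefficient not in FIXED_NAMES:
        raise ValueError(
            f"coefficient must be one of {FIXED_NAMES}, got {coefficient!r}"
        )
    if not fit_result.converged:
        raise ValueError("fit did not converge; Wald inference unavailable")
    est = fit_result.estimates[coefficient]
    se = fit_result.std_errors[coefficient]
    zval = abs(est) / se
    # 2 * upper-tail normal probability, computed in log space for stability
    return float(min(1.0, 2.0 * math.exp(log_ndtr(-zval))))


def lrt_pvalue(statistic: float) -> float:
    """Upper-tail chi-square(1) probability of a (floored) LRT statistic."""
    return float(chi2.sf(max(statistic, 0.0), 1))


def lrt_random_effect(
    data: SimulatedDataset,
    target: str,
    *,
    n_quadrature: int = 7,
    full_fit: FitResult | None = None,
    reduced_fit: FitResult | None = None,
) -> LRTResult:
    """One-df LRT for a variance component on the random-effects ladder.

    ``intercept_variance``: random-intercept model vs plain logistic
    regression.  ``slope_variance``: intercept+slope model (covariance fixed
    at 0) vs intercept-only model.  The statistic 2*(llf - llr) is floored
    at zero; the reference distribution is chi-square(1), which is known to
    be conservative for a variance on its boundary.

    Precomputed fits for the full/reduced models may be passed to avoid
    refitting.
    """
    if target == "intercept_variance":
        full_struct = ModelStructure(random_intercept=True, random_slope=False)
        red_struct = ModelStructure(random_intercept=False, random_slope=False)
    elif target == "slope_variance":
        full_struct = ModelStructure(random_intercept=True, random_slope=True)
        red_struct = ModelStructure(random_intercept=True, random_slope=False)
    else:
        raise ValueError(
            "target must be 'intercept_variance' or 'slope_variance', "
            f"got {target!r}"
        )
    if full_fit is None:
        full_fit = fit(data, full_struct, n_quadrature=n_quadrature, compute_se=False)
    if reduced_fit is None:
        reduced_fit = fit(data, red_struct, n_quadrature=n_quadrature, compute_se=False)
    stat = max(0.0, 2.0 * (full_fit.loglik - reduced_fit.loglik))
    return LRTResult(
        statistic=stat,
        df=1,
        p_value=lrt_pvalue(stat),
        converged=bool(full_fit.converged and reduced_fit.converged),
        loglik_full=full_fit.loglik,
        loglik_reduced=reduced_fit.loglik,
    )
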