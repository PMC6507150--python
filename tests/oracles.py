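"""Independent brute-force oracles used to validate the AGQ likelihood.

These deliberately avoid the package's quadrature machinery: integrals are
computed by dense trapezoid grids over the random effects, cluster by
cluster, directly from the model density.
"""

import math

import numpy as np
from scipy.special import expit


def _cluster_arrays(data):
    for j in range(data.n_level2):
        m = data.cluster_id == j
        yield data.x[m], data.y[m], data.z[m][0]


def dense_loglik_1d(params, data, n_grid=4001, span=10.0):
    """Trapezoid integration of the random-intercept marginal likelihood."""
    sd = math.sqrt(params["sigma0_sq"])
    u = np.linspace(-span * sd, span * sd, n_grid)
    total = 0.0
    for x, y, z in _cluster_arrays(data):
        a = params["gamma00"] + params["gamma01"] * z
        b = params["gamma10"] + params["gamma11"] * z
        eta = (a + u[:, None]) + b * x[None, :]
        p = expit(eta)
        ll = np.sum(np.where(y == 1, np.log(p), np.log1p(-p)), axis=1)
        phi = np.exp(-0.5 * (u / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        total += math.log(np.trapezoid(np.exp(ll) * phi, u))
    return total


def dense_loglik_2d(params, data, n_grid=401, span=8.0):
    """2-D trapezoid integration for random intercept + slope (sigma01=0)."""
    sd0 = math.sqrt(params["sigma0_sq"])
    sd1 = math.sqrt(params["sigma1_sq"])
    u0 = np.linspace(-span * sd0, span * sd0, n_grid)
    u1 = np.linspace(-span * sd1, span * sd1, n_grid)
    U0, U1 = np.meshgrid(u0, u1, indexing="ij")
    phi = np.exp(-0.5 * ((U0 / sd0) ** 2 + (U1 / sd1) ** 2)) / (
        2 * math.pi * sd0 * sd1
    )
    total = 0.0
    for x, y, z in _cluster_arrays(data):
        a = params["gamma00"] + params["gamma01"] * z
        b = params["gamma10"] + params["gamma11"] * z
        eta = (a + U0[:, :, None]) + (b + U1[:, :, None]) * x[None, None, :]
        p = expit(eta)
        ll = np.sum(np.where(y == 1, np.log(p), np.log1p(-p)), axis=2)
        integral = np.trapezoid(np.trapezoid(np.exp(ll) * phi, u1, axis=1), u0)
        total += math.log(integral)
    return total


def laplace_loglik_1d(params, data):
    """Independently coded Laplace approximation (1-D random intercept).

    Modes are found by scipy's scalar minimizer, not the package's Newton
    iteration.
    """
    from scipy.optimize import minimize_scalar

    s0 = params["sigma0_sq"]
    total = 0.0
    for x, y, z in _cluster_arrays(data):
        a = params["gamma00"] + params["gamma01"] * z
        b = params["gamma10"] + params["gamma11"] * z

        def neg_logf(u):
            eta = (a + u) + b * x
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            return -(ll - 0.5 * u * u / s0 - 0.5 * math.log(2 * math.pi * s0))

        res = minimize_scalar(neg_logf, bounds=(-30, 30), method="bounded",
                              options={"xatol": 1e-12})
        u_hat = res.x
        eta = (a + u_hat) + b * x
        p = expit(eta)
        neg_hess = np.sum(p * (1 - p)) + 1.0 / s0
        total += -res.fun + 0.5 * math.log(2 * math.pi) - 0.5 * math.log(neg_hess)
    return total
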