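"""Poisson mixed model with a single random intercept, fit by maximum likelihood.

The model for plant *i* in site (group) *g* is

    y_gi | u_g ~ Poisson(mu_gi),   log mu_gi = x_gi' beta + u_g,
    u_g ~ Normal(0, sigma^2),

with the marginal likelihood integrated over u_g by Gauss-Hermite
quadrature (non-adaptive; adequate for the small group counts and moderate
random-effect variances this pipeline sees). Nested models are compared by
likelihood-ratio chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = ["PoissonGLMMFit", "fit_poisson_glmm", "likelihood_ratio_test"]


@dataclass
class PoissonGLMMFit:
    beta: np.ndarray  # fixed-effect coefficients, aligned with X columns
    sigma: float  # random-intercept standard deviation
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    exog_names: tuple[str, ...]


def _marginal_loglik(
    beta: np.ndarray,
    sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    group_slices: list[np.ndarray],
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    eta = X @ beta
    u = np.sqrt(2.0) * sigma * nodes  # (Q,)
    total = 0.0
    for idx in group_slices:
        # log Poisson likelihood of the group at each quadrature point
        lam = eta[idx][None, :] + u[:, None]  # (Q, n_g)
        ll = y[idx][None, :] * lam - np.exp(lam) - special.gammaln(y[idx] + 1.0)[None, :]
        total += special.logsumexp(log_weights + ll.sum(axis=1))
    return total


def fit_poisson_glmm(
    y,
    X,
    groups,
    exog_names: tuple[str, ...] | None = None,
    n_quad: int = 25,
) -> PoissonGLMMFit:
    """ML fit of a random-intercept Poisson model.

    Parameters
    ----------
    y : array of counts
    X : (n, p) design matrix including the intercept column
    groups : group label per observation (the random-effect factor)
    n_quad : Gauss-Hermite quadrature order
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("random intercept unidentifiable with a single site")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    group_slices = [np.flatnonzero(groups == g) for g in labels]
    nodes, weights = hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    # start at the fixed-effects-only Poisson solution
    from statsmodels.api import GLM, families

    glm = GLM(y, X, family=families.Poisson()).fit()
    x0 = np.concatenate([glm.params, [0.3]])

    def neg_loglik(theta):
        beta, sigma = theta[:-1], theta[-1]
        return -_marginal_loglik(beta, sigma, y, X, group_slices, nodes, log_weights)

    bounds = [(None, None)] * X.shape[1] + [(1e-8, 10.0)]
    res = optimize.minimize(neg_loglik, x0, method="L-BFGS-B", bounds=bounds)
    names = exog_names or tuple(f"x{i}" for i in range(X.shape[1]))
    return PoissonGLMMFit(
        beta=res.x[:-1],
        sigma=float(res.x[-1]),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_obs=y.size,
        n_groups=labels.size,
        exog_names=tuple(names),
    )


def likelihood_ratio_test(
    full: PoissonGLMMFit, null: PoissonGLMMFit, df: int | None = None
) -> tuple[float, float, int]:
    """(LR statistic, p-value, df) for nested random-intercept Poisson fits.

    The statistic is clamped at zero against optimizer round-off (it is
    non-negative for truly nested models).
    """
    if df is None:
        df = len(full.beta) - len(null.beta)
    if df <= 0:
        raise ValueError("full model must have more fixed effects than the null")
    lr = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(lr, df))
    return lr, p, df
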