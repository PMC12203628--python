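"""Independent reference computations used only to check the package.

These deliberately avoid the package's own code paths: the marginal
likelihood of the two-level random-intercept logit is computed by
Gauss-Hermite quadrature, and the exact posterior over (beta0, sigma2) by
brute-force two-dimensional grid integration of that marginal likelihood.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

_NODES, _WEIGHTS = np.polynomial.hermite.hermgauss(40)
_LOGW = np.log(_WEIGHTS / np.sqrt(np.pi))


def _cluster_loglik(beta0, sigma2, y, n):
    """Log marginal likelihood of 2-level binomial clusters via GH quadrature."""
    eta = beta0 + np.sqrt(2.0 * sigma2) * _NODES
    ll_q = y[:, None] * eta[None, :] - n[:, None] * np.logaddexp(0, eta)[None, :]
    return float(np.sum(logsumexp(ll_q + _LOGW[None, :], axis=1)))


def gh_mle_two_level(y, n):
    """Maximum-likelihood (beta0, sigma2) for the 2-level random-intercept logit."""
    res = minimize(
        lambda par: -_cluster_loglik(par[0], np.exp(par[1]), y, n),
        [0.0, 0.0],
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8},
    )
    return float(res.x[0]), float(np.exp(res.x[1]))


def exact_posterior_mean_two_level(
    y, n, prior_shape=0.001, prior_scale=0.001, b0_range=(-2.0, 2.0), s2_range=(0.005, 8.0)
):
    """Exact posterior means of (beta0, sigma2) under flat x inverse-gamma priors.

    Brute-force 2-D integration on a (beta0, log sigma2) grid of the
    GH-marginalised likelihood; independent of the package's sampler.
    """
    b0g = np.linspace(*b0_range, 120)
    s2g = np.exp(np.linspace(np.log(s2_range[0]), np.log(s2_range[1]), 160))
    lp = np.empty((len(b0g), len(s2g)))
    for i, b0 in enumerate(b0g):
        for j, s2 in enumerate(s2g):
            lp[i, j] = _cluster_loglik(b0, s2, y, n) - (prior_shape + 1) * np.log(
                s2
            ) - prior_scale / s2
    w = np.exp(lp - lp.max()) * s2g[None, :]  # log-grid Jacobian
    w /= w.sum()
    return float((w * b0g[:, None]).sum()), float((w * s2g[None, :]).sum())
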