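"""Beta-binomial likelihood in a mean/dispersion parameterisation.

Cluster counts y+ of y_total successes are modelled as beta-binomial with
mean prevalence mu and dispersion phi in (0, 1):

    alpha = mu (1 - phi) / phi,   beta = (1 - mu)(1 - phi) / phi

so phi acts like an intra-cluster correlation: phi -> 0 recovers the
binomial, larger phi inflates the variance

    Var(y+) = n mu (1 - mu) [1 + (n - 1) phi].

Log-gamma forms keep the log-likelihood and its mu/phi derivatives finite
and vectorisable, as needed by the gradient fitter.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["betabinom_loglik", "betabinom_loglik_grad"]


def _check(y_plus, y_total, mu, phi):
    y_plus = np.asarray(y_plus)
    y_total = np.asarray(y_total)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y_plus < 0) or np.any(y_plus > y_total):
        raise ValueError("need 0 <= y_plus <= y_total")
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise ValueError("phi must lie strictly inside (0, 1)")
    return y_plus, y_total, mu, phi


def _ab(mu, phi):
    r = (1.0 - phi) / phi
    return mu * r, (1.0 - mu) * r


def _loglik_core(y, n, mu, phi):
    # no validation: internal fast path for the gradient fitter
    a, b = _ab(mu, phi)
    return (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def _grad_core(y, n, mu, phi):
    a, b = _ab(mu, phi)
    d_all = digamma(n + a + b) - digamma(a + b)
    dl_da = digamma(y + a) - digamma(a) - d_all
    dl_db = digamma(n - y + b) - digamma(b) - d_all
    r = (1.0 - phi) / phi
    d_mu = r * (dl_da - dl_db)
    # da/dphi = -mu/phi^2, db/dphi = -(1-mu)/phi^2
    d_phi = -(mu * dl_da + (1.0 - mu) * dl_db) / phi**2
    return d_mu, d_phi


def betabinom_loglik(y_plus, y_total, mu, phi):
    """Log-pmf of the beta-binomial; broadcasts over its arguments."""
    y, n, mu, phi = _check(y_plus, y_total, mu, phi)
    return _loglik_core(y, n, mu, phi)


def betabinom_loglik_grad(y_plus, y_total, mu, phi):
    """Partial derivatives (d loglik / d mu, d loglik / d phi), elementwise.

    Obtained by the chain rule through alpha(mu, phi), beta(mu, phi) using
    digamma functions.
    """
    y, n, mu, phi = _check(y_plus, y_total, mu, phi)
    return _grad_core(y, n, mu, phi)
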