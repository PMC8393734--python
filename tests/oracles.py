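"""Independent numerical oracles (grid / Gauss-Hermite quadrature).

These deliberately avoid the package's vectorised code paths: they evaluate
the scalar log-likelihood on dense 1-D grids, so variational results can be
checked against brute-force integrals.
"""

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import norm

from splicevb import log_likelihood

ZGRID = np.linspace(-15.0, 15.0, 6001)


def grid_logpost(s, L, m, sig, zgrid=ZGRID):
    ll = np.array([log_likelihood(s, p, L) for p in expit(zgrid)])
    return ll + norm.logpdf(zgrid, loc=m, scale=sig)


def posterior_median_psi(s, L, m, sig, zgrid=ZGRID):
    """Exact-ish posterior median of psi by grid CDF inversion."""
    logpost = grid_logpost(s, L, m, sig, zgrid)
    w = np.exp(logpost - logpost.max())
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(expit(np.interp(0.5, cdf, zgrid)))


def log_evidence(s, L, m, sig, zgrid=ZGRID):
    """log integral of likelihood x prior (multinomial constant omitted)."""
    logpost = grid_logpost(s, L, m, sig, zgrid)
    dz = zgrid[1] - zgrid[0]
    return float(logsumexp(logpost) + np.log(dz))


def gh_expected_loglik(mu_q, delta_q, s, L, n_nodes=200):
    """E_q[log p(s | z)] under q = N(mu_q, delta_q^2), Gauss-Hermite."""
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    z = mu_q + delta_q * x
    ll = np.array([log_likelihood(s, p, L) for p in expit(z)])
    return float((w * ll).sum() / np.sqrt(2 * np.pi))


def gh_expected_expit(mu, delta, n_nodes=200):
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    return float((w * expit(mu + delta * x)).sum() / np.sqrt(2 * np.pi))


def kl_by_quadrature(mu_q, delta_q, mu_p, sigma_p):
    from scipy.integrate import quad

    def integrand(z):
        lq = norm.logpdf(z, mu_q, delta_q)
        lp = norm.logpdf(z, mu_p, sigma_p)
        return np.exp(lq) * (lq - lp)

    lo = mu_q - 12 * delta_q
    hi = mu_q + 12 * delta_q
    val, _ = quad(integrand, lo, hi, limit=200)
    return val
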