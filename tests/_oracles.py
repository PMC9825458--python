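"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive implementations: exhaustive enumeration for the rank-sum
null, the textbook rank formula for Spearman, and a scipy.stats term-by-term
density sum for the curve model's log-posterior.  They share no code with the
package paths they check.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def wilcoxon_exact_p(group_a, group_b) -> float:
    """Two-sided rank-sum p by full enumeration of all C(n, n_a) labelings."""
    a = list(group_a)
    b = list(group_b)
    combined = sorted(a + b)
    n, n_a = len(combined), len(a)
    w_obs = sum(sorted(combined).index(v) + 1 for v in a)  # tie-free ranks
    sums = [sum(idx + 1 for idx in pick) for pick in combinations(range(n), n_a)]
    total = len(sums)
    p_low = sum(s <= w_obs for s in sums) / total
    p_high = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def spearman_rho_bruteforce(xs, ys) -> float:
    """Pearson correlation of midranks, via the plain covariance formula."""
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def log_posterior_oracle(state, x, y, priors) -> float:
    """Term-by-term density sum for the hierarchical curve model.

    Uniform priors are proper densities; the positive-support normal
    hyperpriors are plain normal log-densities (unnormalized truncation),
    matching the package's stated convention.
    """
    a, k = state["a"], state["k"]
    sigma, nu = state["sigma"], state["nu"]
    a_mu, a_sigma = state["a_mu"], state["a_sigma"]
    k_r, k_lam = state["k_r"], state["k_lam"]
    if min(k, nu, k_r, k_lam) <= 0:
        return -np.inf
    if not (priors.sigma_low <= sigma <= priors.sigma_high):
        return -np.inf
    if not (priors.a_sigma_low <= a_sigma <= priors.a_sigma_high):
        return -np.inf
    f = 1.0 / (1.0 + 2.0 ** (-k * (np.asarray(x) - a)))
    lp = float(np.sum(stats.t.logpdf((np.asarray(y) - f) / sigma, df=nu) - np.log(sigma)))
    lp += stats.norm.logpdf(a, loc=a_mu, scale=a_sigma)
    lp += stats.norm.logpdf(a_mu, loc=priors.a_mu_mean, scale=priors.a_mu_precision**-0.5)
    lp += stats.uniform.logpdf(
        a_sigma, loc=priors.a_sigma_low, scale=priors.a_sigma_high - priors.a_sigma_low
    )
    lp += stats.uniform.logpdf(
        sigma, loc=priors.sigma_low, scale=priors.sigma_high - priors.sigma_low
    )
    lp += stats.gamma.logpdf(k, a=k_r, scale=1.0 / k_lam)
    lp += stats.norm.logpdf(nu, loc=priors.nu_mean, scale=priors.nu_precision**-0.5)
    lp += stats.norm.logpdf(k_r, loc=priors.k_r_mean, scale=priors.k_r_precision**-0.5)
    lp += stats.norm.logpdf(
        k_lam, loc=priors.k_lambda_mean, scale=priors.k_lambda_precision**-0.5
    )
    return float(lp)


def grid_posterior_mean_a(x, y, sigma, nu, a_sd, k_shape, k_rate,
                          a_grid, k_grid) -> float:
    """Posterior mean of the curve center by dense 2-D trapezoid quadrature
    of the reduced (center, slope) model with everything else frozen."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lp = np.empty((a_grid.size, k_grid.size))
    for i, a in enumerate(a_grid):
        f = 1.0 / (1.0 + 2.0 ** (-k_grid[:, None] * (x - a)))
        ll = stats.t.logpdf((y - f) / sigma, df=nu).sum(axis=1) - x.size * np.log(sigma)
        lp[i] = (
            ll
            + stats.norm.logpdf(a, loc=0.0, scale=a_sd)
            + stats.gamma.logpdf(k_grid, a=k_shape, scale=1.0 / k_rate)
        )
    w = np.exp(lp - lp.max())
    z = np.trapezoid(np.trapezoid(w, k_grid, axis=1), a_grid)
    num = np.trapezoid(np.trapezoid(w * a_grid[:, None], k_grid, axis=1), a_grid)
    return float(num / z)
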