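"""Independent brute-force oracles used by the tests.

Everything here deliberately avoids the package's own closed-form algebra:
posterior moments come from dense numerical integration of prior x likelihood
on a grid, connected components from a hand-rolled union-find, and grouping
counts from row hashing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def grid_moments(log_density, grid):
    """Mean and variance of a 1-d density known up to a constant on a grid."""
    logw = log_density(grid)
    logw = logw - logw.max()
    w = np.exp(logw)
    norm = np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid) / norm
    var = np.trapezoid(w * (grid - mean) ** 2, grid) / norm
    return mean, var


def gaussian_product_moments(prior_mean, prior_var, xs, ys, lik_var=1.0, lo=None, hi=None, span=12.0, res=1e-3):
    """Posterior moments of theta with prior N(prior_mean, prior_var) and
    likelihood prod_i N(ys[i]; xs[i] * theta, lik_var), via grid integration."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    center = prior_mean
    scale = np.sqrt(prior_var) + 1.0
    g_lo = center - span * scale if lo is None else lo
    g_hi = center + span * scale if hi is None else hi
    grid = np.arange(g_lo, g_hi + res, res)

    def logpost(t):
        lp = stats.norm.logpdf(t, prior_mean, np.sqrt(prior_var))
        for x, y in zip(xs, ys):
            lp = lp + stats.norm.logpdf(y, x * t, np.sqrt(lik_var))
        return lp

    return grid_moments(logpost, grid)


def truncated_gaussian_product_moments(prior_mean, prior_var, lo, hi, xs, ys, lik_vars):
    """As above but with a truncated-normal prior supported on [lo, hi]."""
    grid = np.linspace(lo, hi, int(round((hi - lo) / 1e-3)) + 1)
    sd = np.sqrt(prior_var)

    def logpost(t):
        lp = stats.truncnorm.logpdf(t, (lo - prior_mean) / sd, (hi - prior_mean) / sd, loc=prior_mean, scale=sd)
        for x, y, v in zip(xs, ys, lik_vars):
            lp = lp + stats.norm.logpdf(y, x * t, np.sqrt(v))
        return lp

    return grid_moments(logpost, grid)


def inverse_gamma_product_moments(a0, b0, residuals):
    """Posterior moments of a noise variance with IG(a0, b0) prior and
    N(0, sigma2) residuals, integrating over the precision lam = 1/sigma2."""
    from scipy.integrate import quad

    residuals = np.asarray(residuals, float)
    rss = float(residuals @ residuals)
    n = residuals.size

    def unnorm(lam, k):
        return lam ** (a0 + n / 2.0 - 1 - k) * np.exp(-lam * (b0 + rss / 2.0))

    norm = quad(unnorm, 0, np.inf, args=(0,))[0]
    mean = quad(unnorm, 0, np.inf, args=(1,))[0] / norm
    second = quad(unnorm, 0, np.inf, args=(2,))[0] / norm
    return mean, second - mean**2


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def components_oracle(mask: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """Connected components of the isoform-peptide graph via union-find."""
    mask = np.asarray(mask)
    q, r = mask.shape
    uf = UnionFind(q + r)
    for j in range(q):
        for k in range(r):
            if mask[j, k]:
                uf.union(j, q + k)
    comps: dict[int, tuple[set, set]] = {}
    for node in range(q + r):
        root = uf.find(node)
        iso, pep = comps.setdefault(root, (set(), set()))
        (iso if node < q else pep).add(node if node < q else node - q)
    return [(frozenset(i), frozenset(p)) for i, p in comps.values()]


def distinct_row_count(mask: np.ndarray) -> int:
    return len({tuple(row) for row in np.asarray(mask)})


def marginal_d_posterior_mean_oracle(T, A, P, tau_w, tau_d, tau_i0, n_grid=121):
    """Posterior mean of the condition effect for a 1-isoform model with the
    detectability fixed at 1 (degenerate bounds) and unit peptide noise,
    integrating the latent abundances out analytically and (W, D, I0)
    numerically on a dense grid centered at least-squares estimates."""
    T = np.asarray(T, float).ravel()
    A = np.asarray(A, float).ravel()
    P = np.asarray(P, float)  # (n, 2)
    z = np.ones(2)
    C = np.outer(z, z) + np.eye(2)  # marginal covariance of a peptide row
    Cinv = np.linalg.inv(C)
    a_i = P @ Cinv @ z  # (n,)
    b = float(z @ Cinv @ z)
    n = T.size

    # center the grids on rough OLS estimates so the mass is covered
    X = np.column_stack([np.ones(n), T, A])
    c_i0, c_w, c_d = np.linalg.lstsq(X, a_i / b, rcond=None)[0]
    w = np.linspace(c_w - 1.0, c_w + 1.0, n_grid)
    d = np.linspace(c_d - 1.5, c_d + 1.5, n_grid)
    i0 = np.linspace(c_i0 - 1.5, c_i0 + 1.5, n_grid)
    W, D, I0 = np.meshgrid(w, d, i0, indexing="ij")

    # sufficient statistics of mu_i = I0 + T_i W + A_i D
    sum_mu_a = I0 * a_i.sum() + W * (T * a_i).sum() + D * (A * a_i).sum()
    sum_mu2 = (
        n * I0**2
        + W**2 * (T**2).sum()
        + D**2 * (A**2).sum()
        + 2 * I0 * W * T.sum()
        + 2 * I0 * D * A.sum()
        + 2 * W * D * (T * A).sum()
    )
    loglik = sum_mu_a - 0.5 * b * sum_mu2
    logprior = (
        -0.5 * (W - 1) ** 2 / tau_w - 0.5 * D**2 / tau_d - 0.5 * I0**2 / tau_i0
    )
    logpost = loglik + logprior
    wgt = np.exp(logpost - logpost.max())
    return float((wgt * D).sum() / wgt.sum())
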