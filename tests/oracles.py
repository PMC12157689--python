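"""Independent numerical oracles used by the tests.

These deliberately avoid the algebra of the implementation they check:
Bayes factors are computed by evaluating the full multivariate-normal
marginal density with *finite* prior variances and integrating over the
residual precision tau on a dense log grid; posterior moments come from
grid integration over the effect sizes; haplotype dosages come from
exhaustive enumeration of all copying paths.
"""

import itertools

import numpy as np
from scipy import linalg


def log_marginal(y, W, G, sigma, H=None, Va=1e8, kappa=1e-10):
    """log marginal likelihood of y under the mixed model by tau-quadrature.

    y | b, tau ~ N(Wa + G beta, tau^-1 H); a ~ N(0, tau^-1 Va I),
    beta ~ N(0, tau^-1 sigma^2 I), tau ~ Gamma(kappa/2, kappa/2).
    Marginalizing b gives y | tau ~ N(0, tau^-1 Sigma) with
    Sigma = H + Va W W' + sigma^2 G G'; tau is integrated numerically.
    """
    from scipy.special import gammaln

    n = len(y)
    if H is None:
        H = np.eye(n)
    Sigma = H + Va * W @ W.T
    if G is not None:
        G2 = np.atleast_2d(G.T).T
        Sigma = Sigma + sigma**2 * G2 @ G2.T
    cho = linalg.cho_factor(Sigma)
    logdet = 2 * np.sum(np.log(np.diag(cho[0])))
    q = float(y @ linalg.cho_solve(cho, y))

    def log_integrand(logt):
        t = np.exp(logt)
        lp = (n / 2) * (logt - np.log(2 * np.pi)) - 0.5 * logdet - t * q / 2
        lprior = ((kappa / 2) * np.log(kappa / 2) - gammaln(kappa / 2)
                  + (kappa / 2 - 1) * logt - kappa * t / 2)
        return lp + lprior + logt  # + logt: integration in log-tau

    t0 = np.log(n / q)
    grid = np.linspace(t0 - 50, t0 + 50, 40001)
    vals = log_integrand(grid)
    m = vals.max()
    return m + np.log(np.trapezoid(np.exp(vals - m), grid))


def oracle_lg_bf(y, W, G, sigma, H=None):
    """log10 Bayes factor of (W, G) vs W-only by quadrature."""
    return (log_marginal(y, W, G, sigma, H)
            - log_marginal(y, W, None, sigma, H)) / np.log(10)


def oracle_joint_moments(y, W, x1, x0, sigma, n_grid=241, half_width=9.0):
    """Posterior mean/covariance of (beta1, beta0) by 2-D grid integration.

    For fixed beta, y - G beta ~ N(0, tau^-1 (I + Va W W')); tau is
    integrated in closed form (kappa -> 0), the beta grid numerically.
    """
    n = len(y)
    Va = 1e8
    G = np.column_stack([x1, x0])
    S = np.eye(n) + Va * W @ W.T
    cho = linalg.cho_factor(S)

    # crude center/scale for the grid from ordinary least squares
    X = np.column_stack([W, G])
    beta_ls = np.linalg.lstsq(X, y, rcond=None)[0][-2:]
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    se = np.sqrt(resid @ resid / n / np.diag(G.T @ G))

    g1 = np.linspace(beta_ls[0] - half_width * se[0],
                     beta_ls[0] + half_width * se[0], n_grid)
    g0 = np.linspace(beta_ls[1] - half_width * se[1],
                     beta_ls[1] + half_width * se[1], n_grid)
    B1, B0 = np.meshgrid(g1, g0, indexing="ij")
    lp = np.empty_like(B1)
    for i in range(n_grid):
        for j in range(n_grid):
            b = np.array([B1[i, j], B0[i, j]])
            r = y - G @ b
            q = float(r @ linalg.cho_solve(cho, r)) + float(b @ b) / sigma**2
            lp[i, j] = -((n + 2) / 2) * np.log(q)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    m1 = float((w * B1).sum())
    m0 = float((w * B0).sum())
    v1 = float((w * (B1 - m1) ** 2).sum())
    v0 = float((w * (B0 - m0) ** 2).sum())
    c10 = float((w * (B1 - m1) * (B0 - m0)).sum())
    return m1, m0, v1, v0, c10


def enumerate_dosage(panel, query, rho, eps):
    """Li-Stephens posterior dosages by exhaustive path enumeration.

    Prior over templates is uniform; transitions switch with probability
    rho to a uniform template (including the current one). Missing query
    sites emit 1; the dosage at a site is the posterior expectation of
    P(allele = 1 | template), i.e. 1-eps / eps / 0.5 for panel allele
    1 / 0 / missing.
    """
    panel = np.asarray(panel)
    H, S = panel.shape
    total = np.zeros(S)
    norm = 0.0
    for path in itertools.product(range(H), repeat=S):
        p = 1.0 / H
        for t in range(1, S):
            stay = (1 - rho) + rho / H
            p *= stay if path[t] == path[t - 1] else rho / H
        for t in range(S):
            a = panel[path[t], t]
            if query[t] == -1:
                continue
            if a == -1:
                p *= 0.5
            else:
                p *= (1 - eps) if a == query[t] else eps
        norm += p
        for t in range(S):
            a = panel[path[t], t]
            p_alt = 0.5 if a == -1 else ((1 - eps) if a == 1 else eps)
            total[t] += p * p_alt
    dos = total / norm
    out = np.where(np.asarray(query) == -1, dos, np.asarray(query, float))
    return out
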