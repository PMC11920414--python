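"""Independent brute-force oracles used by the test suite.

Each oracle is implemented with a different numerical route than the
library code it checks (scipy's multivariate-normal CDF instead of the
library's quadrature; golden-section search instead of Brent; power
iteration instead of a dense eigensolver; direct log-density sums
instead of discrepancy bookkeeping).
"""

import numpy as np
from scipy.stats import multivariate_normal, norm


def bvn_cdf_scipy(h, k, rho):
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    pts = np.column_stack(
        [np.clip(np.broadcast_to(h, np.broadcast(h, k).shape).ravel(), -8, 8),
         np.clip(np.broadcast_to(k, np.broadcast(h, k).shape).ravel(), -8, 8)]
    )
    return mvn.cdf(pts).reshape(np.broadcast(h, k).shape)


def table_loglik(table, tau_r, tau_c, rho):
    """Log-likelihood of a contingency table under the bivariate-normal
    threshold model, via scipy's multivariate-normal CDF."""
    tr = np.concatenate(([-np.inf], tau_r, [np.inf]))
    tc = np.concatenate(([-np.inf], tau_c, [np.inf]))
    grid = bvn_cdf_scipy(tr[:, None], tc[None, :], rho)
    p = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return float(np.sum(table * np.log(np.clip(p, 1e-300, 1.0))))


def polychoric_oracle(table, tau_r, tau_c, tol=1e-6):
    """Golden-section maximization of the table log-likelihood over rho."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = -0.995, 0.995
    # coarse grid to bracket the global optimum
    grid = np.linspace(a, b, 41)
    vals = [table_loglik(table, tau_r, tau_c, r) for r in grid]
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = table_loglik(table, tau_r, tau_c, c)
    fd = table_loglik(table, tau_r, tau_c, d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = table_loglik(table, tau_r, tau_c, c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = table_loglik(table, tau_r, tau_c, d)
    return (a + b) / 2.0


def first_pc_power_iteration(R, n_iter=2000, tol=1e-12):
    """Leading eigenvector/value of a symmetric PSD matrix by power
    iteration (sign fixed so the loading sum is positive)."""
    v = np.ones(R.shape[0]) / np.sqrt(R.shape[0])
    lam = 0.0
    for _ in range(n_iter):
        w = R @ v
        lam_new = np.linalg.norm(w)
        w = w / lam_new
        if np.linalg.norm(w - v) < tol:
            v, lam = w, lam_new
            break
        v, lam = w, lam_new
    if v.sum() < 0:
        v = -v
    return v, lam


def gaussian_deviance(data_centered, Sigma):
    """-2 log-likelihood of centered rows under N(0, Sigma)."""
    mvn = multivariate_normal(mean=np.zeros(Sigma.shape[0]), cov=Sigma)
    return -2.0 * float(np.sum(mvn.logpdf(data_centered)))
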