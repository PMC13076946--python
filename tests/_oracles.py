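"""Independent oracles used to verify the implementation.

These deliberately use different algorithm families from the package:
FISTA proximal gradient (vs block coordinate descent) for the sparse
group lasso, closed forms in the orthonormal limit, plain normal
equations for every regression quantity, and two-model residual sums
of squares for the partial F test.
"""

from __future__ import annotations

import math

import numpy as np

W_GROUP = math.sqrt(2.0)


def sgl_objective(X, y, beta, lam, tau, w=W_GROUP):
    n = X.shape[0]
    resid = y - X @ beta
    group_norms = np.linalg.norm(beta.reshape(-1, 2), axis=1)
    return (
        0.5 / n * float(resid @ resid)
        + lam * tau * float(np.sum(np.abs(beta)))
        + lam * (1 - tau) * w * float(np.sum(group_norms))
    )


def _prox(v, t1, t2):
    u = np.sign(v) * np.maximum(np.abs(v) - t1, 0.0)
    u2 = u.reshape(-1, 2)
    norms = np.linalg.norm(u2, axis=1)
    scale = np.where(norms > t2, 1.0 - t2 / np.maximum(norms, 1e-300), 0.0)
    return (u2 * scale[:, None]).reshape(-1)


def fista_sgl(X, y, lam, tau, w=W_GROUP, max_iter=200_000, tol=1e-14, beta0=None):
    """High-precision SGL solution by accelerated proximal gradient."""
    n, m = X.shape
    L = float(np.linalg.eigvalsh(X.T @ X / n)[-1])
    step = 1.0 / L
    t1, t2 = step * lam * tau, step * lam * (1 - tau) * w
    beta = np.zeros(m) if beta0 is None else beta0.copy()
    z = beta.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = X.T @ (X @ z - y) / n
        beta_new = _prox(z - step * grad, t1, t2)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = beta_new + (t - 1) / t_new * (beta_new - beta)
        # restart on objective increase direction (gradient scheme)
        if np.dot(z - beta_new, beta_new - beta) > 0:
            z = beta_new.copy()
            t_new = 1.0
        delta = np.max(np.abs(beta_new - beta))
        beta, t = beta_new, t_new
        if delta < tol:
            break
    return beta


def orthonormal_group_solution(rho, lam, tau, w=W_GROUP):
    """Closed-form minimizer of 0.5||b||^2 - rho'b + lam*tau*||b||_1
    + lam*(1-tau)*w*||b||_2 (group Gram equal to identity)."""
    u = np.sign(rho) * np.maximum(np.abs(rho) - lam * tau, 0.0)
    nrm = np.linalg.norm(u)
    t2 = lam * (1 - tau) * w
    if nrm <= t2:
        return np.zeros_like(rho)
    return (1 - t2 / nrm) * u


def ols_r2(y, columns):
    """R^2 by explicit normal equations with an intercept."""
    n = len(y)
    D = np.column_stack([np.ones(n)] + list(columns))
    coef = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / sst


def ols_residuals(y, columns):
    n = len(y)
    D = np.column_stack([np.ones(n)] + list(columns))
    coef = np.linalg.solve(D.T @ D, D.T @ y)
    return y - D @ coef


def partial_f(y, base_columns, extra_columns):
    """Partial F statistic and P-value by two-model RSS comparison."""
    from scipy import stats

    n = len(y)
    r0 = ols_residuals(y, base_columns)
    r1 = ols_residuals(y, base_columns + extra_columns)
    rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
    q = len(extra_columns)
    dof = n - 1 - len(base_columns) - q
    F = ((rss0 - rss1) / q) / (rss1 / dof)
    return F, float(stats.f.sf(F, q, dof))


def random_grouped_instance(rng, n, p, signal_groups=3, noise=1.0):
    """Standardized grouped design with a sparse group-structured signal."""
    X = rng.standard_normal((n, 2 * p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.zeros(2 * p)
    chosen = rng.choice(p, size=min(signal_groups, p), replace=False)
    for g in chosen:
        beta[2 * g : 2 * g + 2] = rng.standard_normal(2)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y - y.mean(), beta
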