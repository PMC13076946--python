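"""Sparse group lasso solver for (G, GxE) coefficient pairs.

Minimizes, for each lambda on a decreasing path,

    (1/2n) ||y - X beta||_2^2
        + lambda * [ tau * ||beta||_1
                     + (1 - tau) * sum_g w_g ||beta_g||_2 ],

where every group g couples one variant's main-effect and interaction
coefficients (n_g = 2, w_g = sqrt(2)).  tau = 1 recovers the lasso,
tau = 0 the group lasso.

The solver is block coordinate descent over groups with an active-set
inner loop and warm starts down the path; every returned solution
carries a full KKT (subgradient stationarity) residual as an optimality
certificate.  Columns are assumed standardized and ``y`` centered — the
intercept is the training mean, absorbed by centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, DegenerateInputError, InvalidConfigError
from .rules import GROUP_WEIGHT, soft_threshold

DEFAULT_INNER_TOL = 1e-8
DEFAULT_KKT_TOL = 1e-6
DEFAULT_PATH_LENGTH = 100
DEFAULT_MIN_RATIO = 0.01


@dataclass
class LambdaPathSpec:
    """Log-linearly spaced regularization path.

    ``lambda1`` is the printed path maximum
    ``max_g (1/n)||X_g^T y||_2 / (1 - tau)`` (for tau = 1 the lasso
    critical value ``max_j (1/n)|X_j^T y|``).  Because the formula omits
    the group weight w_g = sqrt(2) and the soft-threshold shrinkage it
    upper-bounds the exact critical lambda, so the solution at lambda1
    is always all-zero and the top of the path is slightly conservative.
    """

    lambdas: np.ndarray
    lambda1: float
    min_ratio: float

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.size < 1 or np.any(np.diff(lam) >= 0):
            raise InvalidConfigError("lambda sequence must be strictly decreasing")
        self.lambdas = lam


@dataclass
class CoefficientPath:
    """Solutions beta(lambda) along a decreasing lambda sequence."""

    lambdas: np.ndarray
    tau: float
    coefficients: np.ndarray  # (L, 2p); columns ordered (G_1, G_1xE, G_2, ...)
    intercept: float
    kkt_residuals: np.ndarray  # (L,)
    n_iterations: np.ndarray  # (L,) coordinate-descent sweeps used per lambda
    group_weight: float = GROUP_WEIGHT

    def group_coefficients(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(beta_G, beta_GEI) per group for the k-th lambda."""
        b = self.coefficients[k]
        return b[0::2].copy(), b[1::2].copy()

    def active_groups(self, k: int) -> np.ndarray:
        b = self.coefficients[k].reshape(-1, 2)
        return np.flatnonzero(np.any(b != 0.0, axis=1))


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    tau: float,
    L: int = DEFAULT_PATH_LENGTH,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> LambdaPathSpec:
    """Build the regularization path for a grouped design.

    lambda1 = max_g (1/n)||X_g^T y||_2 / (1-tau); for tau = 1 the
    pure-lasso value max_j (1/n)|X_j^T y| (the printed formula divides
    by zero there).  The sequence is log-linear from lambda1 down to
    lambda1 * min_ratio.
    """
    if not 0.0 <= tau <= 1.0:
        raise InvalidConfigError(f"tau must be in [0, 1], got {tau}")
    if L < 2 or not 0.0 < min_ratio < 1.0:
        raise InvalidConfigError("need L >= 2 and 0 < min_ratio < 1")
    y = np.asarray(y, dtype=float)
    if not np.any(y):
        raise DegenerateInputError("outcome is identically zero")
    n = y.shape[0]
    corr = (X.T @ y) / n
    if tau >= 1.0:
        lam1 = float(np.max(np.abs(corr)))
    else:
        group_norms = np.linalg.norm(corr.reshape(-1, 2), axis=1)
        lam1 = float(np.max(group_norms)) / (1.0 - tau)
    lambdas = lam1 * np.logspace(0.0, np.log10(min_ratio), L)
    return LambdaPathSpec(lambdas=lambdas, lambda1=lam1, min_ratio=min_ratio)


def _prox_group(v: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Prox of ``t1*||.||_1 + t2*||.||_2``: soft-threshold then group shrink."""
    u = np.sign(v) * np.maximum(np.abs(v) - t1, 0.0)
    nrm = np.linalg.norm(u)
    if nrm <= t2:
        return np.zeros_like(u)
    return (1.0 - t2 / nrm) * u


def _solve_group_2d(
    A: np.ndarray,
    rho: np.ndarray,
    lam: float,
    tau: float,
    w_g: float,
    b0: np.ndarray,
    lip: float,
    tol: float = 1e-12,
    max_iter: int = 2000,
) -> np.ndarray:
    """Minimize ``0.5 b'Ab - rho'b + lam*tau*||b||_1 + lam*(1-tau)*w_g*||b||_2``.

    Proximal gradient with the exact Lipschitz step 1/lip where ``lip``
    is the largest eigenvalue of the 2x2 Gram ``A``; exact for this
    strongly convex 2-d problem at the tolerance used.
    """
    step = 1.0 / lip
    t1 = step * lam * tau
    t2 = step * lam * (1.0 - tau) * w_g
    b = b0.copy()
    for _ in range(max_iter):
        grad = A @ b - rho
        b_new = _prox_group(b - step * grad, t1, t2)
        if np.max(np.abs(b_new - b)) < tol:
            return b_new
        b = b_new
    return b


def fit_sgl(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tau: float,
    w_g: float = GROUP_WEIGHT,
    beta0: np.ndarray | None = None,
    inner_tol: float = DEFAULT_INNER_TOL,
    kkt_tol: float = DEFAULT_KKT_TOL,
    max_sweeps: int = 10_000,
    intercept: float = 0.0,
) -> CoefficientPath:
    """Solve the SGL problem along ``lambdas`` (decreasing), warm-starting.

    ``X`` holds the groups to fit, columns ordered (G_1, G_1xE, G_2, ...);
    ``y`` must already be centered.  Each lambda's solution is verified
    by a KKT residual over all given groups; failure to reach ``kkt_tol``
    (relative to max(1, lambda)) raises :class:`ConvergenceError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if m % 2:
        raise InvalidConfigError("design must have an even number of columns (2 per group)")
    p = m // 2
    lambdas = np.asarray(lambdas, dtype=float)

    # per-group 2x2 Grams (1/n) X_g^T X_g and their largest eigenvalues
    grams = np.empty((p, 2, 2))
    lips = np.empty(p)
    for g in range(p):
        Xg = X[:, 2 * g : 2 * g + 2]
        A = (Xg.T @ Xg) / n
        grams[g] = A
        # eigenvalues of a symmetric 2x2
        tr, det = A[0, 0] + A[1, 1], A[0, 0] * A[1, 1] - A[0, 1] ** 2
        disc = max(tr * tr / 4.0 - det, 0.0)
        lips[g] = max(tr / 2.0 + np.sqrt(disc), 1e-12)

    beta = np.zeros(m) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    r = y - X @ beta  # full-scale residual (not /n)

    coefs = np.empty((lambdas.size, m))
    kkts = np.empty(lambdas.size)
    iters = np.zeros(lambdas.size, dtype=int)

    def sweep(groups: np.ndarray, lam: float) -> float:
        """One coordinate-descent pass over ``groups``; returns max change."""
        nonlocal r
        max_change = 0.0
        thresh = lam * (1.0 - tau) * w_g
        for g in groups:
            sl = slice(2 * g, 2 * g + 2)
            Xg = X[:, sl]
            bg = beta[sl]
            rho = (Xg.T @ r) / n + grams[g] @ bg  # (1/n) X_g^T (partial residual)
            shrunk = soft_threshold(rho, lam * tau)
            if np.linalg.norm(shrunk) <= thresh:
                new_bg = np.zeros(2)
            else:
                new_bg = _solve_group_2d(grams[g], rho, lam, tau, w_g, bg, lips[g])
            delta = new_bg - bg
            change = float(np.max(np.abs(delta)))
            if change > 0.0:
                r -= Xg @ delta
                beta[sl] = new_bg
                max_change = max(max_change, change)
        return max_change

    all_groups = np.arange(p)
    for k, lam in enumerate(lambdas):
        n_sweeps = 0
        for _outer in range(100):
            # full pass over every group establishes the working set
            sweep(all_groups, lam)
            n_sweeps += 1
            working = np.flatnonzero(np.any(beta.reshape(-1, 2) != 0.0, axis=1))
            # iterate the (small) working set to convergence
            while n_sweeps < max_sweeps:
                change = sweep(working, lam)
                n_sweeps += 1
                if change < inner_tol:
                    break
            # a clean full pass certifies convergence over all groups
            change = sweep(all_groups, lam)
            n_sweeps += 1
            if change < inner_tol:
                break
        resid = kkt_residual(X, y, beta, lam, tau, w_g)
        tol = kkt_tol * max(1.0, lam)
        if resid > tol:
            raise ConvergenceError(
                f"SGL failed to certify lambda={lam:.3e} "
                f"(KKT residual {resid:.3e} > {tol:.3e})",
                worst_kkt=resid,
            )
        coefs[k] = beta
        kkts[k] = resid
        iters[k] = n_sweeps

    return CoefficientPath(
        lambdas=lambdas,
        tau=tau,
        coefficients=coefs,
        intercept=intercept,
        kkt_residuals=kkts,
        n_iterations=iters,
        group_weight=w_g,
    )


def kkt_residual(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    lam: float,
    tau: float,
    w_g: float = GROUP_WEIGHT,
) -> float:
    """Maximum violation of the subgradient stationarity conditions.

    For a zero group the condition is
    ``||ST_{lam*tau}(X_g^T r)||_2 <= lam*(1-tau)*w_g`` with
    ``r = (y - X beta)/n``; for an active group, stationarity of each
    coordinate.  Returns the largest violation magnitude over all groups.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = X.shape[0]
    r = (y - X @ beta) / n
    corr = (X.T @ r).reshape(-1, 2)
    b2 = beta.reshape(-1, 2)
    group_norms = np.linalg.norm(b2, axis=1)
    worst = 0.0
    for g in range(corr.shape[0]):
        cg, bg, nrm = corr[g], b2[g], group_norms[g]
        if nrm == 0.0:
            viol = max(
                0.0,
                float(np.linalg.norm(soft_threshold(cg, lam * tau)))
                - lam * (1.0 - tau) * w_g,
            )
        else:
            viol = 0.0
            for j in range(2):
                if bg[j] != 0.0:
                    v = cg[j] - lam * tau * np.sign(bg[j]) - lam * (1.0 - tau) * w_g * bg[j] / nrm
                    viol = max(viol, abs(float(v)))
                else:
                    # ell_2 gradient vanishes at beta_j = 0 inside an active group
                    viol = max(viol, max(0.0, abs(float(cg[j])) - lam * tau))
        worst = max(worst, viol)
    return worst
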