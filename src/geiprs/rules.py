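"""Screening mathematics for the sparse group lasso.

Closed-form rules that decide, from the correlation of a group's columns
with the current residual, whether its coefficients can be discarded:

* *safe* rules are certificates — a discarded group/feature has exactly
  zero coefficients in the exact solution at the lambda being checked;
* *strong* rules are heuristics for the next, smaller lambda — they may
  over-discard, and discarded-but-active groups are repaired later by a
  safe-rule checking pass.

Throughout, the residual ``r`` is on the 1/n scale, ``r = (y - X beta)/n``,
so correlations ``X_g^T r`` match the scale of the lambda path.  All
comparisons are strict ``<`` with ties resolved toward *keeping* the
group (conservative).
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import InvalidConfigError

GROUP_WEIGHT = math.sqrt(2.0)
"""Default group weight w_g = sqrt(n_g) for the two-feature (G, GxE) groups."""


def soft_threshold(x: np.ndarray, z: float) -> np.ndarray:
    """Component-wise soft-thresholding ``sign(x) * max(|x| - z, 0)``."""
    if z < 0:
        raise InvalidConfigError(f"soft-threshold level must be >= 0, got {z}")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - z, 0.0)


def group_correlations(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Correlations ``X^T r`` reshaped to (p, 2), one row per (G, GxE) group."""
    c = X.T @ r
    return c.reshape(-1, 2)


def group_safe_discard(
    corr_g: np.ndarray, lam: float, tau: float, w_g: float = GROUP_WEIGHT
) -> bool:
    """Safe certificate that a whole group is zero at ``lam``.

    True iff ``||ST_{lam*tau}(X_g^T r)||_2 < lam*(1-tau)*w_g`` where ``r``
    is the exact-solution residual at the same ``lam``.
    """
    lhs = float(np.linalg.norm(soft_threshold(corr_g, lam * tau)))
    return lhs < lam * (1.0 - tau) * w_g


def feature_safe_discard(corr_j: float, lam: float, tau: float) -> bool:
    """Safe certificate for a single feature: ``|X_j^T r| < lam*tau``."""
    return abs(float(corr_j)) < lam * tau


def group_strong_discard(
    corr_g: np.ndarray,
    lam_prev: float,
    lam_next: float,
    tau: float,
    w_g: float = GROUP_WEIGHT,
) -> bool:
    """Heuristic discard of a group at ``lam_next`` given the residual at
    ``lam_prev`` (``lam_next <= lam_prev``).

    True iff ``||ST_{lam_prev*tau}(X_g^T r_prev)||_2
    < (1-tau) * w_g * (2*lam_next - lam_prev)``.  When the right side is
    <= 0 the rule never discards.
    """
    lhs = float(np.linalg.norm(soft_threshold(corr_g, lam_prev * tau)))
    return lhs < (1.0 - tau) * w_g * (2.0 * lam_next - lam_prev)


def feature_strong_discard(
    corr_j: float, lam_prev: float, lam_next: float, tau: float
) -> bool:
    """Heuristic discard of one feature: ``|X_j^T r_prev| < tau*(2*lam_next - lam_prev)``.

    Unused by the batch-screening driver (each group has only two
    features) but exposed for completeness.
    """
    return abs(float(corr_j)) < tau * (2.0 * lam_next - lam_prev)


def compute_scores(corr: np.ndarray, lam_prev: float, tau: float) -> np.ndarray:
    """Per-group screening scores ``c_g = ||ST_{lam_prev*tau}(X_g^T r_prev)||_2``.

    Parameters
    ----------
    corr
        (p, 2) array of group correlations with the residual at
        ``lam_prev`` (see :func:`group_correlations`).
    """
    shrunk = soft_threshold(np.asarray(corr, dtype=float), lam_prev * tau)
    return np.linalg.norm(shrunk, axis=1)
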