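"""Per-variant 2-df joint (G + GxE) association scan.

For each variant the OLS model ``y ~ 1 + E + G + G*E`` is fitted and
H0: beta_G = beta_GEI = 0 tested with a 2-numerator-df partial F test.
Used both as a P < .01 prefilter ahead of the penalized fit and as the
thresholded (S)GLwT baseline: filter at a grid of stringent thresholds,
fit the sparse-group-lasso path on the retained groups with lambda
chosen by five-fold cross-validation on training, and pick the
(threshold, tau, lambda) combination maximizing validation R^2.

The scan is plain OLS; mixed-model relatedness control is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidConfigError
from .gitlabs import FitResult
from .preprocess import GroupedDesign
from .sgl import fit_sgl, lambda_path

#: Stringent thresholds used by the thresholded baseline.
DEFAULT_THRESHOLD_GRID = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
#: Single-threshold prefilter ahead of the penalized fit.
PREFILTER_THRESHOLD = 0.01


def joint_2df_scan(
    y_resid: np.ndarray,
    E_norm: np.ndarray,
    dosages: np.ndarray,
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Vectorized 2-df scan over all variants.

    Returns a frame with columns ``variant_id beta_G beta_GEI F p_2df n
    monomorphic``; monomorphic variants get F = 0, p = 1 and a flag.
    """
    y = np.asarray(y_resid, dtype=float)
    E = np.asarray(E_norm, dtype=float)
    G = np.asarray(dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, p = G.shape
    if variant_ids is None:
        variant_ids = [f"snp{j + 1}" for j in range(p)]

    # project out the shared reduced design (1, E)
    B = np.column_stack([np.ones(n), E])
    Q, _ = np.linalg.qr(B)
    y_r = y - Q @ (Q.T @ y)
    rss0 = float(y_r @ y_r)
    G_r = G - Q @ (Q.T @ G)
    GE = G * E[:, None]
    GE_r = GE - Q @ (Q.T @ GE)

    # per-variant 2x2 normal equations on the projected columns
    a11 = np.einsum("ij,ij->j", G_r, G_r)
    a22 = np.einsum("ij,ij->j", GE_r, GE_r)
    a12 = np.einsum("ij,ij->j", G_r, GE_r)
    b1 = G_r.T @ y_r
    b2 = GE_r.T @ y_r
    det = a11 * a22 - a12 * a12
    mono = (a11 <= 1e-12) | (det <= 1e-12 * np.maximum(a11 * a22, 1e-300))

    beta_g = np.zeros(p)
    beta_gei = np.zeros(p)
    ok = ~mono
    beta_g[ok] = (a22[ok] * b1[ok] - a12[ok] * b2[ok]) / det[ok]
    beta_gei[ok] = (a11[ok] * b2[ok] - a12[ok] * b1[ok]) / det[ok]
    rss1 = rss0 - (beta_g * b1 + beta_gei * b2)
    dof = n - 4
    F = np.zeros(p)
    with np.errstate(divide="ignore"):  # exact fits give rss1 = 0, F = inf
        F[ok] = ((rss0 - rss1[ok]) / 2.0) / (rss1[ok] / dof)
    F = np.maximum(F, 0.0)
    pvals = np.ones(p)
    pvals[ok] = stats.f.sf(F[ok], 2, dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "beta_G": beta_g,
            "beta_GEI": beta_gei,
            "F": F,
            "p_2df": pvals,
            "n": n,
            "monomorphic": mono,
        }
    )


def joint_2df_test(
    y_resid: np.ndarray, E_norm: np.ndarray, dosage: np.ndarray, variant_id: str = "snp1"
) -> pd.Series:
    """Single-variant convenience wrapper around :func:`joint_2df_scan`."""
    return joint_2df_scan(y_resid, E_norm, np.asarray(dosage)[:, None], [variant_id]).iloc[0]


def filter_variants(p_values: np.ndarray, threshold: float = PREFILTER_THRESHOLD) -> np.ndarray:
    """Indices of variants with p < threshold, original order preserved."""
    return np.flatnonzero(np.asarray(p_values) < threshold)


def _cv_r2_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tau: float, n_folds: int, seed: int
) -> np.ndarray:
    """Mean out-of-fold R^2 per lambda for a fixed path."""
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(n) % n_folds)
    sse = np.zeros(lambdas.size)
    sst = 0.0
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        mu = float(np.mean(y[tr]))
        path = fit_sgl(X[tr], y[tr] - mu, lambdas, tau)
        pred = X[te] @ path.coefficients.T + mu  # (n_te, L)
        sse += np.sum((y[te][:, None] - pred) ** 2, axis=0)
        sst += float(np.sum((y[te] - np.mean(y[te])) ** 2))
    return 1.0 - sse / sst


def baseline_thresholded_gl(
    design: GroupedDesign,
    y_resid: np.ndarray,
    scan: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    taus: tuple[float, ...] = (0.5,),
    n_folds: int = 5,
    L: int = 50,
    min_ratio: float = 0.01,
    seed: int = 0,
) -> FitResult | None:
    """(S)GLwT baseline: P-value thresholding then a penalized path fit.

    For each threshold the retained groups are fitted along a lambda
    path with lambda chosen by ``n_folds``-fold cross-validation on the
    training split; the (threshold, tau, lambda) maximizing validation
    R^2 wins.  tau = 0 gives the GLwT flavor.  Returns None when every
    threshold retains zero variants.
    """
    if n_folds < 2:
        raise InvalidConfigError("need at least 2 CV folds")
    split = design.split_assignment
    tr, va = split == "train", split == "validation"
    y_tr, y_va = y_resid[tr], y_resid[va]
    sst_val = float(np.sum((y_va - np.mean(y_va)) ** 2))
    pvals = scan["p_2df"].to_numpy()

    best: FitResult | None = None
    best_score = -np.inf
    for thr in thresholds:
        kept = filter_variants(pvals, thr)
        if kept.size == 0:
            continue
        cols = np.stack([2 * kept, 2 * kept + 1], axis=1).reshape(-1)
        X_tr, X_va = design.X[np.ix_(tr, cols)], design.X[np.ix_(va, cols)]
        for tau in taus:
            mu = float(np.mean(y_tr))
            lambdas = lambda_path(X_tr, y_tr - mu, tau, L=L, min_ratio=min_ratio).lambdas
            cv_r2 = _cv_r2_path(X_tr, y_tr, lambdas, tau, n_folds, seed)
            k_best = int(np.argmax(cv_r2))
            path = fit_sgl(X_tr, y_tr - mu, lambdas[: k_best + 1], tau)
            beta = path.coefficients[k_best]
            pred = X_va @ beta + mu
            val_r2 = 1.0 - float(np.sum((y_va - pred) ** 2)) / sst_val
            if val_r2 > best_score:
                full = np.zeros(design.X.shape[1])
                full[cols] = beta
                best_score = val_r2
                best = FitResult(
                    lambdas=np.array([lambdas[k_best]]),
                    coefficients=full[None, :],
                    intercept=mu,
                    tau=tau,
                    validation_r2=np.array([val_r2]),
                    selected_index=0,
                    stopping_reason="thresholded baseline",
                    manifest={"threshold": thr, "n_kept": int(kept.size), "cv_r2": cv_r2.tolist()},
                )
    return best
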