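"""Preprocessing: covariate residualization, per-split environment
normalization, and assembly of the grouped (G, GxE) design.

Conventions fixed here and reused everywhere downstream:

* standardization constants (means, sds with denominator n-1) are
  learned on the *training* split only and applied verbatim to
  validation and test, so only training columns have exact mean 0/sd 1;
* the environment variable is normalized to mean 0 / variance 1 within
  each split separately (the method's stated convention); pass
  ``mode="train-only"`` for the conventional alternative that reuses
  training constants;
* missing dosages are mean-imputed with the training mean;
* the intercept is handled by centering y, never by a column of ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError

SPLITS = ("train", "validation", "test")


@dataclass
class GroupedDesign:
    """The interleaved design X = (G_1, G_1xE, G_2, G_2xE, ...).

    ``X`` has 2p columns over all n samples; group g_i owns columns
    (2i, 2i+1).  ``column_means``/``column_sds`` are the training
    standardization constants for the 2p columns.
    """

    X: np.ndarray
    variant_ids: list[str]
    sample_ids: list
    split_assignment: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    dropped_variants: list[str] = field(default_factory=list)
    group_weight: float = np.sqrt(2.0)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1] // 2

    def group_columns(self, g: int) -> tuple[int, int]:
        return 2 * g, 2 * g + 1

    def split_X(self, name: str) -> np.ndarray:
        return self.X[self.split_assignment == name]

    @property
    def dosage_columns(self) -> np.ndarray:
        return self.X[:, 0::2]

    @property
    def gxe_columns(self) -> np.ndarray:
        return self.X[:, 1::2]


@dataclass
class PhenotypeBundle:
    y_raw: np.ndarray
    y_resid: np.ndarray
    environment_raw: np.ndarray
    environment_norm: np.ndarray
    covariates: np.ndarray
    split_assignment: np.ndarray

    def split_y(self, name: str) -> np.ndarray:
        return self.y_resid[self.split_assignment == name]

    def split_env(self, name: str) -> np.ndarray:
        return self.environment_norm[self.split_assignment == name]


def normalize_environment(
    E: np.ndarray, split_assignment: np.ndarray, mode: str = "per-split"
) -> np.ndarray:
    """Normalize E to mean 0 / variance 1 (sd denominator n-1).

    ``per-split`` normalizes within each of train/validation/test
    separately; ``train-only`` learns constants on training and applies
    them to all splits.
    """
    E = np.asarray(E, dtype=float)
    out = np.full_like(E, np.nan)  # samples outside the three splits stay NaN
    if mode == "train-only":
        tr = split_assignment == "train"
        mu, sd = float(np.mean(E[tr])), float(np.std(E[tr], ddof=1))
        if sd == 0.0:
            raise DegenerateInputError("environment constant within training split")
        return (E - mu) / sd
    if mode != "per-split":
        raise ValueError(f"unknown normalization mode {mode!r}")
    for name in SPLITS:
        mask = split_assignment == name
        if not np.any(mask):
            raise DegenerateInputError(f"split {name!r} is empty")
        mu, sd = float(np.mean(E[mask])), float(np.std(E[mask], ddof=1))
        if sd == 0.0:
            raise DegenerateInputError(f"environment constant within split {name!r}")
        out[mask] = (E[mask] - mu) / sd
    return out


def residualize_outcome(
    y: np.ndarray,
    E_norm: np.ndarray,
    covariates: np.ndarray | None,
    split_assignment: np.ndarray,
) -> np.ndarray:
    """Residuals of y after adjusting for E and covariates.

    Coefficients are fitted by least squares on the training split only
    and applied to all splits, so training residuals are orthogonal to
    the adjustment design.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    cols = [np.ones(n), np.asarray(E_norm, dtype=float)]
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        cols.extend(C[:, j] for j in range(C.shape[1]))
    D = np.column_stack(cols)
    tr = split_assignment == "train"
    Dt = D[tr]
    rank = np.linalg.matrix_rank(Dt)
    if rank < D.shape[1]:
        # name the collinear columns via QR pivoting on the training design
        _, R = np.linalg.qr(Dt)
        bad = [j for j in range(D.shape[1]) if abs(R[j, j]) < 1e-10 * abs(R[0, 0])]
        raise DegenerateInputError(
            f"adjustment design rank-deficient on training (columns {bad})"
        )
    coef, *_ = np.linalg.lstsq(Dt, y[tr], rcond=None)
    return y - D @ coef


def build_grouped_design(
    dosages: np.ndarray,
    E_norm: np.ndarray,
    split_assignment: np.ndarray,
    variant_ids: list[str] | None = None,
    sample_ids: list | None = None,
    variant_subset: np.ndarray | None = None,
) -> GroupedDesign:
    """Assemble the standardized grouped design.

    Dosage columns are mean-imputed (training mean) and standardized on
    training; GxE columns are standardized dosage times normalized E,
    then themselves standardized on training.  Variants monomorphic in
    training are dropped with a warning.
    """
    dosages = np.asarray(dosages, dtype=float)
    n, p_all = dosages.shape
    if variant_ids is None:
        variant_ids = [f"snp{j + 1}" for j in range(p_all)]
    if sample_ids is None:
        sample_ids = list(range(n))
    if variant_subset is not None:
        dosages = dosages[:, variant_subset]
        variant_ids = [variant_ids[j] for j in variant_subset]
    p = dosages.shape[1]
    tr = split_assignment == "train"

    keep, dropped = [], []
    X = np.empty((n, 2 * p))
    means = np.empty(2 * p)
    sds = np.empty(2 * p)
    E_norm = np.asarray(E_norm, dtype=float)
    for j in range(p):
        col = dosages[:, j].copy()
        miss = (col < 0) | ~np.isfinite(col)
        valid_tr = tr & ~miss
        if not np.any(valid_tr):
            dropped.append(variant_ids[j])
            continue
        tr_mean = float(np.mean(col[valid_tr]))
        col[miss] = tr_mean
        sd = float(np.std(col[tr], ddof=1))
        if sd == 0.0:
            dropped.append(variant_ids[j])
            continue
        mu = float(np.mean(col[tr]))
        g_std = (col - mu) / sd
        gxe = g_std * E_norm
        mu2, sd2 = float(np.mean(gxe[tr])), float(np.std(gxe[tr], ddof=1))
        if sd2 == 0.0:
            dropped.append(variant_ids[j])
            continue
        k = len(keep)
        X[:, 2 * k] = g_std
        X[:, 2 * k + 1] = (gxe - mu2) / sd2
        means[2 * k], sds[2 * k] = mu, sd
        means[2 * k + 1], sds[2 * k + 1] = mu2, sd2
        # detect within-group collinearity (e.g. two-valued E patterns)
        if abs(np.corrcoef(g_std[tr], gxe[tr])[0, 1]) > 1 - 1e-12:
            warnings.warn(
                f"variant {variant_ids[j]}: GxE column collinear with dosage column"
            )
        keep.append(j)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} variant(s) monomorphic in training: {dropped[:5]}")
    m = len(keep)
    return GroupedDesign(
        X=X[:, : 2 * m].copy(),
        variant_ids=[variant_ids[j] for j in keep],
        sample_ids=sample_ids,
        split_assignment=np.asarray(split_assignment),
        column_means=means[: 2 * m].copy(),
        column_sds=sds[: 2 * m].copy(),
        dropped_variants=dropped,
    )
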