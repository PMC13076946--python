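"""Construction and evaluation of the two polygenic scores.

From a selected coefficient vector, the main-effect score
``PRS_G = sum_i beta_G_i * G_i`` and the interaction score
``PRS_GEI = sum_i beta_GEI_i * G_i`` are genotype-only weighted sums —
the environment multiplies PRS_GEI later, inside the evaluation model

    y ~ 1 + E + PRS_G + PRS_GEI * E.

Predictive performance is the overall R^2 of that refitted model plus
four semi-partial R^2s, each the R^2 drop from removing one term (or
the two PRS terms jointly), and the two-sided t-test P-value of the
PRS_GEI x E coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GeiprsError


@dataclass
class PRSResult:
    sample_ids: list
    prs_g: np.ndarray
    prs_gei: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    overall_r2: float
    sp_r2_gei: float  # R^2: PRS_GEI x E | (PRS_G, E)
    sp_r2_g: float  # R^2: PRS_G | (E, PRS_GEI x E)
    sp_r2_joint: float  # R^2: (PRS_G, PRS_GEI x E) | E
    sp_r2_env: float  # R^2: E | (PRS_G, PRS_GEI x E)
    p_interaction: float | None
    n_used: int
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_r2": self.overall_r2,
            "sp_r2_gei": self.sp_r2_gei,
            "sp_r2_g": self.sp_r2_g,
            "sp_r2_joint": self.sp_r2_joint,
            "sp_r2_env": self.sp_r2_env,
            "p_interaction": self.p_interaction,
            "n_used": self.n_used,
        }


def construct_prs(
    beta_g: np.ndarray,
    beta_gei: np.ndarray,
    genotypes: np.ndarray,
    sample_ids: list | None = None,
    variant_ids: list[str] | None = None,
    target_variant_ids: list[str] | None = None,
    provenance: dict | None = None,
) -> PRSResult:
    """Genotype-weighted scores for a target split.

    ``genotypes`` must already be transformed with the *training*
    standardization constants.  When both id lists are given, every
    coefficient variant must be present in the target genotypes.
    """
    if variant_ids is not None and target_variant_ids is not None:
        pos = {v: i for i, v in enumerate(target_variant_ids)}
        missing = [v for v in variant_ids if v not in pos]
        if missing:
            raise GeiprsError(f"variants absent from target genotypes: {missing[:10]}")
        order = [pos[v] for v in variant_ids]
        genotypes = genotypes[:, order]
    if sample_ids is None:
        sample_ids = list(range(genotypes.shape[0]))
    return PRSResult(
        sample_ids=sample_ids,
        prs_g=genotypes @ np.asarray(beta_g, dtype=float),
        prs_gei=genotypes @ np.asarray(beta_gei, dtype=float),
        provenance=provenance or {},
    )


def _r2(y: np.ndarray, columns: list[np.ndarray], warn: list) -> float:
    """R^2 of y on an intercept plus the given columns (pseudoinverse fit)."""
    n = y.shape[0]
    D = np.column_stack([np.ones(n)] + columns)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        warn.append("rank-deficient model; pseudoinverse fit used")
        coef = np.linalg.pinv(D) @ y
    else:
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / sst


def evaluate(
    y: np.ndarray,
    E_norm: np.ndarray,
    prs: PRSResult,
) -> EvalReport:
    """Overall and semi-partial R^2s plus the interaction P-value.

    Fits the full model ``y ~ 1 + E + PRS_G + PRS_GEI*E`` and the four
    reduced models, forming each semi-partial R^2 as
    ``R^2(full) - R^2(reduced)``.  A PRS_GEI that is identically zero
    (no interaction variants selected) yields ``sp_r2_gei = 0`` and an
    absent interaction P-value.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E_norm, dtype=float)
    g = np.asarray(prs.prs_g, dtype=float)
    ge = np.asarray(prs.prs_gei, dtype=float) * E
    n = y.shape[0]
    warn: list = []

    gei_absent = not np.any(prs.prs_gei)
    full_cols = [E, g, ge]
    overall = _r2(y, full_cols, warn)
    r2_no_gei = _r2(y, [E, g], warn)
    r2_no_g = _r2(y, [E, ge], warn)
    r2_env_only = _r2(y, [E], warn)
    r2_no_env = _r2(y, [g, ge], warn)

    p_int: float | None = None
    if not gei_absent:
        D = np.column_stack([np.ones(n), E, g, ge])
        rank = np.linalg.matrix_rank(D)
        if rank == D.shape[1] and n > D.shape[1]:
            coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ coef
            dof = n - D.shape[1]
            sigma2 = float(np.sum(resid**2)) / dof
            cov = sigma2 * np.linalg.inv(D.T @ D)
            tstat = coef[3] / np.sqrt(cov[3, 3])
            p_int = float(2.0 * stats.t.sf(abs(tstat), dof))
        else:
            warn.append("full model rank-deficient; interaction P-value unavailable")

    return EvalReport(
        overall_r2=overall,
        sp_r2_gei=overall - r2_no_gei,
        sp_r2_g=overall - r2_no_g,
        sp_r2_joint=overall - r2_env_only,
        sp_r2_env=overall - r2_no_env,
        p_interaction=p_int,
        n_used=n,
        warnings=warn,
    )


def stratify_subgroups(
    y: np.ndarray, E: np.ndarray, prs_gei: np.ndarray
) -> pd.DataFrame:
    """Stratify samples at median(E) and bin by global PRS_GEI quartiles.

    Samples with E exactly at the median go to the upper stratum.
    Quartile bins (0-25, 25-50, 50-75, 75-100%) are computed on the
    whole evaluated split with ties broken by rank.  Returns one row
    per (stratum, quartile) cell with n, mean(y), se(y), and the
    per-stratum slope of mean(y) across the quartile index.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    s = np.asarray(prs_gei, dtype=float)
    med = float(np.median(E))
    stratum = np.where(E >= med, "E>=median", "E<median")
    ranks = stats.rankdata(s, method="ordinal")
    quartile = np.minimum((4 * (ranks - 1) / len(s)).astype(int) + 1, 4)

    rows = []
    for strat in ("E<median", "E>=median"):
        mask_s = stratum == strat
        means, qs = [], []
        for q in (1, 2, 3, 4):
            cell = mask_s & (quartile == q)
            n_cell = int(np.sum(cell))
            mean = float(np.mean(y[cell])) if n_cell else np.nan
            se = float(np.std(y[cell], ddof=1) / np.sqrt(n_cell)) if n_cell > 1 else np.nan
            rows.append({"stratum": strat, "quartile": q, "n": n_cell, "mean_y": mean, "se_y": se})
            if n_cell:
                means.append(mean)
                qs.append(q)
        slope = float(np.polyfit(qs, means, 1)[0]) if len(qs) > 1 else np.nan
        for row in rows[-4:]:
            row["stratum_slope"] = slope
    return pd.DataFrame(rows)


def ground_truth_report(truth, split: str = "test", replicate: int = 0) -> EvalReport:
    """Evaluation with the simulator's true aggregates in place of the
    fitted scores — the reference bar every method is compared against."""
    idx = truth.split_idx(split)
    y = truth.phenotype_replicates[replicate][idx]
    E = truth.environment[idx]
    E_norm = (E - np.mean(E)) / np.std(E, ddof=1)
    prs = PRSResult(
        sample_ids=list(idx),
        prs_g=truth.g_main[idx],
        prs_gei=truth.g_gei[idx],
        provenance={"source": "ground truth"},
    )
    return evaluate(y, E_norm, prs)
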