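"""End-to-end orchestration: preprocess -> (prefilter) -> fit -> score -> evaluate.

These functions bind the library modules into the full workflow and are
what the command-line interface and the bagging ensemble call into.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import EvalReport, PRSResult, construct_prs, evaluate
from .exceptions import InvalidConfigError
from .gitlabs import FitResult, run_gitlabs, select_tau
from .gweis import PREFILTER_THRESHOLD, baseline_thresholded_gl, joint_2df_scan
from .preprocess import (
    GroupedDesign,
    PhenotypeBundle,
    build_grouped_design,
    normalize_environment,
    residualize_outcome,
)

MODES = ("geiprs-sgl", "geiprs-gl", "baseline-sglwt", "baseline-glwt")


@dataclass
class PipelineResult:
    design: GroupedDesign
    bundle: PhenotypeBundle
    fit: FitResult | None
    prs_test: PRSResult
    report: EvalReport
    scan: pd.DataFrame | None = None


def prepare(
    dosages: np.ndarray,
    environment: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    split_assignment: np.ndarray,
    variant_ids: list[str] | None = None,
    sample_ids: list | None = None,
    env_mode: str = "per-split",
    variant_subset: np.ndarray | None = None,
) -> tuple[GroupedDesign, PhenotypeBundle]:
    """Normalize E, residualize y, and assemble the grouped design."""
    split_assignment = np.asarray(split_assignment)
    E_norm = normalize_environment(environment, split_assignment, mode=env_mode)
    y_resid = residualize_outcome(y, E_norm, covariates, split_assignment)
    design = build_grouped_design(
        dosages, E_norm, split_assignment, variant_ids, sample_ids, variant_subset
    )
    bundle = PhenotypeBundle(
        y_raw=np.asarray(y, dtype=float),
        y_resid=y_resid,
        environment_raw=np.asarray(environment, dtype=float),
        environment_norm=E_norm,
        covariates=np.asarray(covariates) if covariates is not None else np.zeros((len(y), 0)),
        split_assignment=split_assignment,
    )
    return design, bundle


def fit_model(
    design: GroupedDesign,
    bundle: PhenotypeBundle,
    mode: str = "geiprs-sgl",
    taus: tuple[float, ...] | float = 0.5,
    prefilter_p: float | None = None,
    baseline_thresholds: tuple[float, ...] | None = None,
    seed: int = 0,
    **gitlabs_kwargs,
) -> tuple[FitResult | None, pd.DataFrame | None]:
    """Fit a model in one of the four modes.

    ``geiprs-*`` runs the batch-screening driver (gl forces tau = 0,
    optionally after a 2-df P-value prefilter); ``baseline-*`` runs the
    thresholded (S)GLwT baseline.  Returns (fit, scan); the scan is
    None when no per-variant tests were needed.
    """
    if mode not in MODES:
        raise InvalidConfigError(f"unknown mode {mode!r}; choose from {MODES}")
    split = bundle.split_assignment
    tr, va = split == "train", split == "validation"
    y_tr, y_va = bundle.y_resid[tr], bundle.y_resid[va]
    if isinstance(taus, float):
        taus = (taus,)
    scan: pd.DataFrame | None = None

    if mode.startswith("geiprs"):
        groups = np.arange(design.p)
        if prefilter_p is not None:
            scan = joint_2df_scan(
                y_tr,
                bundle.environment_norm[tr],
                design.dosage_columns[tr],
                design.variant_ids,
            )
            groups = np.flatnonzero(scan["p_2df"].to_numpy() < prefilter_p)
            if groups.size == 0:
                return None, scan
        cols = np.stack([2 * groups, 2 * groups + 1], axis=1).reshape(-1)
        X_tr, X_va = design.X[np.ix_(tr, cols)], design.X[np.ix_(va, cols)]
        if mode == "geiprs-gl":
            taus = (0.0,)
        if len(taus) == 1:
            fit = run_gitlabs(X_tr, y_tr, X_va, y_va, taus[0], **gitlabs_kwargs)
        else:
            _, fit = select_tau(X_tr, y_tr, X_va, y_va, taus=taus, **gitlabs_kwargs)
        # lift coefficients back to full-design coordinates
        lifted = np.zeros((fit.coefficients.shape[0], design.X.shape[1]))
        lifted[:, cols] = fit.coefficients
        fit.coefficients = lifted
        return fit, scan

    scan = joint_2df_scan(
        y_tr, bundle.environment_norm[tr], design.dosage_columns[tr], design.variant_ids
    )
    if mode == "baseline-glwt":
        taus = (0.0,)
    kwargs = {} if baseline_thresholds is None else {"thresholds": baseline_thresholds}
    fit = baseline_thresholded_gl(design, bundle.y_resid, scan, taus=taus, seed=seed, **kwargs)
    return fit, scan


def score_split(design: GroupedDesign, fit: FitResult | None, split: str = "test") -> PRSResult:
    """PRS_G / PRS_GEI on a split from the selected model (zero if no fit)."""
    mask = design.split_assignment == split
    G = design.dosage_columns[mask]
    ids = [design.sample_ids[i] for i in np.flatnonzero(mask)]
    if fit is None:
        z = np.zeros(G.shape[0])
        return PRSResult(sample_ids=ids, prs_g=z, prs_gei=z.copy(), provenance={"empty": True})
    beta_g, beta_gei = fit.selected_group_coefficients()
    return construct_prs(
        beta_g,
        beta_gei,
        G,
        sample_ids=ids,
        provenance={"tau": fit.tau, "lambda": fit.selected_lambda},
    )


def evaluate_split(
    bundle: PhenotypeBundle, prs: PRSResult, split: str = "test"
) -> EvalReport:
    mask = bundle.split_assignment == split
    return evaluate(bundle.y_resid[mask], bundle.environment_norm[mask], prs)


def run_pipeline(
    dosages: np.ndarray,
    environment: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    split_assignment: np.ndarray,
    mode: str = "geiprs-sgl",
    taus: tuple[float, ...] | float = 0.5,
    prefilter_p: float | None = None,
    variant_ids: list[str] | None = None,
    seed: int = 0,
    **gitlabs_kwargs,
) -> PipelineResult:
    """Full workflow on in-memory arrays; evaluation is on the test split."""
    design, bundle = prepare(
        dosages, environment, y, covariates, split_assignment, variant_ids
    )
    fit, scan = fit_model(
        design, bundle, mode=mode, taus=taus, prefilter_p=prefilter_p,
        seed=seed, **gitlabs_kwargs,
    )
    prs = score_split(design, fit, "test")
    report = evaluate_split(bundle, prs, "test")
    return PipelineResult(design=design, bundle=bundle, fit=fit, prs_test=prs, report=report, scan=scan)
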