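"""Memory-bounded ensemble mode.

Fit the model on B random training subsamples (each a fraction f of
the training split, drawn without replacement within a bag and
independently across bags, so bags may overlap) and average the
per-bag test-split scores:

    PRS_G(test)   = mean over bags of per-bag PRS_G(test)
    PRS_GEI(test) = mean over bags of per-bag PRS_GEI(test)

Each bag learns its own standardization constants.  Averaging happens
on the per-bag scores, never on coefficient vectors, because bags do
not share standardization.  With B = 1 and f = 1 the ensemble is
bit-identical to the non-bagged run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import PRSResult
from .exceptions import InvalidConfigError
from .pipeline import fit_model, prepare, score_split

MIN_BAG_SAMPLES = 50


@dataclass
class BaggingConfig:
    n_bags: int = 10
    bag_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_bags < 1:
            raise InvalidConfigError("n_bags must be >= 1")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise InvalidConfigError("bag_fraction must be in (0, 1]")


def run_bagged(
    dosages: np.ndarray,
    environment: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    split_assignment: np.ndarray,
    config: BaggingConfig,
    mode: str = "geiprs-sgl",
    taus: tuple[float, ...] | float = 0.5,
    variant_ids: list[str] | None = None,
    **gitlabs_kwargs,
) -> tuple[PRSResult, list[PRSResult]]:
    """Bagged test-split scores: the average PRS plus the per-bag results.

    Per-bag seeds derive from ``config.seed + bag index``; bag sample
    indices are sorted so a full-fraction bag reproduces the training
    split exactly.
    """
    split_assignment = np.asarray(split_assignment)
    train_idx = np.flatnonzero(split_assignment == "train")
    other_idx = np.flatnonzero(split_assignment != "train")
    n_bag = int(round(config.bag_fraction * train_idx.size))
    if n_bag < MIN_BAG_SAMPLES:
        raise InvalidConfigError(
            f"bag size {n_bag} below the {MIN_BAG_SAMPLES}-sample minimum"
        )

    per_bag: list[PRSResult] = []
    for b in range(config.n_bags):
        rng = np.random.default_rng(config.seed + b)
        bag = np.sort(rng.choice(train_idx, size=n_bag, replace=False))
        keep = np.sort(np.concatenate([bag, other_idx]))
        cov_b = covariates[keep] if covariates is not None else None
        design, bundle = prepare(
            dosages[keep],
            environment[keep],
            y[keep],
            cov_b,
            split_assignment[keep],
            variant_ids,
            sample_ids=list(keep),
        )
        fit, _ = fit_model(design, bundle, mode=mode, taus=taus, **gitlabs_kwargs)
        per_bag.append(score_split(design, fit, "test"))

    prs_g = np.mean([r.prs_g for r in per_bag], axis=0)
    prs_gei = np.mean([r.prs_gei for r in per_bag], axis=0)
    averaged = PRSResult(
        sample_ids=per_bag[0].sample_ids,
        prs_g=prs_g,
        prs_gei=prs_gei,
        provenance={"n_bags": config.n_bags, "bag_fraction": config.bag_fraction},
    )
    return averaged, per_bag
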