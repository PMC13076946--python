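"""Batch-screening driver for genome-scale sparse group lasso paths.

The driver alternates three steps over batches of the lambda path:

* **screening** — rank the groups outside the active set by the
  strong-rule score ``c_g = ||ST_{lam_prev*tau}(X_g^T r)||_2`` and add
  the top M to the strong set;
* **fitting** — solve the SGL/GL problem restricted to the strong set
  for the batch's lambdas, warm-starting from the last certified
  solution;
* **checking** — verify each batch solution against the *full* design
  with the safe rules (weak-group checking, then feature-level checks,
  plus the zero features inside strong groups).  The smallest lambda
  whose violation column is empty — with all larger lambdas in the
  batch also clean — becomes the restart point ``lambda_bar``;
  violating groups are absorbed into the strong set and uncertified
  lambdas are re-queued.

Certified solutions therefore satisfy the full-design KKT conditions at
the solver tolerance even though only the strong set was ever fitted.
Iteration stops after ``n_stop`` consecutive decreases of the
validation R^2 along the certified lambda sequence, and the best model
is the certified lambda with the highest validation R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidConfigError
from .rules import GROUP_WEIGHT, compute_scores, group_correlations, soft_threshold
from .sgl import (
    DEFAULT_INNER_TOL,
    DEFAULT_KKT_TOL,
    DEFAULT_MIN_RATIO,
    DEFAULT_PATH_LENGTH,
    fit_sgl,
    lambda_path,
)

DEFAULT_M = 200
DEFAULT_BATCH_SIZE = 10
DEFAULT_N_STOP = 2
TAU_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class FitResult:
    """Certified path plus the validation-selected model."""

    lambdas: np.ndarray  # certified lambdas, decreasing
    coefficients: np.ndarray  # (n_certified, 2p) in full-design coordinates
    intercept: float
    tau: float
    validation_r2: np.ndarray
    selected_index: int
    stopping_reason: str
    manifest: dict = field(default_factory=dict)

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected_index])

    @property
    def selected_coefficients(self) -> np.ndarray:
        return self.coefficients[self.selected_index]

    def selected_group_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.selected_coefficients
        return b[0::2].copy(), b[1::2].copy()


def _group_cols(groups: np.ndarray) -> np.ndarray:
    """Interleaved column indices for a sorted array of group indices."""
    return np.stack([2 * groups, 2 * groups + 1], axis=1).reshape(-1)


def screening_step(
    scores: np.ndarray, active: np.ndarray, M: int, forced: np.ndarray | None = None
) -> np.ndarray:
    """Strong set = active ∪ forced ∪ top-M scored non-active groups.

    Ties in the score are broken by ascending group index (``argsort``
    with stable kind on -score); fewer than M candidates means take all.
    """
    p = scores.shape[0]
    excluded = np.zeros(p, dtype=bool)
    excluded[active] = True
    if forced is not None:
        excluded[forced] = True
    candidates = np.flatnonzero(~excluded)
    if M > 0 and candidates.size:
        order = candidates[np.argsort(-scores[candidates], kind="stable")]
        chosen = order[:M]
    else:
        chosen = np.empty(0, dtype=int)
    parts = [active, chosen]
    if forced is not None:
        parts.append(forced)
    return np.unique(np.concatenate(parts).astype(int))


def checking_step(
    X: np.ndarray,
    y: np.ndarray,
    strong: np.ndarray,
    batch_lambdas: np.ndarray,
    batch_coefs: np.ndarray,
    tau: float,
    w_g: float = GROUP_WEIGHT,
    slack_tol: float = DEFAULT_KKT_TOL,
) -> tuple[dict, int]:
    """Safe-rule verification of batch solutions against the full design.

    ``batch_coefs`` is (n_batch, 2|S|) over the strong groups.  Returns
    ``(violations, n_certified)`` where ``violations`` maps each lambda
    to the list of violating (group, feature) labels and ``n_certified``
    is the length of the clean prefix of the batch (the last certified
    lambda is ``lambda_bar``; 0 means undefined).

    A weak group is certified zero when the group safe rule holds, or
    failing that when both its features pass the feature safe rule; a
    zero-estimated feature inside a strong group must itself pass the
    feature safe rule.  Comparisons allow a numerical slack of
    ``slack_tol * max(1, lambda)``, matching the solver's KKT
    certificate.
    """
    n, m = X.shape
    p = m // 2
    in_strong = np.zeros(p, dtype=bool)
    in_strong[strong] = True
    weak = np.flatnonzero(~in_strong)
    cols = _group_cols(strong)
    violations: dict[float, list] = {}
    n_certified = 0
    prefix_clean = True
    for k, lam in enumerate(batch_lambdas):
        beta_s = batch_coefs[k]
        r = (y - X[:, cols] @ beta_s) / n
        corr = group_correlations(X, r)  # (p, 2)
        slack = slack_tol * max(1.0, lam)
        viols: list = []
        if weak.size:
            cg = corr[weak]
            lhs = np.linalg.norm(soft_threshold(cg, lam * tau), axis=1)
            rhs = lam * (1.0 - tau) * w_g
            fail_group = lhs >= rhs + slack
            for g in weak[fail_group]:
                feat_fail = np.abs(corr[g]) >= lam * tau + slack
                if np.any(feat_fail):
                    viols.extend(
                        (int(g), ("G", "GEI")[j]) for j in np.flatnonzero(feat_fail)
                    )
        # strong-group weak-feature checking
        b2 = beta_s.reshape(-1, 2)
        active_rows = np.any(b2 != 0.0, axis=1)
        for i in np.flatnonzero(active_rows):
            g = strong[i]
            for j in range(2):
                if b2[i, j] == 0.0 and abs(corr[g, j]) >= lam * tau + slack:
                    viols.append((int(g), ("G", "GEI")[j]))
        if viols:
            violations[float(lam)] = viols
            prefix_clean = False
        elif prefix_clean:
            n_certified = k + 1
    return violations, n_certified


def run_gitlabs(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    tau: float,
    M: int = DEFAULT_M,
    batch_size: int = DEFAULT_BATCH_SIZE,
    n_stop: int = DEFAULT_N_STOP,
    L: int = DEFAULT_PATH_LENGTH,
    min_ratio: float = DEFAULT_MIN_RATIO,
    lambdas: np.ndarray | None = None,
    w_g: float = GROUP_WEIGHT,
    inner_tol: float = DEFAULT_INNER_TOL,
    kkt_tol: float = DEFAULT_KKT_TOL,
) -> FitResult:
    """Run the screen/fit/check iteration over the lambda path.

    ``X_train`` columns must be standardized (training constants) and
    ``X_val`` transformed with the same constants; ``y_train`` is
    centered internally (intercept = training mean).
    """
    if M <= 0 or batch_size <= 0:
        raise InvalidConfigError("M and batch_size must be positive")
    X = np.asarray(X_train, dtype=float)
    n, m = X.shape
    p = m // 2
    intercept = float(np.mean(y_train))
    yc = np.asarray(y_train, dtype=float) - intercept
    if lambdas is None:
        lambdas = lambda_path(X, yc, tau, L=L, min_ratio=min_ratio).lambdas
    lambdas = np.asarray(lambdas, dtype=float)

    y_val = np.asarray(y_val, dtype=float)
    sst_val = float(np.sum((y_val - np.mean(y_val)) ** 2))

    active = np.empty(0, dtype=int)
    forced = np.empty(0, dtype=int)
    r = yc / n
    lam_prev = float(lambdas[0])
    beta_full = np.zeros(m)  # last certified solution, full coordinates

    cert_coefs: list[np.ndarray] = []
    cert_lams: list[float] = []
    val_r2: list[float] = []
    manifest: dict = {"iterations": [], "violations": {}}
    stopping = "path exhausted"
    stall = 0
    cur_M = int(M)

    while len(cert_lams) < lambdas.size:
        batch = lambdas[len(cert_lams) : len(cert_lams) + batch_size]
        corr = group_correlations(X, r)
        scores = compute_scores(corr, lam_prev, tau)
        strong = screening_step(scores, active, cur_M, forced)
        cols = _group_cols(strong)
        warm = beta_full[cols]
        path = fit_sgl(
            X[:, cols], yc, batch, tau, w_g=w_g, beta0=warm,
            inner_tol=inner_tol, kkt_tol=kkt_tol, intercept=intercept,
        )
        viols, n_cert = checking_step(
            X, yc, strong, batch, path.coefficients, tau, w_g=w_g, slack_tol=kkt_tol
        )
        manifest["iterations"].append(
            {
                "strong_size": int(strong.size),
                "active_size": int(active.size),
                "batch": [float(v) for v in batch],
                "n_certified": int(n_cert),
                "M": cur_M,
            }
        )
        for lam, v in viols.items():
            manifest["violations"].setdefault(f"{lam:.6e}", []).extend(v)

        if viols:
            viol_groups = np.unique([g for lam_v in viols.values() for g, _ in lam_v])
            forced = np.union1d(forced, viol_groups.astype(int))
        if n_cert == 0:
            stall += 1
            if stall >= 2:
                cur_M = min(2 * cur_M, p)
                stall = 0
            continue
        stall = 0

        for k in range(n_cert):
            full = np.zeros(m)
            full[cols] = path.coefficients[k]
            cert_coefs.append(full)
            cert_lams.append(float(batch[k]))
            pred = X_val @ full + intercept
            sse = float(np.sum((y_val - pred) ** 2))
            val_r2.append(1.0 - sse / sst_val if sst_val > 0 else 0.0)

        # advance state from the lambda_bar solution
        beta_full = cert_coefs[-1]
        lam_prev = cert_lams[-1]
        b2 = beta_full.reshape(-1, 2)
        active = np.flatnonzero(np.any(b2 != 0.0, axis=1))
        r = (yc - X @ beta_full) / n

        # early stopping on consecutive validation decreases
        run = 0
        for i in range(1, len(val_r2)):
            run = run + 1 if val_r2[i] < val_r2[i - 1] else 0
        if run >= n_stop:
            stopping = f"{n_stop} consecutive validation decreases"
            break

    val_arr = np.asarray(val_r2)
    selected = int(np.argmax(val_arr)) if val_arr.size else 0
    return FitResult(
        lambdas=np.asarray(cert_lams),
        coefficients=np.asarray(cert_coefs),
        intercept=intercept,
        tau=tau,
        validation_r2=val_arr,
        selected_index=selected,
        stopping_reason=stopping,
        manifest=manifest,
    )


def select_tau(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    taus: tuple[float, ...] = TAU_GRID,
    **kwargs,
) -> tuple[float, FitResult]:
    """Run the driver for each tau on the grid; return the winner by
    validation R^2 of its selected model."""
    best: tuple[float, FitResult] | None = None
    for tau in taus:
        res = run_gitlabs(X_train, y_train, X_val, y_val, tau, **kwargs)
        score = res.validation_r2[res.selected_index] if res.validation_r2.size else -np.inf
        if best is None or score > best[1].validation_r2[best[1].selected_index]:
            best = (tau, res)
    assert best is not None
    return best
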