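"""Synthetic GWAS data with genotype-environment interaction structure.

The generator emulates the statistical structure of a two-subpopulation
GWAS cohort: blockwise-LD genotype dosages, a Gaussian environment
variable (mean 1, variance 4 by default), nuisance covariates, and a
quantitative phenotype built as a weighted sum of five standardized
components

    y = w_main*c_main + w_gei*c_gei + w_cov*c_cov + w_sub*c_sub + w_err*c_err

with sum_k w_k^2 = 1, so the phenotype has unit variance and each
component contributes exactly w_k^2 of it.  Genetic effects and the
environment are fixed across replicates; only the error component is
redrawn, so the true aggregates g_main and g_GEI are identical in every
replicate and serve as ground-truth scores for evaluation.

LD is produced by a latent blockwise AR(1) Gaussian copula: two
independent latent "haplotype" Gaussians per sample are thresholded at
each variant's allele frequency, giving Hardy-Weinberg dosages in
{0, 1, 2} whose within-block correlation is positive and decays with
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .exceptions import InvalidConfigError

COMPONENTS = ("main", "gei", "covariate", "subgroup", "error")

#: Variance proportions for the named effect-strength levels.
EFFECT_LEVELS = {"weak": 0.05, "moderate": 0.15, "strong": 0.30}


def scenario_weights(main: str, gei: str) -> dict[str, float]:
    """Component weights w_k for a named scenario.

    ``main`` and ``gei`` are effect levels (weak/moderate/strong) mapped
    to variance proportions 0.05/0.15/0.30; covariate and subgroup each
    take 0.05 and the error absorbs the remainder.  Returns the square
    roots (the w_k), which satisfy sum w_k^2 = 1.
    """
    try:
        v_main, v_gei = EFFECT_LEVELS[main], EFFECT_LEVELS[gei]
    except KeyError as exc:
        raise InvalidConfigError(f"unknown effect level: {exc}") from exc
    v = {"main": v_main, "gei": v_gei, "covariate": 0.05, "subgroup": 0.05}
    v["error"] = 1.0 - sum(v.values())
    return {k: float(np.sqrt(x)) for k, x in v.items()}


@dataclass
class SimulationConfig:
    n_samples: int = 4000
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_blocks: int = 20
    ld_rho: float = 0.5
    subpop_fractions: tuple[float, ...] = (0.5, 0.5)
    subpop_fst_like_shift: float = 0.02
    n_causal_main: int = 30
    n_causal_gei: int = 30
    causal_overlap: float = 0.5
    component_weights: dict[str, float] = field(
        default_factory=lambda: scenario_weights("weak", "strong")
    )
    n_covariates: int = 2
    env_mean: float = 1.0
    env_var: float = 4.0
    n_replicates: int = 100
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise InvalidConfigError("ld_rho must be in [0, 1)")
        if abs(sum(self.subpop_fractions) - 1.0) > 1e-8:
            raise InvalidConfigError("subpop_fractions must sum to 1")
        if self.subpop_fst_like_shift < 0:
            raise InvalidConfigError("subpop_fst_like_shift must be >= 0")
        if not 0.0 <= self.causal_overlap <= 1.0:
            raise InvalidConfigError("causal_overlap must be in [0, 1]")
        n_shared = int(round(self.causal_overlap * self.n_causal_gei))
        needed = self.n_causal_main + self.n_causal_gei - min(
            n_shared, self.n_causal_main, self.n_causal_gei
        )
        if needed > self.n_variants:
            raise InvalidConfigError(
                f"causal sets need {needed} variants but only {self.n_variants} exist"
            )
        if self.env_var <= 0:
            raise InvalidConfigError("env_var must be > 0")
        missing = set(COMPONENTS) - set(self.component_weights)
        if missing:
            raise InvalidConfigError(f"component_weights missing {sorted(missing)}")
        ssq = sum(w * w for w in self.component_weights.values())
        if abs(ssq - 1.0) > 1e-8:
            raise InvalidConfigError(f"sum of squared component weights must be 1, got {ssq}")
        if any(f <= 0 for f in self.split_fractions) or abs(sum(self.split_fractions) - 1.0) > 1e-8:
            raise InvalidConfigError("split_fractions must be positive and sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent substream so any stage is reproducible alone."""
        order = ("genotypes", "environment", "covariates", "effects", "split", "error")
        if stream not in order:
            raise InvalidConfigError(f"unknown rng stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(order))[order.index(stream)]
        )


@dataclass
class SimulationTruth:
    genotypes: np.ndarray  # (n, p) dosages in {0, 1, 2}
    environment: np.ndarray
    covariates: np.ndarray
    phenotype_replicates: list[np.ndarray]
    g_main: np.ndarray  # true aggregated main genetic component, pre-standardization
    g_gei: np.ndarray  # true aggregated GEI genetic component (pre-multiplication by E)
    causal_main_idx: np.ndarray
    causal_gei_idx: np.ndarray
    true_beta_g: np.ndarray
    true_beta_gei: np.ndarray
    split_assignment: np.ndarray  # per-sample label in {"train", "validation", "test"}
    subpop_label: np.ndarray
    standardization: dict[str, tuple[float, float]]  # component -> (mean, sd)
    config: SimulationConfig | None = None

    def split_idx(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.split_assignment == name)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Dosage matrix, subpopulation labels, and causal index sets.

    Returns ``(genotypes, subpop_label, causal_main_idx, causal_gei_idx)``.
    """
    rng = config.rng("genotypes")
    n, p = config.n_samples, config.n_variants
    lo, hi = config.maf_range

    base_maf = rng.uniform(lo, hi, size=p)
    n_sub = len(config.subpop_fractions)
    # per-subpopulation allele-frequency perturbation (FST-like drift)
    freqs = np.empty((n_sub, p))
    for s in range(n_sub):
        shift = config.subpop_fst_like_shift * rng.standard_normal(p)
        freqs[s] = np.clip(base_maf + shift, 0.01, 0.99)

    counts = np.floor(np.asarray(config.subpop_fractions) * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    subpop = np.repeat(np.arange(n_sub), counts)

    # latent blockwise AR(1) Gaussians, one per haplotype
    block_sizes = np.full(config.n_blocks, p // config.n_blocks)
    block_sizes[: p % config.n_blocks] += 1
    rho = config.ld_rho

    def latent() -> np.ndarray:
        z = np.empty((n, p))
        j = 0
        for size in block_sizes:
            eps = rng.standard_normal((n, size))
            z[:, j] = eps[:, 0]
            for k in range(1, size):
                z[:, j + k] = rho * z[:, j + k - 1] + np.sqrt(1 - rho * rho) * eps[:, k]
            j += size
        return z

    thresholds = norm.ppf(freqs)  # (n_sub, p)
    thr = thresholds[subpop]  # (n, p)
    dosage = (latent() < thr).astype(np.int8) + (latent() < thr).astype(np.int8)

    causal_main = np.sort(rng.choice(p, size=config.n_causal_main, replace=False))
    n_shared = int(round(config.causal_overlap * config.n_causal_gei))
    n_shared = min(n_shared, config.n_causal_main, config.n_causal_gei)
    shared = rng.choice(causal_main, size=n_shared, replace=False)
    pool = np.setdiff1d(np.arange(p), causal_main)
    fresh = rng.choice(pool, size=config.n_causal_gei - n_shared, replace=False)
    causal_gei = np.sort(np.concatenate([shared, fresh]))
    return dosage, subpop, causal_main, causal_gei


def simulate_environment(
    n: int,
    mean: float = 1.0,
    var: float = 4.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """i.i.d. Gaussian environment draws with the given mean and variance."""
    if var <= 0:
        raise InvalidConfigError(f"environment variance must be > 0, got {var}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return mean + np.sqrt(var) * rng.standard_normal(n)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return np.zeros_like(x, dtype=float), mu, sd
    return (x - mu) / sd, mu, sd


def simulate_phenotypes(
    genotypes: np.ndarray,
    environment: np.ndarray,
    covariates: np.ndarray,
    config: SimulationConfig,
    subpop_label: np.ndarray,
    causal_main_idx: np.ndarray,
    causal_gei_idx: np.ndarray,
) -> SimulationTruth:
    """Phenotype replicates as a weighted sum of standardized components.

    Effects and all components except the error are fixed; each
    replicate redraws only the error term.  g_main and g_GEI are stored
    pre-standardization along with their standardization constants.
    """
    w = config.component_weights
    missing = set(COMPONENTS) - set(w)
    if missing:
        raise InvalidConfigError(f"component_weights missing {sorted(missing)}")
    n = genotypes.shape[0]
    eff = config.rng("effects")

    G_std = np.empty(genotypes.shape)
    for j in range(genotypes.shape[1]):
        G_std[:, j], _, sd = _standardize(genotypes[:, j].astype(float))

    beta_g = np.zeros(genotypes.shape[1])
    beta_gei = np.zeros(genotypes.shape[1])
    beta_g[causal_main_idx] = eff.standard_normal(causal_main_idx.size)
    beta_gei[causal_gei_idx] = eff.standard_normal(causal_gei_idx.size)

    g_main = G_std[:, causal_main_idx] @ beta_g[causal_main_idx]
    g_gei = G_std[:, causal_gei_idx] @ beta_gei[causal_gei_idx]

    c_main, mu_m, sd_m = _standardize(g_main)
    c_gei, mu_i, sd_i = _standardize(g_gei * environment)
    gamma = eff.standard_normal(covariates.shape[1]) if covariates.shape[1] else np.zeros(0)
    c_cov, mu_c, sd_c = _standardize(covariates @ gamma) if covariates.size else (np.zeros(n), 0.0, 0.0)
    c_sub, mu_s, sd_s = _standardize(subpop_label.astype(float))
    if sd_s == 0.0 and w["subgroup"] != 0.0:
        raise InvalidConfigError("subgroup component has zero variance but nonzero weight")

    fixed = (
        w["main"] * c_main + w["gei"] * c_gei + w["covariate"] * c_cov + w["subgroup"] * c_sub
    )
    err_rng = config.rng("error")
    replicates = []
    for _ in range(config.n_replicates):
        c_err, _, _ = _standardize(err_rng.standard_normal(n))
        replicates.append(fixed + w["error"] * c_err)

    split_rng = config.rng("split")
    split = split_data(n, config.split_fractions, subpop_label, rng=split_rng)

    return SimulationTruth(
        genotypes=genotypes,
        environment=environment,
        covariates=covariates,
        phenotype_replicates=replicates,
        g_main=g_main,
        g_gei=g_gei,
        causal_main_idx=causal_main_idx,
        causal_gei_idx=causal_gei_idx,
        true_beta_g=beta_g,
        true_beta_gei=beta_gei,
        split_assignment=split,
        subpop_label=subpop_label,
        standardization={
            "main": (mu_m, sd_m),
            "gei": (mu_i, sd_i),
            "covariate": (mu_c, sd_c),
            "subgroup": (mu_s, sd_s),
        },
        config=config,
    )


def split_data(
    n: int,
    split_fractions: tuple[float, float, float],
    subpop_label: np.ndarray,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Train/validation/test assignment stratified by subpopulation."""
    if any(f <= 0 for f in split_fractions) or abs(sum(split_fractions) - 1.0) > 1e-8:
        raise InvalidConfigError("split_fractions must be positive and sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = np.array(["train", "validation", "test"])
    out = np.empty(n, dtype=object)
    for s in np.unique(subpop_label):
        idx = np.flatnonzero(subpop_label == s)
        perm = rng.permutation(idx)
        n_s = idx.size
        n_tr = int(round(split_fractions[0] * n_s))
        n_va = int(round(split_fractions[1] * n_s))
        n_va = min(n_va, n_s - n_tr)
        bounds = [0, n_tr, n_tr + n_va, n_s]
        for k in range(3):
            out[perm[bounds[k] : bounds[k + 1]]] = labels[k]
    counts = {lab: int(np.sum(out == lab)) for lab in labels}
    if any(v == 0 for v in counts.values()):
        raise InvalidConfigError(f"a split received zero samples: {counts}")
    return out.astype("U10")


def simulate_study(config: SimulationConfig) -> SimulationTruth:
    """End-to-end simulation: genotypes, environment, covariates, phenotypes."""
    genotypes, subpop, causal_main, causal_gei = simulate_genotypes(config)
    env = simulate_environment(
        config.n_samples, config.env_mean, config.env_var, rng=config.rng("environment")
    )
    cov_rng = config.rng("covariates")
    covariates = cov_rng.standard_normal((config.n_samples, config.n_covariates))
    return simulate_phenotypes(
        genotypes, env, covariates, config, subpop, causal_main, causal_gei
    )
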