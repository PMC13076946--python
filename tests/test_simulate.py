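"""Simulator: genotype structure, environment moments, phenotype composition."""

import numpy as np
import pytest

from geiprs.exceptions import InvalidConfigError
from geiprs.simulate import (
    SimulationConfig,
    scenario_weights,
    simulate_environment,
    simulate_genotypes,
    simulate_study,
    split_data,
)

from _oracles import ols_r2


class TestGenotypes:
    def test_dosages_legal_and_maf_bounded(self, small_truth):
        G = small_truth.genotypes
        assert set(np.unique(G)) <= {0, 1, 2}
        freq = G.mean(axis=0) / 2
        maf = np.minimum(freq, 1 - freq)
        n = G.shape[0]
        lo = small_truth.config.maf_range[0]
        assert np.all(maf >= lo - 3 * np.sqrt(lo * (1 - lo) / (2 * n)))

    def test_independent_variants_when_ld_zero(self):
        cfg = SimulationConfig(
            n_samples=1500, n_variants=30, n_blocks=30, ld_rho=0.0,
            subpop_fractions=(1.0,), subpop_fst_like_shift=0.0, seed=3,
            n_causal_main=5, n_causal_gei=5,
        )
        G, _, _, _ = simulate_genotypes(cfg)
        corr = np.corrcoef(G.T.astype(float))
        off = corr[~np.eye(30, dtype=bool)]
        assert np.max(np.abs(off)) < 3 / np.sqrt(1500) * 2.5

    def test_adjacent_ld_matches_latent_oracle(self):
        # brute-force oracle: draw a large bivariate-normal latent sample with
        # the AR(1) adjacent correlation, threshold at each variant's allele
        # frequency, and measure the dosage correlation directly
        cfg = SimulationConfig(
            n_samples=2000, n_variants=100, n_blocks=4, ld_rho=0.8,
            subpop_fractions=(1.0,), subpop_fst_like_shift=0.0, seed=1,
            n_causal_main=5, n_causal_gei=5,
        )
        G, _, _, _ = simulate_genotypes(cfg)
        freq = G.mean(axis=0) / 2.0

        from scipy.stats import norm

        oracle_rng = np.random.default_rng(999)
        big = 40_000
        block = 25

        def oracle_pair_corr(f1, f2):
            z1 = oracle_rng.standard_normal(big)
            z2 = 0.8 * z1 + np.sqrt(1 - 0.64) * oracle_rng.standard_normal(big)
            w1 = oracle_rng.standard_normal(big)
            w2 = 0.8 * w1 + np.sqrt(1 - 0.64) * oracle_rng.standard_normal(big)
            d1 = (z1 < norm.ppf(f1)).astype(int) + (w1 < norm.ppf(f1)).astype(int)
            d2 = (z2 < norm.ppf(f2)).astype(int) + (w2 < norm.ppf(f2)).astype(int)
            return np.corrcoef(d1, d2)[0, 1]

        got, expected = [], []
        for b in range(4):
            for j in range(b * block, (b + 1) * block - 1):
                got.append(np.corrcoef(G[:, j], G[:, j + 1])[0, 1])
                expected.append(oracle_pair_corr(freq[j], freq[j + 1]))
        assert np.mean(got) == pytest.approx(np.mean(expected), abs=0.1)
        assert np.mean(got) > 0.3  # positive, substantial within-block LD

    def test_subpopulations_differ_in_allele_frequency(self):
        cfg = SimulationConfig(
            n_samples=4000, n_variants=50, subpop_fst_like_shift=0.1, seed=5,
            n_causal_main=5, n_causal_gei=5,
        )
        G, sub, _, _ = simulate_genotypes(cfg)
        f0 = G[sub == 0].mean(0) / 2
        f1 = G[sub == 1].mean(0) / 2
        assert np.std(f0 - f1) > 0.03

    def test_bad_maf_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(maf_range=(0.0, 0.6))


class TestEnvironment:
    def test_paper_moments(self):
        E = simulate_environment(100_000, 1.0, 4.0, seed=2)
        assert 0.97 <= E.mean() <= 1.03
        assert 3.9 <= E.var(ddof=1) <= 4.1

    def test_degenerate_variance_limit(self):
        E = simulate_environment(100, 1.0, 1e-12, seed=0)
        np.testing.assert_allclose(E, 1.0, atol=1e-4)

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(
            simulate_environment(50, 1.0, 4.0, seed=7),
            simulate_environment(50, 1.0, 4.0, seed=7),
        )

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_environment(10, 1.0, 0.0)


class TestPhenotypes:
    def test_pure_noise_weights_give_null_model(self):
        w = {"main": 0.0, "gei": 0.0, "covariate": 0.0, "subgroup": 0.0, "error": 1.0}
        cfg = SimulationConfig(
            n_samples=1000, n_variants=40, component_weights=w, seed=4,
            n_causal_main=5, n_causal_gei=5, n_replicates=2,
        )
        truth = simulate_study(cfg)
        y = truth.phenotype_replicates[0]
        r2 = ols_r2(y, [truth.g_main])
        assert r2 < 3 * 2 / 1000

    def test_unit_phenotype_variance(self, small_truth):
        n = small_truth.config.n_samples
        for y in small_truth.phenotype_replicates:
            assert abs(y.var(ddof=1) - 1.0) < 5 / np.sqrt(n)

    def test_component_variances_match_weights(self, small_truth):
        # regression oracle: R^2 of y on c_main ~ w_main^2, incremental ~ w_gei^2
        w = {"main": np.sqrt(0.3), "gei": np.sqrt(0.2), "covariate": 0.0,
             "subgroup": 0.0, "error": np.sqrt(0.5)}
        # independent variants and disjoint causal sets keep the main and
        # GEI components near-orthogonal so R^2 decomposes by weight
        cfg = SimulationConfig(
            n_samples=5000, n_variants=60, n_blocks=60, ld_rho=0.0,
            component_weights=w, seed=6, causal_overlap=0.0,
            n_causal_main=8, n_causal_gei=8, n_replicates=1,
        )
        truth = simulate_study(cfg)
        y = truth.phenotype_replicates[0]
        c_main = (truth.g_main - truth.g_main.mean()) / truth.g_main.std(ddof=1)
        gei_raw = truth.g_gei * truth.environment
        c_gei = (gei_raw - gei_raw.mean()) / gei_raw.std(ddof=1)
        r2_main = ols_r2(y, [c_main])
        r2_both = ols_r2(y, [c_main, c_gei])
        assert r2_main == pytest.approx(0.3, abs=0.03)
        assert r2_both - r2_main == pytest.approx(0.2, abs=0.03)

    def test_truth_fixed_across_replicates(self, small_truth):
        # only the error draw differs between replicates
        y0, y1 = small_truth.phenotype_replicates[:2]
        assert not np.array_equal(y0, y1)
        assert small_truth.g_main.tobytes() == small_truth.g_main.tobytes()
        w_err = small_truth.config.component_weights["error"]
        # the non-error part is identical: residual differences are pure error
        diff = (y0 - y1) / w_err
        assert abs(diff.var(ddof=1) - 2.0) < 0.3  # variance of difference of two std normals

    def test_beta_support_matches_causal_sets(self, small_truth):
        np.testing.assert_array_equal(
            np.flatnonzero(small_truth.true_beta_g), small_truth.causal_main_idx
        )
        np.testing.assert_array_equal(
            np.flatnonzero(small_truth.true_beta_gei), small_truth.causal_gei_idx
        )

    def test_bad_weight_sum_rejected(self):
        w = {"main": 0.5, "gei": 0.5, "covariate": 0.5, "subgroup": 0.5, "error": 0.5}
        with pytest.raises(InvalidConfigError):
            SimulationConfig(component_weights=w)

    def test_missing_component_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(component_weights={"main": 1.0})


class TestSplit:
    def test_sizes_arithmetic(self):
        sub = np.zeros(10, dtype=int)
        out = split_data(10, (0.6, 0.2, 0.2), sub, seed=0)
        counts = {k: int(np.sum(out == k)) for k in ("train", "validation", "test")}
        assert counts == {"train": 6, "validation": 2, "test": 2}

    def test_stratified_by_subpopulation(self):
        sub = np.repeat([0, 1], 500)
        out = split_data(1000, (0.6, 0.2, 0.2), sub, seed=1)
        for name in ("train", "validation", "test"):
            frac0 = np.mean(sub[out == name] == 0)
            assert abs(frac0 - 0.5) < 2 / np.sum(out == name)

    def test_deterministic(self):
        sub = np.repeat([0, 1], 50)
        a = split_data(100, (0.6, 0.2, 0.2), sub, seed=9)
        b = split_data(100, (0.6, 0.2, 0.2), sub, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_empty_split_rejected(self):
        with pytest.raises(InvalidConfigError):
            split_data(3, (0.98, 0.01, 0.01), np.zeros(3, dtype=int), seed=0)


def test_scenario_presets_sum_to_one():
    for main in ("weak", "moderate", "strong"):
        for gei in ("weak", "moderate", "strong"):
            w = scenario_weights(main, gei)
            assert sum(v * v for v in w.values()) == pytest.approx(1.0)
    assert scenario_weights("strong", "weak")["main"] == pytest.approx(np.sqrt(0.30))
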