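"""PRS construction, overall/semi-partial R^2 algebra, stratification."""

import numpy as np
import pytest

from geiprs.evaluate import (
    PRSResult,
    construct_prs,
    evaluate,
    ground_truth_report,
    stratify_subgroups,
)
from geiprs.exceptions import GeiprsError

from _oracles import ols_r2


def _orthonormal_columns(rng, n, k):
    Q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return Q - Q.mean(0)


class TestConstructPrs:
    def test_single_variant_identity(self, rng):
        G = rng.standard_normal((20, 1))
        res = construct_prs(np.array([1.0]), np.array([0.0]), G)
        np.testing.assert_array_equal(res.prs_g, G[:, 0])
        np.testing.assert_array_equal(res.prs_gei, 0.0)

    def test_hand_matrix_vector_products(self):
        G = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0], [2.0, 2.0, 0.0], [1.0, 1.0, 1.0]])
        bg = np.array([0.5, -1.0, 2.0])
        bi = np.array([1.0, 0.0, -0.5])
        res = construct_prs(bg, bi, G)
        np.testing.assert_allclose(res.prs_g, [4.5, 1.0, -1.0, 1.5])
        np.testing.assert_allclose(res.prs_gei, [0.0, -0.5, 2.0, 0.5])

    def test_variant_order_permutation_invariant(self, rng):
        G = rng.standard_normal((10, 4))
        bg, bi = rng.standard_normal(4), rng.standard_normal(4)
        ids = ["a", "b", "c", "d"]
        r1 = construct_prs(bg, bi, G, variant_ids=ids, target_variant_ids=ids)
        perm = [2, 0, 3, 1]
        r2 = construct_prs(
            bg, bi, G[:, perm], variant_ids=ids,
            target_variant_ids=[ids[j] for j in perm],
        )
        np.testing.assert_allclose(r1.prs_g, r2.prs_g)
        np.testing.assert_allclose(r1.prs_gei, r2.prs_gei)

    def test_missing_variant_rejected(self, rng):
        with pytest.raises(GeiprsError, match="absent"):
            construct_prs(
                np.ones(2), np.ones(2), rng.standard_normal((5, 1)),
                variant_ids=["a", "b"], target_variant_ids=["a"],
            )

    def test_linear_in_coefficients(self, rng):
        G = rng.standard_normal((15, 3))
        bg, bi = rng.standard_normal(3), rng.standard_normal(3)
        r1 = construct_prs(bg, bi, G)
        r2 = construct_prs(2 * bg, 2 * bi, G)
        np.testing.assert_allclose(r2.prs_g, 2 * r1.prs_g)
        np.testing.assert_allclose(r2.prs_gei, 2 * r1.prs_gei)


class TestEvaluate:
    def test_orthogonal_decomposition_identity(self, rng):
        n = 400
        # E bounded away from zero so PRS_GEI = h/E is well conditioned
        E = rng.choice([-1.0, 1.0], n) * rng.uniform(0.5, 1.5, n)
        E = E - E.mean()
        assert np.min(np.abs(E)) > 0.2

        def orthogonalize(v, basis):
            v = v - v.mean()
            for b in basis:
                v = v - b * (b @ v) / (b @ b)
            return v

        g = orthogonalize(rng.standard_normal(n), [E])
        h = orthogonalize(rng.standard_normal(n), [E, g])
        prs = PRSResult(sample_ids=list(range(n)), prs_g=g, prs_gei=h / E)
        y = 1.0 * E + 2.0 * g + 3.0 * h
        rep = evaluate(y, E, prs)
        total = rep.sp_r2_env + rep.sp_r2_g + rep.sp_r2_gei
        assert total == pytest.approx(rep.overall_r2, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 200
        E = rng.standard_normal(n)
        prs = PRSResult(
            sample_ids=list(range(n)),
            prs_g=rng.standard_normal(n),
            prs_gei=rng.standard_normal(n),
        )
        ge = prs.prs_gei * E
        y = 0.5 * E + prs.prs_g - 0.8 * ge + rng.standard_normal(n)
        rep = evaluate(y, E, prs)
        full = ols_r2(y, [E, prs.prs_g, ge])
        assert rep.overall_r2 == pytest.approx(full, abs=1e-10)
        assert rep.sp_r2_gei == pytest.approx(full - ols_r2(y, [E, prs.prs_g]), abs=1e-10)
        assert rep.sp_r2_g == pytest.approx(full - ols_r2(y, [E, ge]), abs=1e-10)
        assert rep.sp_r2_joint == pytest.approx(full - ols_r2(y, [E]), abs=1e-10)
        assert rep.sp_r2_env == pytest.approx(full - ols_r2(y, [prs.prs_g, ge]), abs=1e-10)

    def test_zero_gei_score_reports_absent_interaction(self, rng):
        n = 100
        prs = PRSResult(
            sample_ids=list(range(n)),
            prs_g=rng.standard_normal(n),
            prs_gei=np.zeros(n),
        )
        rep = evaluate(rng.standard_normal(n), rng.standard_normal(n), prs)
        assert rep.sp_r2_gei == pytest.approx(0.0, abs=1e-12)
        assert rep.p_interaction is None

    def test_interaction_pvalue_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 150
        E = rng.standard_normal(n)
        prs = PRSResult(
            sample_ids=list(range(n)),
            prs_g=rng.standard_normal(n),
            prs_gei=rng.standard_normal(n),
        )
        ge = prs.prs_gei * E
        y = 0.3 * ge + rng.standard_normal(n)
        rep = evaluate(y, E, prs)
        D = sm.add_constant(np.column_stack([E, prs.prs_g, ge]))
        sm_p = sm.OLS(y, D).fit().pvalues[-1]
        assert rep.p_interaction == pytest.approx(sm_p, abs=1e-10)

    def test_affine_rescaling_of_prs_g_leaves_r2_unchanged(self, rng):
        n = 120
        E = rng.standard_normal(n)
        g = rng.standard_normal(n)
        gei = rng.standard_normal(n)
        y = g + gei * E + rng.standard_normal(n)
        r1 = evaluate(y, E, PRSResult(list(range(n)), g, gei))
        r2 = evaluate(y, E, PRSResult(list(range(n)), 5.0 * g + 2.0, gei))
        assert r1.overall_r2 == pytest.approx(r2.overall_r2, abs=1e-10)
        assert r1.sp_r2_gei == pytest.approx(r2.sp_r2_gei, abs=1e-10)

    def test_nested_r2_monotone(self, rng):
        n = 150
        E = rng.standard_normal(n)
        prs = PRSResult(list(range(n)), rng.standard_normal(n), rng.standard_normal(n))
        rep = evaluate(rng.standard_normal(n), E, prs)
        for sp in (rep.sp_r2_gei, rep.sp_r2_g, rep.sp_r2_joint, rep.sp_r2_env):
            assert sp >= -1e-12
            assert sp <= rep.overall_r2 + 1e-12


class TestStratify:
    def test_constant_outcome_gives_flat_cells(self, rng):
        n = 200
        tbl = stratify_subgroups(np.ones(n), rng.standard_normal(n), rng.standard_normal(n))
        assert np.allclose(tbl["mean_y"], 1.0)
        assert np.allclose(tbl["stratum_slope"], 0.0)

    def test_cell_counts_sum_to_n(self, rng):
        n = 237
        tbl = stratify_subgroups(
            rng.standard_normal(n), rng.standard_normal(n), rng.standard_normal(n)
        )
        assert tbl["n"].sum() == n

    def test_null_prs_cells_near_grand_mean(self, rng):
        n = 2000
        y = rng.standard_normal(n)
        tbl = stratify_subgroups(y, rng.standard_normal(n), rng.standard_normal(n))
        for _, row in tbl.iterrows():
            assert abs(row["mean_y"] - y.mean()) < 3.5 * row["se_y"]

    def test_opposite_trends_across_strata(self, rng):
        # outcome grows with the score above the E median and shrinks below it
        n = 1000
        E = rng.standard_normal(n)
        s = rng.standard_normal(n)
        y = s * np.sign(E - np.median(E))
        tbl = stratify_subgroups(y, E, s)
        slopes = tbl.groupby("stratum")["stratum_slope"].first()
        assert slopes["E<median"] < 0 < slopes["E>=median"]

    def test_median_ties_go_to_upper_stratum(self):
        E = np.array([0.0, 0.0, 0.0, 1.0, 2.0, -1.0, -2.0, 3.0])
        y = np.arange(8.0)
        s = np.arange(8.0)
        tbl = stratify_subgroups(y, E, s)
        upper_n = tbl[tbl["stratum"] == "E>=median"]["n"].sum()
        assert upper_n == np.sum(E >= np.median(E))


class TestGroundTruth:
    def test_no_gei_weight_gives_no_gei_variance(self):
        from geiprs.simulate import SimulationConfig, simulate_study

        w = {"main": np.sqrt(0.4), "gei": 0.0, "covariate": 0.0,
             "subgroup": 0.0, "error": np.sqrt(0.6)}
        cfg = SimulationConfig(
            n_samples=2000, n_variants=40, component_weights=w, seed=13,
            n_causal_main=6, n_causal_gei=6, n_replicates=1,
        )
        truth = simulate_study(cfg)
        rep = ground_truth_report(truth, "test", 0)
        assert rep.sp_r2_gei < 0.02

    def test_fitted_method_cannot_beat_ground_truth_much(self, small_truth):
        from geiprs.pipeline import evaluate_split, fit_model, prepare, score_split

        design, bundle = prepare(
            small_truth.genotypes, small_truth.environment,
            small_truth.phenotype_replicates[0], small_truth.covariates,
            small_truth.split_assignment,
        )
        fit, _ = fit_model(design, bundle, taus=0.5, M=30, batch_size=10, L=30)
        rep = evaluate_split(bundle, score_split(design, fit, "test"), "test")
        gt = ground_truth_report(small_truth, "test", 0)
        assert rep.overall_r2 <= gt.overall_r2 + 0.05
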