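import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import medipipe as mp
from medipipe.hidim import (
    adjust_fdr_bh,
    adjust_fdr_mixture,
    fit_mediator_models,
    joint_significance,
    pool_candidates,
    run_all_methods,
)
from conftest import adjustment_matrix


class TestMediatorModels:
    def test_exact_proportionality_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        M = pd.DataFrame({"m": 2.0 * x})
        alpha, p, ids = fit_mediator_models(M, x)
        assert alpha[0] == pytest.approx(2.0, abs=1e-10)
        assert p[0] < 1e-30

    def test_matches_per_probe_brute_force(self):
        rng = np.random.default_rng(1)
        n = 90
        x = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        M = pd.DataFrame(
            rng.normal(size=(n, 5)) + np.outer(x, rng.normal(size=5) * 0.3),
            columns=[f"cg{i}" for i in range(5)],
        )
        alpha, p, ids = fit_mediator_models(M, x, C)
        for j, probe in enumerate(ids):
            X = np.column_stack([np.ones(n), x, C])
            coef, *_ = np.linalg.lstsq(X, M[probe].to_numpy(), rcond=None)
            resid = M[probe].to_numpy() - X @ coef
            dof = n - X.shape[1]
            cov = (resid @ resid / dof) * np.linalg.pinv(X.T @ X)
            t = coef[1] / np.sqrt(cov[1, 1])
            assert alpha[j] == pytest.approx(coef[1], abs=1e-10)
            assert p[j] == pytest.approx(2 * stats.t.sf(abs(t), dof), rel=1e-8)

    def test_null_pvalues_uniform(self):
        # probes independent of the exposure give uniform p-values
        rng = np.random.default_rng(2)
        n, p = 150, 1000
        x = rng.normal(size=n)
        M = pd.DataFrame(rng.normal(size=(n, p)))
        _, pvals, _ = fit_mediator_models(M, x)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestJointSignificance:
    def test_scalar_definition(self):
        assert joint_significance([0.01], [0.04])[0] == 0.04
        assert joint_significance([1.0], [0.3])[0] == 1.0

    def test_vector_matches_scalar_map(self):
        pa = np.array([0.1, 0.5, 0.9])
        pb = np.array([0.2, 0.4, 0.95])
        vec = joint_significance(pa, pb)
        for i in range(3):
            assert vec[i] == joint_significance([pa[i]], [pb[i]])[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            joint_significance([1.2], [0.5])

    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=30
        )
    )
    def test_never_below_either_component(self, pairs):
        pa = np.array([a for a, _ in pairs])
        pb = np.array([b for _, b in pairs])
        pj = joint_significance(pa, pb)
        assert (pj >= pa).all() and (pj >= pb).all()


class TestFdr:
    def test_bh_hand_computed_example(self):
        adj = adjust_fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)

    def test_bh_single_and_ties(self):
        assert adjust_fdr_bh([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(adjust_fdr_bh([0.2, 0.2, 0.2]), 0.2)
        assert adjust_fdr_bh([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bh_adjusted_at_least_raw(self, ps):
        adj = adjust_fdr_bh(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_mixture_null_calibration(self):
        rng = np.random.default_rng(3)
        reps, m = 500, 200
        any_flag = 0
        for _ in range(reps):
            flags, _, _ = adjust_fdr_mixture(rng.random(m), rng.random(m), 0.05)
            any_flag += flags.any()
        assert any_flag / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_mixture_flags_overwhelming_signal(self):
        flags, props, q = adjust_fdr_mixture([1e-12] * 10, [1e-12] * 10, 0.05)
        assert flags.all()

    def test_mixture_never_more_conservative_than_bh(self):
        rng = np.random.default_rng(4)
        for r in range(30):
            pa, pb = rng.random(100), rng.random(100)
            pa[:5] *= 1e-6
            pb[:5] *= 1e-6
            flags_mix, _, _ = adjust_fdr_mixture(pa, pb, 0.05)
            bh = adjust_fdr_bh(joint_significance(pa, pb)) < 0.05
            assert (flags_mix | ~bh).all()  # BH-flagged => mixture-flagged

    def test_mixture_power_exceeds_bh_on_mixed_simulation(self):
        pow_mix, pow_bh = [], []
        for r in range(200):
            rng = np.random.default_rng(70_000 + r)
            m, k = 500, 5
            pa, pb = rng.random(m), rng.random(m)
            pa[:k] = 2 * stats.norm.sf(np.abs(rng.normal(4, 1, k)))
            pb[:k] = 2 * stats.norm.sf(np.abs(rng.normal(4, 1, k)))
            pa[k : k + 50] = 2 * stats.norm.sf(np.abs(rng.normal(3, 1, 50)))
            flags, _, _ = adjust_fdr_mixture(pa, pb, 0.05)
            bh = adjust_fdr_bh(joint_significance(pa, pb)) < 0.05
            pow_mix.append(flags[:k].mean())
            pow_bh.append(bh[:k].mean())
        assert np.mean(pow_mix) >= np.mean(pow_bh)

    def test_mixture_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr_mixture([0.1, 0.2], [0.1], 0.05)


@pytest.fixture(scope="module")
def planted_results(small_cohort):
    _, matrix, pheno, truth = small_cohort
    C = adjustment_matrix(pheno)
    results = run_all_methods(
        matrix.beta,
        pheno["gwg"].to_numpy(),
        pheno["z_birthweight"].to_numpy(),
        covariates=C,
        seed=1,
    )
    return results, truth


class TestMethodRuns:
    def test_planted_mediators_become_candidates(self, planted_results):
        results, truth = planted_results
        for res in results.values():
            assert set(truth.true_mediator_ids) <= set(res.candidate_ids())

    def test_pipeline_containment(self, planted_results):
        results, _ = planted_results
        for res in results.values():
            kept = set(res.screen.kept_probe_ids)
            selected = set(res.selected_ids())
            candidates = set(res.candidate_ids())
            assert candidates <= selected <= kept

    def test_accounting_identity(self, planted_results):
        results, _ = planted_results
        for res in results.values():
            assert res.direct_effect + res.global_indirect == pytest.approx(
                res.total_effect, abs=1e-10
            )

    def test_joint_p_dominates_components(self, planted_results):
        results, _ = planted_results
        for res in results.values():
            for c in res.selected:
                assert c.p_joint == max(c.p_alpha, c.p_beta)
                assert c.p_fdr >= 0.0

    def test_hdma_and_hima_agree_on_strong_fixture(self, planted_results):
        results, truth = planted_results
        strong = set(truth.true_mediator_ids)
        assert strong <= set(results["hdma"].candidate_ids())
        assert strong <= set(results["hima"].candidate_ids())

    def test_individual_runners_match_shared_run(self, small_cohort):
        _, matrix, pheno, _ = small_cohort
        C = adjustment_matrix(pheno)
        x = pheno["gwg"].to_numpy()
        y = pheno["z_birthweight"].to_numpy()
        shared = run_all_methods(matrix.beta, x, y, covariates=C, seed=2)
        solo = mp.run_hdma(matrix.beta, x, y, covariates=C, seed=2)
        assert solo.candidate_ids() == shared["hdma"].candidate_ids()
        assert solo.global_indirect == pytest.approx(
            shared["hdma"].global_indirect, abs=1e-12
        )

    def test_unknown_method_rejected(self, small_cohort):
        _, matrix, pheno, _ = small_cohort
        with pytest.raises(ValueError):
            run_all_methods(
                matrix.beta,
                pheno["gwg"].to_numpy(),
                pheno["z_birthweight"].to_numpy(),
                methods=("nope",),
            )


class TestPooling:
    def test_union_with_provenance(self):
        results = [
            ("HDMA", ["cg19242268", "cg08461903", "cg14798382", "cg21516291"]),
            ("HIMA", ["cg19242268", "cg08461903", "cg21516291"]),
            ("HIMA2", ["cg19242268", "cg08461903"]),
        ]
        pooled, prov = pool_candidates(results)
        assert len(pooled) == 4
        assert prov["cg19242268"] == ["HDMA", "HIMA", "HIMA2"]
        assert prov["cg14798382"] == ["HDMA"]

    def test_identical_sets_union_is_that_set(self):
        sets = [("A", ["x", "y"]), ("B", ["x", "y"])]
        pooled, _ = pool_candidates(sets)
        assert pooled == ["x", "y"]

    def test_disjoint_singletons(self):
        pooled, _ = pool_candidates([("A", ["a"]), ("B", ["b"]), ("C", ["c"])])
        assert len(pooled) == 3

    def test_empty_input_gives_empty_set(self):
        pooled, prov = pool_candidates([])
        assert pooled == [] and prov == {}
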