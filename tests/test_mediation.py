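import numpy as np
import pandas as pd
import pytest

from medipipe.mediation import (
    EffectDecomposition,
    MediationModelSpec,
    PathwayEffect,
    UnsupportedTopologyError,
    bootstrap_mediation,
    enumerate_serial_pathways,
    estimate_paths,
    select_serial_mediators,
)


def _hand_ols(design_cols, target):
    n = len(target)
    X = np.column_stack([np.ones(n), *design_cols])
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    return coef[1:]


@pytest.fixture(scope="module")
def serial_fixture():
    rng = np.random.default_rng(3)
    n = 300
    x = rng.normal(size=n)
    m1 = 0.5 * x + rng.normal(0, 0.6, n)
    m2 = 0.3 * x + 0.4 * m1 + rng.normal(0, 0.8, n)
    m3 = 0.2 * x + 0.1 * m1 + 0.6 * m2 + rng.normal(0, 0.5, n)
    y = 0.25 * x + 1.0 * m1 - 0.5 * m2 + 0.8 * m3 + rng.normal(0, 0.7, n)
    M = pd.DataFrame({"m1": m1, "m2": m2, "m3": m3})
    return M, x, y


class TestEnumerateSerialPathways:
    def test_single_mediator_one_pathway(self):
        assert enumerate_serial_pathways(1) == [(0,)]

    def test_two_mediators_three_pathways(self):
        assert enumerate_serial_pathways(2) == [(0,), (1,), (0, 1)]

    def test_three_mediators_seven_labeled_pathways(self):
        chains = enumerate_serial_pathways(3)
        assert chains == [
            (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2),
        ]
        assert len(chains) == 2**3 - 1

    def test_more_than_three_rejected(self):
        with pytest.raises(UnsupportedTopologyError):
            enumerate_serial_pathways(4)


class TestEstimatePaths:
    def test_single_model_closed_form(self):
        rng = np.random.default_rng(0)
        n = 100
        x = rng.normal(size=n)
        a, b, c = 0.7, 1.3, 0.4
        m = a * x + rng.normal(0, 1e-6, n)  # tiny noise keeps the fit identified
        y = b * m + c * x
        M = pd.DataFrame({"m": m})
        spec = MediationModelSpec("X", ["m"], "single", "ols", n_boot=10)
        dec = estimate_paths(M, x, y, None, spec)
        assert dec.pathways[0].estimate == pytest.approx(a * b, abs=1e-6)
        assert dec.direct[0] == pytest.approx(c, abs=1e-6)
        assert dec.total[0] == pytest.approx(a * b + c, abs=1e-6)

    def test_serial_products_match_hand_computed_oracle(self, serial_fixture):
        M, x, y = serial_fixture
        m1, m2, m3 = (M[c].to_numpy() for c in ("m1", "m2", "m3"))
        a1, = _hand_ols([x], m1)
        a2, d12 = _hand_ols([x, m1], m2)
        a3, d13, d23 = _hand_ols([x, m1, m2], m3)
        c, b1, b2, b3 = _hand_ols([x, m1, m2, m3], y)
        expected = [
            a1 * b1, a2 * b2, a3 * b3,
            a1 * d12 * b2, a1 * d13 * b3, a2 * d23 * b3,
            a1 * d12 * d23 * b3,
        ]
        spec = MediationModelSpec("X", ["m1", "m2", "m3"], "serial", "ols", n_boot=10)
        dec = estimate_paths(M, x, y, None, spec)
        for pw, ex in zip(dec.pathways, expected):
            assert pw.estimate == pytest.approx(ex, abs=1e-10)
        assert dec.direct[0] == pytest.approx(c, abs=1e-10)

    def test_decomposition_identities(self, serial_fixture):
        M, x, y = serial_fixture
        spec = MediationModelSpec("X", ["m1", "m2", "m3"], "serial", "ols", n_boot=10)
        dec = estimate_paths(M, x, y, None, spec)
        assert sum(p.estimate for p in dec.pathways) == pytest.approx(
            dec.total_indirect, abs=1e-10
        )
        assert dec.direct[0] + dec.total_indirect == pytest.approx(
            dec.total[0], abs=1e-10
        )

    def test_serial_reduces_to_parallel_without_cross_effects(self):
        # cross-mediator sample coefficients forced to exactly zero
        rng = np.random.default_rng(5)
        n = 250
        x = rng.normal(size=n)

        def _residualize(v, basis):
            B = np.column_stack([np.ones(n), *basis])
            q, _ = np.linalg.qr(B)
            return v - q @ (q.T @ v)

        m1 = 0.5 * x + rng.normal(0, 0.5, n)
        e2 = _residualize(rng.normal(0, 0.5, n), [x, m1])
        m2 = 0.3 * x + e2
        e3 = _residualize(rng.normal(0, 0.5, n), [x, m1, m2])
        m3 = 0.2 * x + e3
        y = 0.1 * x + m1 + 0.5 * m2 - 0.5 * m3 + rng.normal(0, 0.5, n)
        M = pd.DataFrame({"m1": m1, "m2": m2, "m3": m3})
        sspec = MediationModelSpec("X", ["m1", "m2", "m3"], "serial", "ols", n_boot=10)
        pspec = MediationModelSpec("X", ["m1", "m2", "m3"], "parallel", "ols", n_boot=10)
        ser = estimate_paths(M, x, y, None, sspec)
        par = estimate_paths(M, x, y, None, pspec)
        for chain in [("m1",), ("m2",), ("m3",)]:
            assert ser.pathway(chain).estimate == pytest.approx(
                par.pathway(chain).estimate, abs=1e-8
            )
        for pw in ser.pathways:
            if len(pw.mediator_chain) > 1:
                assert pw.estimate == pytest.approx(0.0, abs=1e-8)

    def test_parallel_null_mediators_estimate_near_zero(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        M = pd.DataFrame({"m1": rng.normal(size=n), "m2": rng.normal(size=n)})
        y = 0.5 * x + rng.normal(size=n)
        spec = MediationModelSpec("X", ["m1", "m2"], "parallel", "ols", n_boot=200, seed=1)
        dec, draws = bootstrap_mediation(M, x, y, None, spec, return_draws=True)
        for j, pw in enumerate(dec.pathways):
            assert abs(pw.estimate) < 3 * draws[:, j].std()

    def test_missing_mediator_rejected(self, serial_fixture):
        M, x, y = serial_fixture
        spec = MediationModelSpec("X", ["nope"], "single", "ols", n_boot=10)
        with pytest.raises(KeyError):
            estimate_paths(M, x, y, None, spec)

    def test_robust_estimator_agrees_on_clean_data(self, serial_fixture):
        M, x, y = serial_fixture
        so = MediationModelSpec("X", ["m1"], "single", "ols", n_boot=10)
        sr = MediationModelSpec("X", ["m1"], "single", "robust", n_boot=10)
        do = estimate_paths(M, x, y, None, so)
        dr = estimate_paths(M, x, y, None, sr)
        assert dr.pathways[0].estimate == pytest.approx(
            do.pathways[0].estimate, abs=0.05
        )


class TestBootstrap:
    def test_percentile_bounds_equal_draw_quantiles(self):
        rng = np.random.default_rng(7)
        n = 200
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.6 * m + 0.2 * x + rng.normal(size=n)
        spec = MediationModelSpec("X", ["m"], "single", "ols", n_boot=400, seed=11)
        dec, draws = bootstrap_mediation(
            pd.DataFrame({"m": m}), x, y, None, spec, return_draws=True
        )
        assert dec.pathways[0].ci_low == pytest.approx(
            np.quantile(draws[:, 0], 0.025), abs=1e-12
        )
        assert dec.pathways[0].ci_high == pytest.approx(
            np.quantile(draws[:, 0], 0.975), abs=1e-12
        )

    def test_null_mediator_ci_covers_zero_at_nominal_rate(self):
        covered = 0
        reps = 200
        for r in range(reps):
            rng = np.random.default_rng(80_000 + r)
            n = 150
            x = rng.normal(size=n)
            m = rng.normal(size=n)  # unrelated to x and y
            y = 0.4 * x + rng.normal(size=n)
            spec = MediationModelSpec("X", ["m"], "single", "ols", n_boot=199, seed=r)
            dec = bootstrap_mediation(pd.DataFrame({"m": m}), x, y, None, spec)
            if dec.pathways[0].ci_low <= 0.0 <= dec.pathways[0].ci_high:
                covered += 1
        assert 0.90 <= covered / reps <= 0.99

    def test_strong_mediation_detected_with_high_power(self):
        detected = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(90_000 + r)
            n = 500
            x = rng.normal(size=n)
            m = 0.6 * x + rng.normal(size=n)
            y = 0.6 * m + 0.2 * x + rng.normal(size=n)
            spec = MediationModelSpec("X", ["m"], "single", "ols", n_boot=199, seed=r)
            dec = bootstrap_mediation(pd.DataFrame({"m": m}), x, y, None, spec)
            if dec.pathways[0].significant:
                detected += 1
        assert detected / reps >= 0.99

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = m + rng.normal(size=n)
        spec = MediationModelSpec("X", ["m"], "single", "ols", n_boot=100, seed=5)
        d1 = bootstrap_mediation(pd.DataFrame({"m": m}), x, y, None, spec)
        d2 = bootstrap_mediation(pd.DataFrame({"m": m}), x, y, None, spec)
        assert d1.pathways[0].ci_low == d2.pathways[0].ci_low
        assert d1.total_indirect_ci == d2.total_indirect_ci


class TestModelSpecValidation:
    def test_single_requires_one_mediator(self):
        with pytest.raises(ValueError):
            MediationModelSpec("X", ["a", "b"], "single")

    def test_serial_capped_at_three(self):
        with pytest.raises(UnsupportedTopologyError):
            MediationModelSpec("X", ["a", "b", "c", "d"], "serial")

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError):
            MediationModelSpec("X", ["a"], "fancy")


def _single_result(probe, estimate, significant):
    return EffectDecomposition(
        pathways=[
            PathwayEffect(
                label=f"X -> {probe} -> Y",
                mediator_chain=(probe,),
                estimate=estimate,
                ci_low=0.001 if significant else -0.001,
                ci_high=estimate + 0.01,
                significant=significant,
            )
        ],
        total_indirect=estimate,
        total_indirect_ci=None,
        direct=(0.0, 0.0, 1.0),
        total=(estimate, 0.0, 1.0),
    )


class TestSelectSerialMediators:
    def test_significant_first_then_magnitude(self):
        singles = [
            _single_result("cg19242268", 0.0026, True),
            _single_result("cg08461903", 0.0019, False),
            _single_result("cg14798382", 0.0042, True),
            _single_result("cg21516291", 0.0019, False),
        ]
        assert select_serial_mediators(singles, 3) == [
            "cg14798382", "cg19242268", "cg08461903",
        ]

    def test_all_tied_stable_by_probe_id(self):
        singles = [
            _single_result("cgB", 0.001, False),
            _single_result("cgA", 0.001, False),
        ]
        assert select_serial_mediators(singles, 2) == ["cgA", "cgB"]

    def test_k_zero_empty(self):
        assert select_serial_mediators([_single_result("cgA", 0.1, True)], 0) == []

    def test_fewer_candidates_than_k_returns_all(self):
        singles = [_single_result("cgA", 0.1, True)]
        assert select_serial_mediators(singles, 3) == ["cgA"]
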