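"""ETEL core: dual solve, weights, likelihood, feasibility."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from betel.etel import (
    SolverSettings,
    check_feasibility,
    etel_loglik,
    etel_weights,
    solve_dual,
)
from betel.exceptions import NonConvergenceError, ValidationError
from betel.moments import design_mean_model
from betel.simulation import gen_design_data

from conftest import feasible_random_instance

TIGHT = SolverSettings(tol=1e-12)


def primal_entropy_maximizer(G):
    """Independent oracle: direct constrained maximization of the entropy
    sum(-p log p) on the simplex subject to the moment constraint."""
    n, m = G.shape

    def neg_entropy(p):
        return float(np.sum(p * np.log(np.maximum(p, 1e-300))))

    cons = [
        {"type": "eq", "fun": lambda p: p.sum() - 1.0},
        {"type": "eq", "fun": lambda p: G.T @ p},
    ]
    res = minimize(
        neg_entropy,
        np.full(n, 1.0 / n),
        method="SLSQP",
        bounds=[(1e-12, 1.0)] * n,
        constraints=cons,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x, -res.fun


class TestDualClosedForm:
    @pytest.mark.parametrize("a,b", [(-1.0, 2.0), (-3.0, 0.5), (-0.2, 0.7)])
    def test_two_point_tilt(self, a, b):
        # closed form for n=2, m=1 with a < 0 < b: lam = ln(-a/b)/(b-a)
        G = np.array([[a], [b]])
        lam, _, conv = solve_dual(G, TIGHT)
        assert conv
        assert lam[0] == pytest.approx(np.log(-a / b) / (b - a), abs=1e-10)
        p = etel_weights(G, lam)
        assert float(p @ G[:, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_known_instance_weights_and_loglik(self):
        G = np.array([[-1.0], [2.0]])
        ev = etel_loglik(G, TIGHT)
        assert ev.feasible and ev.converged
        np.testing.assert_allclose(ev.p, [2.0 / 3.0, 1.0 / 3.0], atol=1e-10)
        assert ev.loglik == pytest.approx(np.log(8.0 / 9.0), abs=1e-10)

    def test_centered_data_gives_zero_tilt(self):
        G = np.array([[-1.0], [1.0]])
        lam, it, conv = solve_dual(G, TIGHT)
        assert conv and it == 0 and lam[0] == 0.0
        assert etel_loglik(G, TIGHT).loglik == 0.0


class TestFeasibility:
    def test_origin_between_rows(self):
        assert check_feasibility(np.array([[-1.0], [2.0]]))

    def test_exhaustive_convex_combination_oracle(self):
        # brute-force search over the weight grid agrees with the LP
        G = np.array([[-1.0], [2.0]])
        grid = np.linspace(0.0, 1.0, 2001)
        vals = grid * G[0, 0] + (1 - grid) * G[1, 0]
        assert np.min(np.abs(vals)) < 1e-3
        assert check_feasibility(G)

    def test_one_sided_rows_infeasible(self):
        assert not check_feasibility(np.array([[1.0], [2.0]]))

    def test_single_zero_row_feasible(self):
        assert check_feasibility(np.zeros((1, 2)))

    def test_single_nonzero_row_infeasible(self):
        assert not check_feasibility(np.array([[0.5, 0.0]]))
        assert etel_loglik(np.array([[0.5]])).loglik == -np.inf

    def test_degenerate_single_zero_row_loglik(self):
        ev = etel_loglik(np.zeros((1, 1)))
        assert ev.feasible and ev.loglik == 0.0

    @given(
        st.integers(2, 8),
        st.integers(1, 3),
        st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_appending_negated_sum_row_makes_feasible(self, n, m, seed):
        rng = np.random.default_rng(seed)
        G = feasible_random_instance(rng, n + 1, m)
        assert check_feasibility(G)
        ev = etel_loglik(G)
        assert ev.feasible

    def test_infeasible_evaluation_has_sentinel(self):
        ev = etel_loglik(np.array([[1.0], [2.0]]))
        assert not ev.feasible
        assert ev.loglik == -np.inf
        assert ev.lam is None and ev.p is None


class TestWeights:
    def test_zero_tilt_uniform(self):
        G = np.random.default_rng(0).standard_normal((7, 2))
        np.testing.assert_allclose(etel_weights(G, np.zeros(2)), np.full(7, 1 / 7))

    def test_repeated_row_uniform_for_any_tilt(self):
        G = np.tile([[1.3, -0.2]], (5, 1))
        np.testing.assert_allclose(etel_weights(G, [3.0, -1.0]), np.full(5, 0.2))

    def test_no_overflow_for_extreme_inputs(self):
        G = np.array([[700.0], [-700.0]])
        p = etel_weights(G, np.array([2.0]))
        assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,m,seed", [(6, 1, 0), (10, 2, 1), (12, 3, 2), (9, 2, 3)])
    def test_dual_matches_primal_entropy_maximizer(self, n, m, seed):
        rng = np.random.default_rng(seed)
        G = feasible_random_instance(rng, n, m)
        ev = etel_loglik(G, TIGHT)
        assert ev.feasible
        p_oracle, ent_oracle = primal_entropy_maximizer(G)
        ent_dual = float(-np.sum(ev.p * np.log(ev.p)))
        assert ent_dual == pytest.approx(ent_oracle, abs=1e-6)
        np.testing.assert_allclose(ev.p, p_oracle, atol=1e-5)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_simplex_conservation_and_constraint(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(4, 40)), int(rng.integers(1, 4))
        G = feasible_random_instance(rng, n, m)
        s = SolverSettings(tol=1e-9)
        ev = etel_loglik(G, s)
        assert ev.feasible
        assert np.all(ev.p > 0)
        assert ev.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(ev.p @ G)) <= 10 * s.tol
        assert ev.loglik <= 0.0

    def test_loglik_zero_iff_mean_zero(self):
        rng = np.random.default_rng(5)
        G = feasible_random_instance(rng, 8, 2)
        ev = etel_loglik(G, TIGHT)
        if np.max(np.abs(G.mean(axis=0))) > 1e-8:
            assert ev.loglik < 0.0
        Gc = G - G.mean(axis=0)
        assert etel_loglik(Gc, TIGHT).loglik == pytest.approx(0.0, abs=1e-12)

    def test_dual_mode_matches_lp_mode(self):
        rng = np.random.default_rng(9)
        cases = [feasible_random_instance(rng, int(rng.integers(4, 20)), m)
                 for m in (2, 3, 2, 3)]
        # clearly infeasible: origin outside a shifted cloud
        cases.append(rng.standard_normal((10, 2)) + 8.0)
        for G in cases:
            a = etel_loglik(G, feasibility="lp")
            b = etel_loglik(G, feasibility="dual")
            assert a.feasible == b.feasible
            if a.feasible:
                assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_boundary_origin_rejected(self):
        # origin is a vertex/edge of the hull: weights would need a zero
        G = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ev = etel_loglik(G, feasibility="dual")
        assert not ev.feasible and ev.loglik == -np.inf

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            etel_loglik(np.array([[np.nan], [1.0]]))
        with pytest.raises(ValidationError):
            etel_weights(np.array([[1.0]]), np.array([np.inf]))


class TestSeparation:
    def test_likelihood_ratio_outside_ball_decays_with_n(self):
        """The ETEL concentrates: away from the maximizer the likelihood
        ratio shrinks superpolynomially as n grows (checked in aggregate
        over seeded replications)."""
        model = design_mean_model()
        ratios = {50: [], 200: []}
        for n in ratios:
            for seed in range(12):
                df = gen_design_data(n, seed=seed)
                from betel.moments import hajek_mean

                th = hajek_mean(df)
                ll_hat = etel_loglik(model.moments(df, np.array([th]))).loglik
                grid = [t for t in np.linspace(0.02, 0.98, 25) if abs(t - th) >= 0.2]
                best = max(
                    etel_loglik(model.moments(df, np.array([t]))).loglik
                    for t in grid
                )
                ratios[n].append(best - ll_hat)
        assert np.mean(ratios[200]) < np.mean(ratios[50]) < 0.0
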