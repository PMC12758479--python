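"""Unit tests for the unbalanced entropic OT solver and its companions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from ottehr import (
    CostMatrix,
    DiscreteMeasure,
    OTConfig,
    TransportPlan,
    barycentric_projection,
    build_cost_matrix,
    plan_unbalancedness,
    solve_ugw,
    solve_unbalanced_ot,
)
from ottehr.ot import gw_discrepancy, read_plan, write_plan

from oracles import grid_oracle_ugw, grid_oracle_uot, ugw_objective, uot_objective


def uniform(points):
    return DiscreteMeasure.uniform(np.asarray(points, dtype=float))


class TestCostMatrix:
    def test_three_four_five(self):
        cost = build_cost_matrix(uniform([[0, 0]]), uniform([[3, 4]]))
        np.testing.assert_allclose(cost.values, [[5.0]])

    def test_symmetric_zero_diagonal(self):
        m = uniform([[1, 1], [2, 2]])
        cost = build_cost_matrix(m, m).values
        np.testing.assert_allclose(cost, [[0, np.sqrt(2)], [np.sqrt(2), 0]],
                                   atol=1e-15)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(3, 2)), rng.normal(size=(2, 2))
        cost = build_cost_matrix(uniform(a), uniform(b)).values
        for i in range(3):
            for j in range(2):
                assert cost[i, j] == np.linalg.norm(a[i] - b[j])

    def test_dimension_mismatch_names_both(self):
        with pytest.raises(ValueError, match="2.*3|3.*2"):
            build_cost_matrix(uniform([[0, 0]]), uniform([[0, 0, 0]]))


class TestUnbalancedSolver:
    def test_zero_cost_singleton_preserves_mass(self):
        A = DiscreteMeasure([[0.0]], [1.0])
        B = DiscreteMeasure([[0.0]], [1.0])
        plan = solve_unbalanced_ot(A, B, CostMatrix([[0.0]]), OTConfig())
        assert plan.coupling[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_two_by_two_against_grid_oracle(self):
        # line supports {0, 1} on both sides, uniform half masses
        A = DiscreteMeasure([[0.0], [1.0]], [0.5, 0.5])
        B = DiscreteMeasure([[0.0], [1.0]], [0.5, 0.5])
        config = OTConfig(entropic_reg=10.0, mass_reg=10.0)
        cost = build_cost_matrix(A, B)
        plan = solve_unbalanced_ot(A, B, cost, config)
        _, oracle_obj = grid_oracle_uot(cost.values, A.mass, B.mass,
                                        lam=10.0, rho=10.0, step=0.005)
        assert plan.objective <= oracle_obj + 1e-2

    def test_objective_consistent_with_loop_restatement(self):
        rng = np.random.default_rng(3)
        A = DiscreteMeasure(rng.normal(size=(4, 2)), np.full(4, 0.25))
        B = DiscreteMeasure(rng.normal(size=(3, 2)), np.full(3, 1 / 3))
        config = OTConfig(entropic_reg=2.0, mass_reg=1.5)
        cost = build_cost_matrix(A, B)
        plan = solve_unbalanced_ot(A, B, cost, config)
        expected = uot_objective(plan.coupling, cost.values, A.mass, B.mass,
                                 lam=2.0, rho=1.5)
        assert plan.objective == pytest.approx(expected, rel=1e-10)

    def test_balanced_mode_hits_marginals(self):
        rng = np.random.default_rng(1)
        A = DiscreteMeasure(rng.normal(size=(3, 2)), np.array([0.2, 0.3, 0.5]))
        B = DiscreteMeasure(rng.normal(size=(4, 2)), np.full(4, 0.25))
        config = OTConfig(entropic_reg=1.0, mode="balanced_entropic")
        plan = solve_unbalanced_ot(A, B, build_cost_matrix(A, B), config)
        np.testing.assert_allclose(plan.row_marginal, A.mass, atol=1e-6)
        np.testing.assert_allclose(plan.col_marginal, B.mass, atol=1e-6)
        # relaxing the constraints can only lower the optimum
        relaxed = solve_unbalanced_ot(
            A, B, build_cost_matrix(A, B),
            OTConfig(entropic_reg=1.0, mass_reg=1e4),
        )
        assert plan.objective >= relaxed.objective - 1e-6

    def test_balanced_mode_rejects_unequal_totals(self):
        A = DiscreteMeasure([[0.0]], [1.0])
        B = DiscreteMeasure([[1.0]], [2.0])
        with pytest.raises(ValueError, match="equal total"):
            solve_unbalanced_ot(A, B, CostMatrix([[1.0]]),
                                OTConfig(mode="balanced_entropic"))

    def test_shape_mismatch_rejected(self):
        A = DiscreteMeasure([[0.0], [1.0]], [0.5, 0.5])
        B = DiscreteMeasure([[0.0]], [1.0])
        with pytest.raises(ValueError, match="cost shape"):
            solve_unbalanced_ot(A, B, CostMatrix([[0.0]]), OTConfig())

    def test_symmetry_under_transposition(self):
        rng = np.random.default_rng(9)
        A = DiscreteMeasure(rng.normal(size=(3, 2)), rng.random(3) + 0.1)
        B = DiscreteMeasure(rng.normal(size=(4, 2)), rng.random(4) + 0.1)
        config = OTConfig(entropic_reg=1.0, mass_reg=2.0)
        fwd = solve_unbalanced_ot(A, B, build_cost_matrix(A, B), config)
        bwd = solve_unbalanced_ot(B, A, build_cost_matrix(B, A), config)
        np.testing.assert_allclose(fwd.coupling, bwd.coupling.T, atol=1e-8)

    def test_marginal_fields_match_coupling(self):
        rng = np.random.default_rng(2)
        A = DiscreteMeasure(rng.normal(size=(3, 1)), np.full(3, 1 / 3))
        B = DiscreteMeasure(rng.normal(size=(5, 1)), np.full(5, 0.2))
        plan = solve_unbalanced_ot(A, B, build_cost_matrix(A, B), OTConfig())
        np.testing.assert_allclose(plan.row_marginal, plan.coupling.sum(axis=1),
                                   atol=1e-10)
        np.testing.assert_allclose(plan.col_marginal, plan.coupling.sum(axis=0),
                                   atol=1e-10)


class TestGromovWasserstein:
    def test_never_worse_than_product_coupling_seed(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        A = B = DiscreteMeasure.uniform(pts)
        config = OTConfig(entropic_reg=20.0, mass_reg=5.0)
        plan = solve_ugw(A, B, config)
        d = cdist(pts, pts)
        product = np.outer(A.mass, B.mass)
        assert gw_discrepancy(d, d, plan.coupling) <= (
            gw_discrepancy(d, d, product) + 1e-9
        )

    def test_isometry_invariance_across_dimensions(self):
        # same intra-domain spacings (1, 2), embedded in 5-D and shifted
        pts = np.array([[0.0], [1.0], [3.0]])
        A = DiscreteMeasure.uniform(pts)
        emb = np.zeros((3, 5))
        emb[:, 2] = pts[:, 0] + 100.0
        B = DiscreteMeasure.uniform(emb)
        plan = solve_ugw(A, B, OTConfig(entropic_reg=20.0, mass_reg=5.0))
        assert plan.transport_cost == pytest.approx(0.0, abs=1e-3)

    def test_three_by_three_against_grid_oracle(self):
        rng = np.random.default_rng(12)
        A = DiscreteMeasure(rng.normal(size=(3, 2)), np.full(3, 1 / 3))
        B = DiscreteMeasure(rng.normal(size=(3, 4)), np.full(3, 1 / 3))
        config = OTConfig(entropic_reg=10.0, mass_reg=10.0)
        plan = solve_ugw(A, B, config)
        d_a = cdist(A.support, A.support)
        d_b = cdist(B.support, B.support)
        solver_obj = ugw_objective(plan.coupling, d_a, d_b, A.mass, B.mass,
                                   lam=10.0, rho=10.0)
        _, oracle_obj = grid_oracle_ugw(d_a, d_b, A.mass, B.mass,
                                        lam=10.0, rho=10.0, step=0.02)
        assert solver_obj <= oracle_obj + 5e-2 * abs(oracle_obj)

    def test_rejects_single_point_side(self):
        A = DiscreteMeasure([[0.0]], [1.0])
        B = DiscreteMeasure([[0.0], [1.0]], [0.5, 0.5])
        with pytest.raises(ValueError, match=">= 2 points"):
            solve_ugw(A, B, OTConfig())


class TestBarycentricProjection:
    def test_single_nonzero_entry_selects_source_point(self):
        plan = TransportPlan(np.array([[0.0, 0.7, 0.0]]))
        B = uniform([[1, 1], [2, 5], [9, 9]])
        out = barycentric_projection(plan, B)
        np.testing.assert_array_equal(out[0], [2.0, 5.0])

    def test_equal_weights_give_midpoint(self):
        plan = TransportPlan(np.array([[0.2, 0.2]]))
        B = uniform([[0, 0], [2, 2]])
        assert barycentric_projection(plan, B)[0] == pytest.approx([1.0, 1.0])

    def test_matches_weighted_average_recomputation(self):
        rng = np.random.default_rng(7)
        coupling = rng.random((3, 2)) + 0.01
        B = uniform(rng.normal(size=(2, 4)))
        out = barycentric_projection(TransportPlan(coupling), B)
        for i in range(3):
            expected = sum(coupling[i, j] * B.support[j] for j in range(2))
            expected /= coupling[i].sum()
            np.testing.assert_allclose(out[i], expected, atol=1e-12)

    def test_zero_rows_returned_missing(self):
        plan = TransportPlan(np.array([[0.0, 0.0], [0.5, 0.5]]))
        out = barycentric_projection(plan, uniform([[0, 0], [2, 2]]))
        assert np.isnan(out[0]).all()
        assert out[1] == pytest.approx([1.0, 1.0])

    def test_all_zero_rows_error(self):
        plan = TransportPlan(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty transport"):
            barycentric_projection(plan, uniform([[0, 0], [1, 1]]))

    def test_permutation_equivariance_in_b_ordering(self):
        rng = np.random.default_rng(8)
        coupling = rng.random((4, 5)) + 0.01
        support = rng.normal(size=(5, 3))
        perm = rng.permutation(5)
        out = barycentric_projection(TransportPlan(coupling), uniform(support))
        out_perm = barycentric_projection(
            TransportPlan(coupling[:, perm]), uniform(support[perm])
        )
        np.testing.assert_allclose(out, out_perm, atol=1e-12)


class TestUnbalancedness:
    def test_exact_rows_give_zero(self):
        plan = TransportPlan(np.array([[0.25, 0.25], [0.1, 0.4]]))
        assert plan_unbalancedness(plan, plan.row_marginal) == 0.0

    def test_arithmetic(self):
        plan = TransportPlan(np.array([[0.4, 0.0], [0.0, 0.4]]))
        assert plan_unbalancedness(plan, np.array([0.5, 0.5])) == pytest.approx(0.2)

    def test_length_mismatch(self):
        plan = TransportPlan(np.array([[1.0]]))
        with pytest.raises(ValueError, match="length"):
            plan_unbalancedness(plan, np.array([1.0, 2.0]))

    def test_large_rho_limit_on_balanced_instance(self):
        rng = np.random.default_rng(4)
        A = DiscreteMeasure(rng.normal(size=(4, 2)), np.full(4, 0.25))
        B = DiscreteMeasure(rng.normal(size=(4, 2)), np.full(4, 0.25))
        config = OTConfig(entropic_reg=1.0, mass_reg=1e4)
        plan = solve_unbalanced_ot(A, B, build_cost_matrix(A, B), config)
        assert plan_unbalancedness(plan, A.mass) <= 1e-3


def test_plan_roundtrip_preserves_coupling_and_params(tmp_path):
    rng = np.random.default_rng(6)
    A = DiscreteMeasure(rng.normal(size=(3, 2)), np.full(3, 1 / 3))
    B = DiscreteMeasure(rng.normal(size=(2, 2)), np.full(2, 0.5))
    config = OTConfig(entropic_reg=0.5, mass_reg=2.0)
    plan = solve_unbalanced_ot(A, B, build_cost_matrix(A, B), config)
    path = tmp_path / "plan.tsv"
    write_plan(plan, config, path)
    coupling, params = read_plan(path)
    np.testing.assert_allclose(coupling, plan.coupling, rtol=1e-12)
    assert params["lambda"] == 0.5
    assert params["rho"] == 2.0
    assert params["mode"] == "unbalanced_entropic"


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_total_coupling_mass_finite(seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(1, 5, size=2)
    A = DiscreteMeasure(rng.normal(size=(n, 2)), rng.random(n) + 0.05)
    B = DiscreteMeasure(rng.normal(size=(m, 2)), rng.random(m) + 0.05)
    config = OTConfig(entropic_reg=float(rng.uniform(0.1, 10)),
                      mass_reg=float(rng.uniform(0.5, 10)))
    plan = solve_unbalanced_ot(A, B, build_cost_matrix(A, B), config)
    assert np.isfinite(plan.coupling).all()
    assert (plan.coupling >= 0).all()
    assert np.isfinite(plan.coupling.sum())
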