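"""The cycle-splitting solver: worked solves, transformations, full runs."""

import numpy as np
import pytest
import sympy as sp

from crnsteady.conserved import find_conserved_quantities, stoichiometric_cqs
from crnsteady.graph import PairType, state_equation
from crnsteady.model import generate_random_network, parse_network, positive_symbol
from crnsteady.solver import (
    NoPositiveSolutionError,
    Provenance,
    eliminate_to_univariate,
    ratio_transform,
    solve_flux_parameter,
    solve_steady_state,
    split_cycle_type0,
)
from conftest import evaluate_positive, sym

A, B, C, X = (sym(s) for s in "ABCX")
k1, k2, k3, k4, k5 = (sym(f"k{i}") for i in range(1, 6))
q1 = sym("q1")


def equation(expr):
    return state_equation(expr, X)


class TestWorkedSolves:
    """The four printed example solves of a dimerization/degradation
    equation, reproduced symbolically."""

    def test_solve_for_influx_parameter(self):
        eq = equation(k1 * A**2 - k2 * X)
        a = solve_flux_parameter(eq, k1)
        assert sp.cancel(a.expression - k2 * X / A**2) == 0

    def test_solve_for_outflux_parameter(self):
        eq = equation(k1 * A**2 - k2 * X)
        a = solve_flux_parameter(eq, k2)
        assert sp.cancel(a.expression - k1 * A**2 / X) == 0

    def test_solve_with_three_outfluxes(self):
        eq = equation(k1 * A**2 - k2 * X - k3 * X * B - k4 * X / (q1 + C))
        a = solve_flux_parameter(eq, k1)
        expected = (X / A**2) * (k2 + k3 * B + k4 / (q1 + C))
        assert sp.simplify(a.expression - expected) == 0

    def test_two_influx_ratio_transform(self):
        eq = equation(
            k1 * A**2 + k5 * B - k2 * X - k3 * X * B - k4 * X / (q1 + C)
        )
        assignments = ratio_transform(eq, k1, side="influx")
        assert [a.target for a in assignments] == [k1, k5]
        assert assignments[1].provenance is Provenance.RATIO_DEFINITION
        (r,) = sorted(
            assignments[0].expression.free_symbols
            - {A, B, C, X, k2, k3, k4, q1},
            key=str,
        )
        outflux_sum = X * (k2 + k3 * B + k4 / (q1 + C))
        assert sp.simplify(
            assignments[0].expression - outflux_sum / (A**2 * (1 + r))
        ) == 0
        assert sp.simplify(
            assignments[1].expression - outflux_sum * r / (B * (1 + r))
        ) == 0

    def test_transform_residual_is_zero(self):
        expr = k1 * A**2 + k5 * B - k2 * X - k3 * X * B - k4 * X / (q1 + C)
        assignments = ratio_transform(equation(expr), k1)
        subs = {a.target: a.expression for a in assignments}
        assert sp.simplify(expr.subs(subs)) == 0

    def test_single_influx_degenerates_to_direct_solve(self):
        expr = k1 * A**2 - k2 * X - k3 * X * B
        via_ratio = ratio_transform(equation(expr), k1, side="influx")
        direct = solve_flux_parameter(equation(expr), k1)
        assert len(via_ratio) == 1
        assert sp.simplify(via_ratio[0].expression - direct.expression) == 0

    def test_direct_solve_refuses_shared_side(self):
        eq = equation(k1 * A**2 + k5 * B - k2 * X)
        with pytest.raises(NoPositiveSolutionError):
            solve_flux_parameter(eq, k1)

    def test_expressions_are_subtraction_free_positive(self):
        eq = equation(
            k1 * A**2 + k5 * B - k2 * X - k3 * X * B - k4 * X / (q1 + C)
        )
        for a in ratio_transform(eq, k1):
            assert a.expression.is_positive


class TestType0:
    def test_frees_the_cq_state(self, six_state):
        cqs = find_conserved_quantities(six_state)
        freed, cq = split_cycle_type0([sym("D"), sym("G")], cqs)
        assert freed == sym("G")
        assert cq.used

    def test_cycle_disjoint_from_cqs(self, six_state):
        cqs = find_conserved_quantities(six_state)
        with pytest.raises(LookupError):
            split_cycle_type0([sym("A")], cqs)

    def test_each_cq_used_once(self, six_state):
        cqs = find_conserved_quantities(six_state)
        split_cycle_type0([sym("G")], cqs)
        with pytest.raises(LookupError):
            split_cycle_type0([sym("F")], cqs)


class TestSixStateRun:
    def test_loop_trace_matches_expected_move_sequence(self, six_state_solution):
        trace = six_state_solution.trace
        assert [r.pair_type for r in trace] == [
            PairType.TYPE3,
            PairType.TYPE1,
            PairType.TYPE0,
        ]
        assert trace[0].state == sym("A")
        assert set(trace[0].solved) == {sym("k0"), sym("k2")}
        assert trace[1].state == sym("B")
        assert trace[1].solved == [sym("k1")]
        assert trace[2].state == sym("G")
        tree = [
            a.target
            for a in six_state_solution.assignments
            if a.provenance is Provenance.TREE_SOLVE
        ]
        assert tree == [sym("C"), sym("D"), sym("F")]

    def test_fixes_six_quantities_with_one_free_ratio(self, six_state_solution):
        sol = six_state_solution
        assert sol.n_fixed == 6
        assert [str(r) for r in sol.ratio_parameters] == ["r1"]
        free = sol.free_symbols()
        assert {sym("A"), sym("B"), sym("G"), sym("r1")} <= free
        assert free & {sym("k0"), sym("k1"), sym("k2")} == set()

    def test_counting_invariant(self, six_state, six_state_solution):
        rank = int(np.linalg.matrix_rank(six_state.stoichiometry))
        sol = six_state_solution
        assert sol.n_fixed - sol.n_ratio_definitions == rank == 5

    def test_residuals_vanish_symbolically(self, six_state_solution):
        assert all(r == 0 for r in six_state_solution.residuals())

    def test_positivity_on_random_draws(self, six_state_solution):
        form = six_state_solution.independent_form
        free = sorted(six_state_solution.free_symbols(), key=str)
        values = evaluate_positive(
            [a.expression for a in form], free, np.random.default_rng(3), n=50
        )
        assert (values > 0).all()


class TestThreeStateRun:
    def test_fixes_b_c_k1_leaving_a_free(self, three_state_solution):
        sol = three_state_solution
        assert set(sol.fixed_targets) == {sym("k1"), sym("B"), sym("C")}
        assert sol.free_states == [sym("A")]
        assert sol.ratio_parameters == []

    def test_k1_expression_matches_closed_form(self, three_state_solution):
        k1_expr = next(
            a.expression
            for a in three_state_solution.independent_form
            if a.target == sym("k1")
        )
        expected = sym("A") * sym("k2") * sym("k3") * sym("k5") / (
            sym("k4") * sym("k6")
        ) + sym("k0") / sym("A")
        assert sp.simplify(k1_expr - expected) == 0

    def test_b_and_c_closed_forms(self, three_state_solution):
        subs = three_state_solution.substitution_map()
        assert sp.simplify(subs[sym("B")] - sym("A") * sym("k2") / sym("k4")) == 0
        expected_c = sym("A") ** 2 * sym("k2") * sym("k5") / (sym("k4") * sym("k6"))
        assert sp.simplify(subs[sym("C")] - expected_c) == 0


class TestEdgeCases:
    def test_tree_like_chain_solves_without_fixing_parameters(self):
        net = parse_network("0 -> A ; k0\nA -> B ; k1*A\nB -> 0 ; k2*B")
        sol = solve_steady_state(net)
        assert all(a.provenance is Provenance.TREE_SOLVE for a in sol.assignments)
        assert sol.ratio_parameters == []
        assert all(r == 0 for r in sol.residuals())

    def test_state_without_outflux_is_unsolvable(self):
        net = parse_network("0 -> A ; k0")
        with pytest.raises(ValueError):
            solve_steady_state(net)

    def test_back_substitution_is_idempotent(self, six_state_solution):
        from crnsteady.solver import back_substitute

        again = back_substitute(six_state_solution)
        targets = set(a.target for a in again.independent_form)
        for a in again.independent_form:
            assert not (a.expression.free_symbols & targets)


class TestElimination:
    def test_six_state_state_solve_needs_degree_six(self, six_state):
        poly = eliminate_to_univariate(six_state, sym("A"))
        assert poly.degree() == 6

    def test_four_state_state_solve_is_linear(self, four_state):
        poly = eliminate_to_univariate(four_state, sym("A"))
        assert poly.degree() == 1

    def test_three_state_state_solve_is_quadratic(self, three_state):
        poly = eliminate_to_univariate(three_state, sym("A"))
        assert poly.degree() == 2


def _try_solve(seed):
    net = generate_random_network(4, 7, seed=seed)
    try:
        return net, solve_steady_state(net, detect_state_dependent_cqs=False)
    except (NoPositiveSolutionError, ValueError):
        return net, None


class TestRandomFixtures:
    """Positivity, residual and counting invariants on generated networks."""

    def test_solvable_fixtures_satisfy_invariants(self):
        solved = 0
        rng = np.random.default_rng(0)
        for seed in range(12):
            net, sol = _try_solve(seed)
            if sol is None:
                continue
            solved += 1
            assert all(r == 0 for r in sol.residuals())
            n_cq = len(stoichiometric_cqs(net))
            rank = net.n_states - n_cq
            assert sol.n_fixed - sol.n_ratio_definitions == rank
            form = sol.independent_form
            free = sorted(sol.free_symbols(), key=str)
            if form:
                values = evaluate_positive(
                    [a.expression for a in form], free, rng, n=20
                )
                assert (values >= 0).all()
            assert len(sol.trace) <= 10 * net.n_states
        assert solved >= 6  # most random fixtures are solvable

    def test_deterministic_output(self):
        net1, sol1 = _try_solve(3)
        net2, sol2 = _try_solve(3)
        assert sol1 is not None and sol2 is not None
        assert [str(a) for a in sol1.assignments] == [str(a) for a in sol2.assignments]
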